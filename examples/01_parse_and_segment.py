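"""Parse a CASAS-dialect event log and segment it into activity instances.

The log below is a miniature annotated stream: a 'Bathe' activity wrapped in
begin/end markers, one numeric temperature reading, and a trailing
unannotated motion event that belongs to no activity.
"""

import io

import zeroshot_har as z

LOG = """\
2012-07-18 13:47:05.0 M012 ON
2012-07-18 13:47:10.0 D002 OPEN Bathe begin
2012-07-18 13:47:15.0 M012 OFF
2012-07-18 13:47:20.0 T101 21.5
2012-07-18 13:47:25.0 M013 ON
2012-07-18 13:47:35.0 D002 CLOSE Bathe end
2012-07-18 13:48:00.0 M012 ON
"""

events = z.parse_events(io.StringIO(LOG))
print(f"parsed {len(events)} events "
      f"({sum(e.is_categorical for e in events)} categorical, "
      f"{sum(not e.is_categorical for e in events)} numeric)")

for inst in z.segment_instances(events):
    print(f"instance '{inst.label}': {len(inst.events)} events "
          f"from {inst.start.time()} to {inst.end.time()}")
# Only events between the begin and end annotations (inclusive) are inside
# the instance; the 13:48 event is outside every activity and is dropped.
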