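"""Turn activity instances into the per-sensor ON-count feature matrix.

Each instance becomes a row; column j counts that sensor's activation events
(ON/OPEN).  OFF/CLOSE transitions and numeric sensors contribute nothing, so
the row sum equals the instance's total number of activations.
"""

import io

import zeroshot_har as z

LOG = """\
2012-07-18 09:00:00.0 M001 ON Cook begin
2012-07-18 09:00:05.0 M001 OFF
2012-07-18 09:00:10.0 M001 ON
2012-07-18 09:00:15.0 D003 OPEN
2012-07-18 09:00:20.0 M001 OFF Cook end
2012-07-18 10:00:00.0 M002 ON Sleep begin
2012-07-18 10:00:05.0 M002 OFF Sleep end
"""

instances = z.segment_instances(z.parse_events(io.StringIO(LOG)))
vocabulary = z.build_vocabulary(instances)
matrix = z.build_feature_matrix(instances, vocabulary)

print("sensors:", vocabulary.sensor_ids)
for label, row in zip(matrix.row_labels, matrix.values):
    print(f"{label:>6}: {row.tolist()}")
# 'Cook' activates M001 twice and opens D003 once -> [1, 2, 0];
# 'Sleep' turns M002 on once -> [0, 0, 1].
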