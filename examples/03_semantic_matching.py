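"""Activity labels as word-vector prototypes; nearest-prototype matching.

Multi-word labels average their tokens' vectors ('Wash Dinner Dishes' is the
mean of wash, dinner, dishes), and an unknown semantic vector is labeled by
maximal cosine similarity against the candidate prototypes.
"""

import io

import numpy as np

import zeroshot_har as z

TABLE = """\
5 3
wash 1.0 0.0 0.0
dinner 0.0 1.0 0.0
dishes 0.0 0.0 1.0
sleep -0.9 0.1 0.0
toilet 0.1 -0.8 0.3
"""

table = z.load_embeddings(io.StringIO(TABLE))
protos = [z.label_to_prototype(lab, table)
          for lab in ("Wash Dinner Dishes", "Sleep", "Toilet")]
for p in protos:
    print(f"{p.label:>18}: {np.round(p.vector, 3).tolist()}")

query = np.array([0.4, 0.3, 0.35])  # a hypothetical predicted semantic vector
label, similarity = z.nearest_prototype(query, protos)
print(f"query matches '{label}' with cosine similarity {similarity:.3f}")
# The query points into the positive octant shared by wash/dinner/dishes, so
# the composite 'Wash Dinner Dishes' prototype wins.
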