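"""Stress-test the semantic space with distractor vocabulary.

Zero-shot accuracy is recomputed while the candidate label set is inflated
with extra words: random tokens (easy — a well-spanned space barely moves)
and each prototype's nearest embedding neighbors (hard — semantically close
impostors soak up predictions).
"""

import io

import zeroshot_har.casas as casas
import zeroshot_har.synthetic as syn
from zeroshot_har.evaluation import evaluate_with_distractors
from zeroshot_har.features import build_feature_matrix, build_vocabulary, fit_scaler
from zeroshot_har.network import NetworkConfig, ZeroShotNetwork

scenario = syn.make_congruent_scenario(
    3, 2, 12, train_instances_per_class=25, test_instances=60,
    embedding_dim=8, seed=3,
)
stream, _, _ = syn.generate_stream(
    scenario.seen_profiles + scenario.unseen_profiles, 3
)
instances = casas.segment_instances(casas.parse_events(io.StringIO(stream)))
train = [i for i in instances if i.label in scenario.seen_labels]
test = [i for i in instances if i.label in scenario.unseen_labels]
vocab = build_vocabulary(train)
scaler = fit_scaler(build_feature_matrix(train, vocab))
xtr = build_feature_matrix(train, vocab, scaler=scaler)
xts = build_feature_matrix(test, vocab, scaler=scaler)
table, seen_protos, unseen_protos = syn.make_toy_embeddings(scenario)

net = ZeroShotNetwork(
    NetworkConfig(input_dim=xtr.n, hidden2=8, epochs=80, seed=3), seen_protos
)
net.train(xtr)

for mode in ("random", "knn"):
    accuracy = evaluate_with_distractors(
        net, xts, unseen_protos, table,
        distractor_counts=(0, 5, 10, 20), mode=mode, seed=5,
    )
    row = "  ".join(f"k={k}: {a:.2f}" for k, a in accuracy.items())
    print(f"{mode:>6} distractors -> {row}")
# k=0 is the plain evaluation.  Nearest-neighbor distractors bite harder
# than random ones at every k.  Note the toy space has only 8 dimensions, so
# even random words land near the prototypes; in a 300-d embedding random
# nouns are nearly orthogonal and the random curve stays much flatter.
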