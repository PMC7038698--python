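"""Confusion matrices, one-vs-rest metrics, correlations, distractors."""

import io

import numpy as np
import pytest

import zeroshot_har as z
from zeroshot_har.evaluation import write_metrics_table

from conftest import HH101_S1, HH101_S2, HH125_S2, expand_confusion


class TestConfusion:
    def test_perfect_predictions_give_diagonal(self):
        truth = ["a", "b", "c", "a"]
        cm = z.confusion(truth, truth, ["a", "b", "c"])
        assert (cm.counts == np.diag([2, 1, 1])).all()
        assert cm.micro_accuracy == 1.0

    def test_random_pairs_match_brute_force_tally(self):
        rng = np.random.default_rng(0)
        labels = ["x", "y", "z"]
        truth = [labels[i] for i in rng.integers(3, size=50)]
        predicted = [labels[i] for i in rng.integers(3, size=50)]
        cm = z.confusion(truth, predicted, labels)
        for i, t in enumerate(labels):
            for j, p in enumerate(labels):
                expected = sum(1 for a, b in zip(truth, predicted) if a == t and b == p)
                assert cm.counts[i, j] == expected
        assert cm.total == 50

    def test_published_scenario1_matrix_reconstructs_exactly(self):
        labels, counts = HH101_S1
        truth, predicted = expand_confusion(labels, counts)
        cm = z.confusion(truth, predicted, labels)
        assert (cm.counts == counts).all()
        assert cm.counts[0].tolist() == [84, 0, 0]

    def test_length_mismatch_and_unknown_label_error(self):
        with pytest.raises(ValueError):
            z.confusion(["a"], ["a", "b"], ["a", "b"])
        with pytest.raises(ValueError, match="'q'"):
            z.confusion(["a"], ["q"], ["a", "b"])


class TestClassMetrics:
    def test_published_hh101_scenario1_metrics(self):
        labels, counts = HH101_S1
        cm = z.ConfusionMatrix(labels, counts)
        metrics = z.class_metrics(cm)
        relax = metrics["Relax"].rounded()
        assert relax["accuracy"] == 98.87 and relax["f_measure"] == 0.96
        sleep = metrics["Sleep"].rounded()
        assert sleep["accuracy"] == 83.2 and sleep["f_measure"] == 0.6
        toilet = metrics["Toilet"].rounded()
        assert toilet["accuracy"] == 84.33 and toilet["f_measure"] == 0.88
        # N(Classified)/N(Truth) accounting = column/row sums
        assert metrics["Relax"].n_classified == 91 and metrics["Relax"].n_truth == 84
        assert metrics["Sleep"].n_classified == 176 and metrics["Sleep"].n_truth == 86
        assert metrics["Toilet"].n_classified == 352 and metrics["Toilet"].n_truth == 449

    def test_diagonal_matrix_is_perfect_everywhere(self):
        cm = z.ConfusionMatrix(("a", "b"), np.diag([5, 7]))
        for m in z.class_metrics(cm).values():
            assert m.accuracy == 100.0
            assert m.precision == m.recall == m.f_measure == 1.0

    def test_random_matrix_matches_brute_force_one_vs_rest(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 30, size=(4, 4))
        labels = tuple("abcd")
        cm = z.ConfusionMatrix(labels, counts)
        metrics = z.class_metrics(cm)
        total = counts.sum()
        for i, lab in enumerate(labels):
            tp = counts[i, i]
            fp = counts[:, i].sum() - tp
            fn = counts[i, :].sum() - tp
            tn = total - tp - fp - fn
            m = metrics[lab]
            assert (m.tp, m.fp, m.fn, m.tn) == (tp, fp, fn, tn)
            assert m.tp + m.tn + m.fp + m.fn == total
            assert m.accuracy == pytest.approx(100 * (tp + tn) / total)
            assert m.precision == pytest.approx(tp / (tp + fp) if tp + fp else 0.0)
            assert m.recall == pytest.approx(tp / (tp + fn) if tp + fn else 0.0)

    def test_f_measure_invariant_under_precision_recall_exchange(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            k = int(rng.integers(2, 6))
            counts = rng.integers(0, 20, size=(k, k))
            if counts.sum() == 0:
                continue
            cm = z.ConfusionMatrix(tuple(f"c{i}" for i in range(k)), counts)
            transposed = z.ConfusionMatrix(cm.labels, counts.T.copy())
            for lab in cm.labels:
                m, mt = z.class_metrics(cm)[lab], z.class_metrics(transposed)[lab]
                # transposing swaps precision and recall but leaves F unchanged
                assert m.precision == pytest.approx(mt.recall)
                assert m.f_measure == pytest.approx(mt.f_measure)
                assert m.accuracy == pytest.approx(mt.accuracy)

    def test_zero_denominator_conventions(self):
        counts = np.array([[0, 3], [0, 5]])  # class a: never predicted, never right
        m = z.class_metrics(z.ConfusionMatrix(("a", "b"), counts))["a"]
        assert m.precision == 0.0 and m.recall == 0.0 and m.f_measure == 0.0

    def test_metrics_table_layout(self):
        labels, counts = HH101_S2
        sink = io.StringIO()
        write_metrics_table(z.ConfusionMatrix(labels, counts), sink)
        lines = sink.getvalue().splitlines()
        assert lines[0].split("\t") == [
            "Class", "N (Classified)", "N (Truth)", "Accuracy",
            "Precision", "Recall", "F-Measure",
        ]
        # precision/recall follow the one-vs-rest definitions literally
        assert lines[1].split("\t") == ["Cook Lunch", "17", "13", "97.84", "0.76", "1", "0.87"]


class TestCorrelationMatrix:
    def test_self_correlation_is_one(self):
        labels, matrix = z.correlation_matrix(
            {"a": np.array([1.0, 2, 3]), "b": np.array([1.0, 2, 3])}
        )
        assert matrix[0, 0] == 1.0 and matrix[0, 1] == pytest.approx(1.0)

    def test_negated_vector_gives_minus_one_under_pearson(self):
        x = np.array([1.0, -2.0, 3.0])
        _, matrix = z.correlation_matrix({"x": x, "neg": -x}, method="pearson")
        assert matrix[0, 1] == pytest.approx(-1.0)

    def test_random_triple_matches_covariance_formula(self):
        rng = np.random.default_rng(4)
        vectors = {lab: rng.normal(size=10) for lab in "abc"}
        labels, matrix = z.correlation_matrix(vectors, method="pearson")
        for i, li in enumerate(labels):
            for j, lj in enumerate(labels):
                x, y = vectors[li], vectors[lj]
                expected = ((x - x.mean()) * (y - y.mean())).mean() / (x.std() * y.std())
                assert matrix[i, j] == pytest.approx(expected, abs=1e-10)
        assert np.allclose(matrix, matrix.T)

    def test_constant_vector_under_pearson_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            z.correlation_matrix(
                {"a": np.ones(4), "b": np.arange(4.0)}, method="pearson"
            )

    def test_cosine_method_matches_direct_computation(self):
        rng = np.random.default_rng(6)
        vectors = {lab: rng.normal(size=5) for lab in "ab"}
        _, matrix = z.correlation_matrix(vectors, method="cosine")
        assert matrix[0, 1] == pytest.approx(
            z.cosine_similarity(vectors["a"], vectors["b"])
        )


@pytest.fixture(scope="module")
def synthetic_setup():
    import io as _io

    import zeroshot_har.casas as casas
    import zeroshot_har.synthetic as syn
    from zeroshot_har.features import build_feature_matrix, build_vocabulary, fit_scaler
    from zeroshot_har.network import NetworkConfig, ZeroShotNetwork

    scenario = syn.make_congruent_scenario(
        3, 2, 12, train_instances_per_class=25, test_instances=60,
        embedding_dim=8, seed=3,
    )
    stream, _, _ = syn.generate_stream(
        scenario.seen_profiles + scenario.unseen_profiles, 3
    )
    instances = casas.segment_instances(casas.parse_events(_io.StringIO(stream)))
    train = [i for i in instances if i.label in scenario.seen_labels]
    test = [i for i in instances if i.label in scenario.unseen_labels]
    vocab = build_vocabulary(train)
    scaler = fit_scaler(build_feature_matrix(train, vocab))
    xtr = build_feature_matrix(train, vocab, scaler=scaler)
    xts = build_feature_matrix(test, vocab, scaler=scaler)
    table, seen_p, unseen_p = syn.make_toy_embeddings(scenario)
    net = ZeroShotNetwork(
        NetworkConfig(input_dim=xtr.n, hidden2=8, epochs=80, seed=3), seen_p
    )
    net.train(xtr)
    return net, xts, unseen_p, table


class TestDistractors:
    def test_zero_distractors_is_a_no_op(self, synthetic_setup):
        net, xts, unseen, table = synthetic_setup
        results = z.evaluate_with_distractors(
            net, xts, unseen, table, distractor_counts=[0], seed=0
        )
        predicted = net.predict_zero_shot(xts, unseen)
        plain = np.mean([p == t for p, t in zip(predicted, xts.row_labels)])
        assert results[0] == pytest.approx(plain)

    def test_orthogonal_distractors_leave_accuracy_unchanged(self, synthetic_setup):
        net, xts, unseen, table = synthetic_setup
        from zeroshot_har.features import FeatureMatrix

        # a test subset smaller than L so its embeddings span a proper subspace
        sub = FeatureMatrix(xts.values[:5], xts.row_labels[:5], xts.vocabulary)
        predicted = net.predict_zero_shot(sub, unseen)
        base = np.mean([p == t for p, t in zip(predicted, sub.row_labels)])
        # construct distractors orthogonal to every embedding of the subset
        embeddings = net.embed(np.asarray(sub.values, dtype=float))
        _, _, vt = np.linalg.svd(embeddings)
        rank = np.linalg.matrix_rank(embeddings)
        assert rank < embeddings.shape[1], "need a nonempty orthogonal complement"
        orth = [z.ClassPrototype(f"orth{i}", v) for i, v in enumerate(vt[rank:][:2])]
        with_orth = net.predict_zero_shot(sub, list(unseen) + orth)
        accuracy = np.mean([p == t for p, t in zip(with_orth, sub.row_labels)])
        assert accuracy == pytest.approx(base)

    def test_duplicate_prototype_resolved_by_tie_break(self, synthetic_setup):
        net, xts, unseen, table = synthetic_setup
        twin = z.ClassPrototype("AAATwin", unseen[0].vector.copy())
        predicted = net.predict_zero_shot(xts, list(unseen) + [twin])
        # brute-force enumeration with the lexicographic tie rule
        for row, pred in zip(np.asarray(xts.values, dtype=float), predicted):
            emb = net.embed(row)
            sims = {p.label: z.cosine_similarity(emb, p.vector)
                    for p in list(unseen) + [twin]}
            best = max(sims.values())
            expected = min(lab for lab, s in sims.items() if s == pytest.approx(best))
            assert pred == expected
        # the twin sorts before the original, so it absorbs those wins
        assert unseen[0].label not in predicted

    def test_random_mode_keeps_accuracy_high_and_knn_is_harder(self, synthetic_setup):
        net, xts, unseen, table = synthetic_setup
        random_acc = z.evaluate_with_distractors(
            net, xts, unseen, table, distractor_counts=[0, 10], mode="random", seed=5
        )
        knn_acc = z.evaluate_with_distractors(
            net, xts, unseen, table, distractor_counts=[10], mode="knn", seed=5
        )
        assert random_acc[0] >= 0.8
        assert knn_acc[10] <= random_acc[10] + 1e-9

    def test_k_exceeding_vocabulary_is_an_error(self, synthetic_setup):
        net, xts, unseen, table = synthetic_setup
        with pytest.raises(ValueError, match="exceeds"):
            z.evaluate_with_distractors(
                net, xts, unseen, table, distractor_counts=[10_000], seed=0
            )
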