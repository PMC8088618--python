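"""Metrics, paired tests, and the cross-validation driver."""

import itertools

import numpy as np
import pytest
from scipy.stats import wilcoxon as scipy_wilcoxon

from dtifuse.evaluation import (
    ConfusionCounts,
    CrossValidationResult,
    auprc,
    auroc,
    classification_metrics,
    cross_validate,
    wilcoxon_signed_rank,
)
from dtifuse.model import TrainingConfig
from dtifuse.splits import split_baseline


def auroc_brute_force(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestClassificationMetrics:
    def test_hand_computed_example(self):
        m = classification_metrics(ConfusionCounts(tp=2, tn=6, fp=1, fn=1))
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["recall"] == pytest.approx(2 / 3)
        assert m["f_measure"] == pytest.approx(2 / 3)
        assert m["accuracy"] == pytest.approx(0.8)

    def test_zero_precision_recall_convention(self):
        m = classification_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=5))
        assert m["f_measure"] == 0.0
        assert m["accuracy"] == 0.5

    def test_perfect_classifier(self):
        m = classification_metrics(ConfusionCounts(tp=4, tn=6, fp=0, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_accuracy_identity(self):
        c = ConfusionCounts(tp=3, tn=2, fp=4, fn=1)
        m = classification_metrics(c)
        assert m["accuracy"] * c.total == pytest.approx(c.tp + c.tn)

    def test_from_predictions(self):
        c = ConfusionCounts.from_predictions([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert auroc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_single_inversion(self):
        assert auroc([0.9, 0.4, 0.6, 0.2], [1, 0, 1, 0]) == 1.0
        assert auroc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auroc([0.1, 0.9], [1, 1])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(2, 9))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            scores = rng.choice([0.1, 0.2, 0.3, 0.4], size=n)
            assert auroc(scores, labels) == pytest.approx(
                auroc_brute_force(scores, labels)
            )


class TestAuprc:
    def test_perfect_ranking(self):
        assert auprc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_single_positive_ranked_last(self):
        # precision at the positive's threshold = 1/4, one recall step
        assert auprc([0.9, 0.8, 0.7, 0.1], [0, 0, 0, 1]) == pytest.approx(0.25)

    def test_mean_approaches_prevalence_under_random_scores(self):
        # asymptotic property: average precision has a small positive bias
        # at low n, so test at n large enough for it to vanish
        rng = np.random.default_rng(1)
        labels = np.array([1] * 200 + [0] * 800)
        values = [
            auprc(rng.random(1000), labels) for _ in range(100)
        ]
        assert np.mean(values) == pytest.approx(0.2, abs=0.02)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            auprc([0.1, 0.2], [0, 0])

    def test_matches_sklearn_average_precision(self):
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(2)
        for _ in range(20):
            labels = rng.integers(0, 2, size=30)
            if labels.sum() == 0:
                continue
            scores = rng.random(30)
            assert auprc(scores, labels) == pytest.approx(
                average_precision_score(labels, scores)
            )


def wilcoxon_enumeration(d, alternative):
    """Exhaustive sign-assignment oracle for small n."""
    from scipy.stats import rankdata

    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    p_ge = (ws >= w_obs - 1e-9).mean()
    p_le = (ws <= w_obs + 1e-9).mean()
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        with pytest.warns(UserWarning, match="zero"):
            assert wilcoxon_signed_rank([1, 2, 3], [1, 2, 3]) == 1.0

    def test_five_positive_differences_exact(self):
        a = [2.0, 3.0, 4.0, 5.0, 6.0]
        b = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert wilcoxon_signed_rank(a, b, "greater") == pytest.approx(0.03125)
        assert wilcoxon_signed_rank(a, b, "two-sided") == pytest.approx(0.0625)

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_matches_enumeration_oracle(self, alternative):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(2, 11))
            d = rng.choice([-3, -2, -1, 1, 2, 3], size=n).astype(float)
            a = d
            b = np.zeros(n)
            assert wilcoxon_signed_rank(a, b, alternative) == pytest.approx(
                wilcoxon_enumeration(d, alternative)
            )

    def test_agrees_with_scipy_exact(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        ours = wilcoxon_signed_rank(a, b, "two-sided")
        theirs = scipy_wilcoxon(a, b, alternative="two-sided",
                                method="exact").pvalue
        assert ours == pytest.approx(theirs)


class TestCrossValidate:
    def test_per_fold_table_and_summary(self, small_benchmark):
        b = small_benchmark
        rng = np.random.default_rng(0)
        pe = {p: rng.normal(size=8) for p in b.sequences}
        ce = {c: rng.normal(size=8) for c in b.smiles}
        assignment = split_baseline(b.pairs, k=3, seed=0)
        cfg = TrainingConfig(epochs=2, batch_size=64, latent_dim=8,
                             validation_fraction=0.0, seed=0)
        result = cross_validate(assignment, "network", cfg,
                                protein_embeddings=pe,
                                compound_embeddings=ce)
        assert len(result.table) == 3
        assert set(result.table["fold"]) == {0, 1, 2}
        assert len(result.predictions) == 3
        assert result.sd["auroc"] >= 0.0
        assert "mean" in result.summary()

    def test_sd_zero_for_identical_folds(self):
        import pandas as pd

        table = pd.DataFrame(
            [{"fold": i, "auroc": 0.8, "auprc": 0.7, "f_measure": 0.6,
              "accuracy": 0.75} for i in range(5)]
        )
        result = CrossValidationResult(table=table)
        assert (result.sd == 0).all()
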