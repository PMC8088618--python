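"""Fusion model: forward arithmetic, loss, training behaviour, prediction."""

import numpy as np
import pytest

from dtifuse import _nn
from dtifuse.interactome import LabeledPairSet
from dtifuse.model import FusionModel, FusionResults, TrainingConfig, bce_l2_loss
from dtifuse.protein_features import CnnConfig


def network_model(latent=3, emb=4, n=6, seed=0, **cfg_kw):
    rng = np.random.default_rng(seed)
    pe = {f"P{i}": rng.normal(size=emb) for i in range(n)}
    ce = {f"C{i}": rng.normal(size=emb) for i in range(n)}
    pairs = LabeledPairSet.from_records(
        [(f"P{i}", f"C{(i * 3 + 1) % n}", i % 2) for i in range(n)]
    )
    cfg = TrainingConfig(latent_dim=latent, dropout=0.0, l2=0.0,
                         validation_fraction=0.0, seed=seed, **cfg_kw)
    model = FusionModel(pairs, mode="network", protein_embeddings=pe,
                        compound_embeddings=ce, config=cfg)
    # identity scalers so latent arithmetic is directly inspectable
    model._scalers = {
        "emb_p": (np.zeros(emb), np.ones(emb)),
        "emb_c": (np.zeros(emb), np.ones(emb)),
    }
    return model, pairs, pe, ce


class TestForward:
    def test_unit_latent_vectors_give_sigmoid_one(self):
        model, pairs, _, _ = network_model()
        e1 = np.zeros(3)
        e1[0] = 1.0
        model.f.W[...] = 0.0
        model.f.b[...] = e1
        model.g.W[...] = 0.0
        model.g.b[...] = e1
        model.h.W[...] = 1.0
        model.h.b[...] = 0.0
        score = model._forward(["P0"], ["C0"])[0]
        assert score == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-12)

    def test_zero_latent_gives_sigmoid_of_bias(self):
        model, *_ = network_model()
        model.f.W[...] = 0.0
        model.f.b[...] = 0.0
        model.h.b[...] = 0.0
        assert model._forward(["P0"], ["C0"])[0] == pytest.approx(0.5)
        model.h.b[...] = 2.0
        assert model._forward(["P0"], ["C0"])[0] == pytest.approx(
            1 / (1 + np.exp(-2.0))
        )

    def test_matches_matrix_arithmetic_oracle(self):
        model, pairs, pe, ce = network_model(seed=3)
        prots = list(pairs.frame["protein_id"])
        comps = list(pairs.frame["compound_id"])
        got = model._forward(prots, comps)
        vp = np.stack([pe[p] for p in prots])
        vc = np.stack([ce[c] for c in comps])
        x = vp @ model.f.W + model.f.b
        y = vc @ model.g.W + model.g.b
        logit = (x * y) @ model.h.W[:, 0] + model.h.b[0]
        np.testing.assert_allclose(got, 1 / (1 + np.exp(-logit)), atol=1e-10)

    def test_not_symmetric_under_side_swap(self):
        # f and g are distinct maps: swapping the two feature vectors
        # changes the score in general
        model, pairs, pe, ce = network_model(seed=4)
        p, c = "P0", "C0"
        s1 = model._forward([p], [c])[0]
        pe_swapped = {p: ce[c]}
        ce_swapped = {c: pe[p]}
        model.protein_embeddings = pe_swapped
        model.compound_embeddings = ce_swapped
        s2 = model._forward([p], [c])[0]
        assert abs(s1 - s2) > 1e-6

    def test_mode_requires_matching_inputs(self):
        pairs = LabeledPairSet.from_records([("P0", "C0", 1)])
        with pytest.raises(ValueError, match="needs"):
            FusionModel(pairs, mode="network")
        with pytest.raises(ValueError, match="needs"):
            FusionModel(pairs, mode="molecular")


class TestLoss:
    def test_cross_entropy_at_half(self):
        assert bce_l2_loss(np.array([0.5]), np.array([1.0])) == pytest.approx(
            0.6931, abs=1e-4
        )

    def test_l2_penalty(self):
        loss = bce_l2_loss(
            np.array([0.5]), np.array([1.0]),
            weights=[np.array([1.0]), np.array([2.0])], l2=0.1,
        )
        assert loss == pytest.approx(-np.log(0.5) + 0.25, abs=1e-10)

    def test_lambda_zero_is_pure_cross_entropy(self):
        scores = np.array([0.3, 0.8])
        labels = np.array([0.0, 1.0])
        with_w = bce_l2_loss(scores, labels, weights=[np.ones(5)], l2=0.0)
        without = bce_l2_loss(scores, labels)
        assert with_w == without

    def test_saturated_scores_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            loss = bce_l2_loss(np.array([1.0]), np.array([1.0]))
        assert np.isfinite(loss)


class TestTraining:
    def test_deterministic_given_seed(self, small_benchmark):
        b = small_benchmark
        cfg = TrainingConfig(epochs=3, batch_size=64, latent_dim=8,
                             validation_fraction=0.0, seed=5,
                             cnn=CnnConfig(layers=((4, 5), (4, 3))))
        losses = []
        for _ in range(2):
            m = FusionModel(b.pairs, mode="molecular",
                            sequences=b.sequences,
                            fingerprints=b.fingerprints, config=cfg)
            losses.append(m.fit().final_train_loss)
        assert losses[0] == losses[1]

    def test_strong_l2_shrinks_weights(self, small_benchmark):
        b = small_benchmark
        norms = {}
        for l2 in (0.0, 10.0):
            cfg = TrainingConfig(epochs=10, batch_size=64, latent_dim=8,
                                 validation_fraction=0.0, seed=5, l2=l2,
                                 cnn=CnnConfig(layers=((4, 5), (4, 3))))
            m = FusionModel(b.pairs, mode="molecular",
                            sequences=b.sequences,
                            fingerprints=b.fingerprints, config=cfg)
            m.fit()
            norms[l2] = np.sqrt(sum(float((w**2).sum())
                                    for w in m._weight_arrays()))
        assert norms[10.0] < norms[0.0]

    def test_empty_training_set_rejected(self):
        empty = LabeledPairSet.from_records([])
        with pytest.raises(ValueError, match="empty"):
            FusionModel(empty, mode="network", protein_embeddings={},
                        compound_embeddings={})

    def test_history_and_summary(self, small_benchmark):
        b = small_benchmark
        cfg = TrainingConfig(epochs=4, batch_size=64, latent_dim=8,
                             validation_fraction=0.1, patience=10, seed=1,
                             cnn=CnnConfig(layers=((4, 5), (4, 3))))
        m = FusionModel(b.pairs, mode="molecular", sequences=b.sequences,
                        fingerprints=b.fingerprints, config=cfg)
        res = m.fit()
        assert len(res.history) <= 4
        assert "val_auroc" in res.history[-1]
        text = res.summary()
        assert "molecular" in text and "final train loss" in text


class TestPredict:
    def _fitted(self, small_benchmark):
        b = small_benchmark
        cfg = TrainingConfig(epochs=2, batch_size=64, latent_dim=8,
                             validation_fraction=0.0, seed=2,
                             cnn=CnnConfig(layers=((4, 5), (4, 3))))
        m = FusionModel(b.pairs, mode="molecular", sequences=b.sequences,
                        fingerprints=b.fingerprints, config=cfg)
        return b, m.fit()

    def test_threshold_is_strict(self, small_benchmark):
        _, res = self._fitted(small_benchmark)
        scores = np.array([0.51, 0.5, 0.49])
        labels = (scores > 0.5).astype(int)
        np.testing.assert_array_equal(labels, [1, 0, 0])

    def test_threshold_zero_all_positive(self, small_benchmark):
        b, res = self._fitted(small_benchmark)
        _, labels = res.predict(b.pairs, threshold=0.0)
        assert labels.min() == 1

    def test_missing_features_listed(self, small_benchmark):
        b, res = self._fitted(small_benchmark)
        ghost = LabeledPairSet.from_records([("GHOST", "C0000", 1)])
        with pytest.raises(ValueError, match="GHOST"):
            res.predict(ghost)
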