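"""The multi-modal interaction prediction model.

A protein is represented by the concatenation of its 1D-CNN sequence
encoding ``a`` and its protein-network embedding ``N_p``; a compound by the
concatenation of its fingerprint ``b`` and its compound-network embedding
``N_c``.  Fully connected maps ``f`` and ``g`` project both sides onto a
shared latent space of dimension ``d``; the interaction score is

    score = sigmoid( h( x_1 y_1, ..., x_d y_d ) ),     x = f(v_p), y = g(v_c)

an element-wise product followed by a fully connected output layer — a
learnable extension of cosine similarity.  A pair is called interacting
when score > threshold (default 0.5; ties are negative).

Three modes share this architecture:

* ``integrated`` — both modalities concatenated per side;
* ``molecular``  — sequence encoding and fingerprint only;
* ``network``    — the two node2vec embeddings only.

Training minimizes mean binary cross-entropy plus an L2 penalty
``l2 * sum(w^2) / 2`` over the convolutional and fully connected
parameters, by mini-batch Adam.  Batch normalization follows each
convolutional layer; dropout follows the fully connected latent maps
(both disabled appropriately at inference).  The model object follows the
fit/results pattern: ``FusionModel(...).fit()`` returns a
:class:`FusionResults` with the learned parameters, training history,
``predict`` and ``summary``.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np

from . import _nn
from .interactome import LabeledPairSet
from .protein_features import CnnConfig, CnnEncoder, one_hot_encode

logger = logging.getLogger(__name__)

Mode = Literal["integrated", "molecular", "network"]

__all__ = ["TrainingConfig", "FusionModel", "FusionResults", "bce_l2_loss"]


@dataclass
class TrainingConfig:
    """Optimization and architecture hyperparameters."""

    epochs: int = 200
    batch_size: int = 128
    learning_rate: float = 1e-3
    l2: float = 1e-4
    dropout: float = 0.5
    latent_dim: int = 128
    threshold: float = 0.5
    validation_fraction: float = 0.1
    patience: int = 20
    max_len: int | None = None  # None: longest training sequence
    clip_norm: float = 5.0  # global gradient-norm clip; 0 disables
    seed: int = 0
    cnn: CnnConfig = field(default_factory=CnnConfig)

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.l2 < 0:
            raise ValueError("l2 must be >= 0")


def bce_l2_loss(
    scores: np.ndarray,
    labels: np.ndarray,
    weights: list[np.ndarray] | None = None,
    l2: float = 0.0,
) -> float:
    """Mean binary cross-entropy plus ``l2 * sum(w^2) / 2``.

    Scores exactly 0 or 1 are clipped to 1e-12 with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if ((scores <= 0) | (scores >= 1)).any():
        warnings.warn("scores at 0 or 1 clipped to avoid log(0)")
        scores = np.clip(scores, 1e-12, 1 - 1e-12)
    data = -np.mean(labels * np.log(scores) + (1 - labels) * np.log(1 - scores))
    penalty = 0.0
    if weights and l2 > 0:
        penalty = l2 * sum(float((w**2).sum()) for w in weights) / 2.0
    return float(data + penalty)


class FusionModel:
    """Protein-compound interaction model over one, or both, modalities.

    Parameters
    ----------
    pairs : LabeledPairSet
        Training pairs with binary labels.
    mode : {"integrated", "molecular", "network"}
    sequences : mapping protein_id -> amino-acid string
        Required for integrated and molecular modes.
    fingerprints : mapping compound_id -> binary/real feature vector
        Required for integrated and molecular modes.
    protein_embeddings, compound_embeddings : mapping id -> vector
        Required for integrated and network modes (an
        :class:`~dtifuse.embedding.EmbeddingTable` works directly).
    config : TrainingConfig
    """

    def __init__(
        self,
        pairs: LabeledPairSet,
        mode: Mode = "integrated",
        *,
        sequences: Mapping[str, str] | None = None,
        fingerprints: Mapping[str, np.ndarray] | None = None,
        protein_embeddings=None,
        compound_embeddings=None,
        config: TrainingConfig | None = None,
    ):
        if len(pairs) == 0:
            raise ValueError("empty training set")
        if mode not in ("integrated", "molecular", "network"):
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode
        self.pairs = pairs
        self.config = config or TrainingConfig()
        self.sequences = sequences
        self.fingerprints = fingerprints
        self.protein_embeddings = protein_embeddings
        self.compound_embeddings = compound_embeddings

        self.uses_molecular = mode in ("integrated", "molecular")
        self.uses_network = mode in ("integrated", "network")
        if self.uses_molecular:
            if sequences is None or fingerprints is None:
                raise ValueError(f"mode {mode!r} needs sequences and fingerprints")
            self._check_coverage(pairs, sequences, fingerprints)
        if self.uses_network:
            if protein_embeddings is None or compound_embeddings is None:
                raise ValueError(f"mode {mode!r} needs both embedding tables")
            self._check_coverage(pairs, protein_embeddings, compound_embeddings)

        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self._onehot_cache: dict[str, object] = {}
        self._scalers: dict[str, tuple[np.ndarray, np.ndarray]] = {}

        prot_dim = comp_dim = 0
        self.cnn: CnnEncoder | None = None
        if self.uses_molecular:
            self.max_len = cfg.max_len or max(
                len(sequences[p]) for p in pairs.proteins
            )
            self.cnn = CnnEncoder(cfg.cnn, rng)
            prot_dim += cfg.cnn.out_dim
            any_fp = next(iter(fingerprints.values()))
            self.fp_dim = len(np.asarray(any_fp))
            comp_dim += self.fp_dim
        if self.uses_network:
            self.emb_dim_p = len(np.asarray(
                protein_embeddings[next(iter(pairs.proteins))]))
            self.emb_dim_c = len(np.asarray(
                compound_embeddings[next(iter(pairs.compounds))]))
            prot_dim += self.emb_dim_p
            comp_dim += self.emb_dim_c

        self.f = _nn.Affine(prot_dim, cfg.latent_dim, rng)
        self.g = _nn.Affine(comp_dim, cfg.latent_dim, rng)
        self.h = _nn.Affine(cfg.latent_dim, 1, rng)
        self._dropout_rng = np.random.default_rng(cfg.seed + 10_000)
        self.drop_f = _nn.Dropout(cfg.dropout, self._dropout_rng)
        self.drop_g = _nn.Dropout(cfg.dropout, self._dropout_rng)

    # ------------------------------------------------------------------
    @staticmethod
    def _check_coverage(pairs, prot_table, comp_table):
        missing_p = [p for p in sorted(pairs.proteins) if p not in prot_table]
        missing_c = [c for c in sorted(pairs.compounds) if c not in comp_table]
        if missing_p or missing_c:
            raise ValueError(
                f"missing features for proteins {missing_p[:5]} "
                f"and compounds {missing_c[:5]}"
            )

    def _onehot(self, protein: str):
        enc = self._onehot_cache.get(protein)
        if enc is None:
            enc = one_hot_encode(self.sequences[protein], self.max_len)
            self._onehot_cache[protein] = enc
        return enc

    # ------------------------------------------------------------------
    # forward / backward over a batch of (protein, compound) id pairs
    def _protein_inputs(self, proteins: list[str]):
        if not self.uses_molecular:
            return None, None
        mats = np.stack([self._onehot(p).matrix for p in proteins])
        lengths = np.array([self._onehot(p).true_length for p in proteins])
        return mats, lengths

    def _scale(self, name: str, block: np.ndarray) -> np.ndarray:
        """Standardize a feature block per dimension.

        Statistics are frozen on first use (training data), so the two
        modalities enter the latent maps on comparable scales and test
        inputs are transformed consistently.
        """
        if name not in self._scalers:
            mean = block.mean(axis=0)
            std = block.std(axis=0)
            std[std < 1e-8] = 1.0
            self._scalers[name] = (mean, std)
        mean, std = self._scalers[name]
        return (block - mean) / std

    def _forward(self, proteins: list[str], compounds: list[str],
                 train: bool = False) -> np.ndarray:
        parts_p, parts_c = [], []
        if self.uses_molecular:
            mats, lengths = self._protein_inputs(proteins)
            a = self.cnn.forward(mats, lengths, train=train)
            parts_p.append(a)
            parts_c.append(self._scale("fp", np.stack(
                [np.asarray(self.fingerprints[c], dtype=float)
                 for c in compounds])))
        if self.uses_network:
            parts_p.append(self._scale("emb_p", np.stack(
                [np.asarray(self.protein_embeddings[p], dtype=float)
                 for p in proteins])))
            parts_c.append(self._scale("emb_c", np.stack(
                [np.asarray(self.compound_embeddings[c], dtype=float)
                 for c in compounds])))
        v_p = np.concatenate(parts_p, axis=1)
        v_c = np.concatenate(parts_c, axis=1)
        x = self.drop_f.forward(self.f.forward(v_p), train)
        y = self.drop_g.forward(self.g.forward(v_c), train)
        self._x, self._y = x, y
        logit = self.h.forward(x * y)[:, 0]
        return _nn.sigmoid(logit)

    def _backward(self, dlogit: np.ndarray) -> None:
        dz = self.h.backward(dlogit[:, None])
        dx = dz * self._y
        dy = dz * self._x
        dv_p = self.f.backward(self.drop_f.backward(dx))
        self.g.backward(self.drop_g.backward(dy))
        if self.uses_molecular:
            da = dv_p[:, : self.config.cnn.out_dim]
            self.cnn.backward(da)

    # parameters subject to L2 (conv + fully connected weights and biases)
    def _weight_params(self):
        items = self.f.params() + self.g.params() + self.h.params()
        if self.cnn is not None:
            items += self.cnn.weight_params()
        return items

    def _all_params(self):
        items = self._weight_params()
        if self.cnn is not None:
            items += self.cnn.norm_params()
        return items

    def _zero_grad(self):
        for layer in (self.f, self.g, self.h):
            layer.zero_grad()
        if self.cnn is not None:
            self.cnn.zero_grad()

    def _weight_arrays(self) -> list[np.ndarray]:
        return [p for p, _ in self._weight_params()]

    def _snapshot(self):
        state = [p.copy() for p, _ in self._all_params()]
        if self.cnn is not None:
            state.append(
                [(n.running_mean.copy(), n.running_var.copy())
                 for n in self.cnn.norms if n is not None]
            )
        return state

    def _restore(self, state):
        items = self._all_params()
        for (p, _), saved in zip(items, state):
            p[...] = saved
        if self.cnn is not None:
            for norm, (rm, rv) in zip(
                [n for n in self.cnn.norms if n is not None], state[-1]
            ):
                norm.running_mean[...] = rm
                norm.running_var[...] = rv

    # ------------------------------------------------------------------
    def fit(self, verbose: bool = False) -> "FusionResults":
        """Train by mini-batch Adam; returns a results object.

        A ``validation_fraction`` of the training pairs is held out for
        early stopping on validation loss (patience in epochs, best
        parameters restored); set the fraction to 0 to train for the full
        epoch budget.
        """
        cfg = self.config
        frame = self.pairs.frame
        proteins = frame["protein_id"].to_numpy()
        compounds = frame["compound_id"].to_numpy()
        labels = frame["label"].to_numpy().astype(float)
        n = len(labels)
        rng = np.random.default_rng(cfg.seed + 20_000)

        # freeze feature scalers on the full training set
        if self.uses_molecular:
            self._scale("fp", np.stack(
                [np.asarray(self.fingerprints[c], dtype=float)
                 for c in sorted(self.pairs.compounds)]))
        if self.uses_network:
            self._scale("emb_p", np.stack(
                [np.asarray(self.protein_embeddings[p], dtype=float)
                 for p in sorted(self.pairs.proteins)]))
            self._scale("emb_c", np.stack(
                [np.asarray(self.compound_embeddings[c], dtype=float)
                 for c in sorted(self.pairs.compounds)]))

        n_val = int(round(cfg.validation_fraction * n))
        use_val = 0 < n_val < n
        perm = rng.permutation(n)
        val_idx = perm[:n_val] if use_val else np.empty(0, dtype=int)
        tr_idx = perm[n_val:] if use_val else perm

        if use_val and len(set(labels[val_idx])) < 2:
            # single-class validation split cannot rank; skip early stopping
            use_val = False
            tr_idx = perm

        optimizer = _nn.Adam(self._all_params(), lr=cfg.learning_rate)
        history: list[dict] = []
        best_val = -np.inf
        best_state = None
        best_epoch = -1
        stale = 0

        for epoch in range(cfg.epochs):
            order = rng.permutation(len(tr_idx))
            epoch_loss = 0.0
            n_batches = 0
            for s in range(0, len(tr_idx), cfg.batch_size):
                idx = tr_idx[order[s : s + cfg.batch_size]]
                p_batch = list(proteins[idx])
                c_batch = list(compounds[idx])
                y = labels[idx]
                self._zero_grad()
                scores = self._forward(p_batch, c_batch, train=True)
                eps = 1e-12
                data_loss = -np.mean(
                    y * np.log(scores + eps)
                    + (1 - y) * np.log(1 - scores + eps)
                )
                dlogit = (scores - y) / len(y)
                self._backward(dlogit)
                # L2 gradient on weights
                if cfg.l2 > 0:
                    for p, g in self._weight_params():
                        g += cfg.l2 * p
                if cfg.clip_norm > 0:
                    gnorm = np.sqrt(sum(float((g**2).sum())
                                        for _, g in self._all_params()))
                    if gnorm > cfg.clip_norm:
                        scale = cfg.clip_norm / gnorm
                        for _, g in self._all_params():
                            g *= scale
                optimizer.step()
                penalty = (
                    cfg.l2 * sum(float((w**2).sum())
                                 for w in self._weight_arrays()) / 2.0
                    if cfg.l2 > 0 else 0.0
                )
                epoch_loss += data_loss + penalty
                n_batches += 1
            record = {"epoch": epoch, "train_loss": epoch_loss / n_batches}
            if use_val:
                from .evaluation import auroc as _auroc  # lazy: avoid cycle

                val_scores = self._predict_scores(
                    list(proteins[val_idx]), list(compounds[val_idx])
                )
                record["val_loss"] = bce_l2_loss(
                    np.clip(val_scores, 1e-12, 1 - 1e-12), labels[val_idx],
                    self._weight_arrays(), cfg.l2,
                )
                # early stopping tracks validation AUROC: ranking quality is
                # robust to label noise, where cross-entropy degrades as
                # scores saturate
                record["val_auroc"] = _auroc(val_scores, labels[val_idx])
                if record["val_auroc"] > best_val + 1e-6:
                    best_val = record["val_auroc"]
                    best_state = self._snapshot()
                    best_epoch = epoch
                    stale = 0
                else:
                    stale += 1
            history.append(record)
            if verbose:
                logger.info("epoch %d: %s", epoch, record)
            if use_val and stale >= cfg.patience:
                break
        if best_state is not None:
            self._restore(best_state)
        return FusionResults(
            model=self, history=history,
            stopped_epoch=history[-1]["epoch"],
            best_epoch=best_epoch if best_state is not None
            else history[-1]["epoch"],
        )

    # ------------------------------------------------------------------
    def _predict_scores(self, proteins: list[str], compounds: list[str],
                        batch_size: int = 512) -> np.ndarray:
        out = np.empty(len(proteins))
        for s in range(0, len(proteins), batch_size):
            out[s : s + batch_size] = self._forward(
                proteins[s : s + batch_size],
                compounds[s : s + batch_size],
                train=False,
            )
        return out


@dataclass
class FusionResults:
    """Fitted model: learned parameters, history, prediction, summary."""

    model: FusionModel
    history: list[dict]
    stopped_epoch: int
    best_epoch: int

    def predict(self, pairs: LabeledPairSet,
                threshold: float | None = None):
        """Scores and hard labels for a pair set.

        A pair is labelled interacting iff score > threshold (strict;
        a score exactly at the threshold is negative).
        """
        threshold = (self.model.config.threshold
                     if threshold is None else threshold)
        frame = pairs.frame
        proteins = list(frame["protein_id"])
        compounds = list(frame["compound_id"])
        missing = []
        if self.model.uses_molecular:
            missing += [p for p in set(proteins)
                        if p not in self.model.sequences]
            missing += [c for c in set(compounds)
                        if c not in self.model.fingerprints]
        if self.model.uses_network:
            missing += [p for p in set(proteins)
                        if p not in self.model.protein_embeddings]
            missing += [c for c in set(compounds)
                        if c not in self.model.compound_embeddings]
        if missing:
            raise ValueError(f"missing features for entities: {sorted(missing)[:10]}")
        scores = self.model._predict_scores(proteins, compounds)
        labels = (scores > threshold).astype(int)
        return scores, labels

    @property
    def final_train_loss(self) -> float:
        return self.history[-1]["train_loss"]

    def summary(self) -> str:
        m = self.model
        cfg = m.config
        lines = [
            "Protein-compound interaction fusion model",
            "=" * 44,
            f"mode:            {m.mode}",
            f"training pairs:  {len(m.pairs)} "
            f"({int(m.pairs.frame['label'].sum())} positive)",
            f"latent dim d:    {cfg.latent_dim}",
        ]
        if m.uses_molecular:
            lines.append(
                f"CNN:             {cfg.cnn.layers} filters, "
                f"max_len {m.max_len}, fp dim {m.fp_dim}"
            )
        if m.uses_network:
            lines.append(
                f"embeddings:      protein d={m.emb_dim_p}, "
                f"compound d={m.emb_dim_c}"
            )
        lines += [
            f"optimizer:       Adam lr={cfg.learning_rate}, "
            f"batch={cfg.batch_size}, l2={cfg.l2}, dropout={cfg.dropout}",
            f"epochs run:      {self.stopped_epoch + 1} "
            f"(best epoch {self.best_epoch + 1})",
            f"final train loss {self.final_train_loss:.4f}",
        ]
        if "val_loss" in self.history[-1]:
            lines.append(
                f"final val loss   {self.history[-1]['val_loss']:.4f}"
            )
        return "\n".join(lines)
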