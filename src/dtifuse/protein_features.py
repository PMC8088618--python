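"""Protein sequence featurization: one-hot encoding, k-mer frequencies,
and a 1D convolutional sequence encoder.

A sequence is embedded as a 20 x max_len one-hot matrix over the standard
amino-acid alphabet ``ACDEFGHIKLMNPQRSTVWY`` (fixed order; part of the
model contract).  Nonstandard residue codes (B, J, O, U, X, Z) map to
all-zero columns; sequences longer than max_len are truncated.

The encoder applies stacked 1-D convolutions (full-height filters) with
Leaky-ReLU activation and non-overlapping average pooling after each
convolution, optionally batch-normalized, followed by a global max pool
over valid (non-padding) positions.  The output dimension equals the last
layer's filter count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _nn

logger = logging.getLogger(__name__)

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
NONSTANDARD = set("BJOUXZ")

__all__ = [
    "ALPHABET",
    "OneHotSequence",
    "CnnConfig",
    "CnnEncoder",
    "one_hot_encode",
    "cnn_encode",
    "kmer_frequency",
]


@dataclass
class OneHotSequence:
    """20 x max_len one-hot matrix plus the unpadded sequence length."""

    matrix: np.ndarray
    true_length: int

    @property
    def max_len(self) -> int:
        return self.matrix.shape[1]


def one_hot_encode(sequence: str, max_len: int) -> OneHotSequence:
    """One-hot encode an amino-acid string, right-padding with zero columns."""
    if not sequence:
        raise ValueError("empty sequence")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    sequence = sequence.upper()
    bad = [ch for ch in sequence if not ch.isalpha() or not ch.isascii()]
    if bad:
        raise ValueError(f"non-letter characters in sequence: {sorted(set(bad))}")
    if len(sequence) > max_len:
        warnings.warn(
            f"sequence of length {len(sequence)} truncated to {max_len}"
        )
        sequence = sequence[:max_len]
    mat = np.zeros((len(ALPHABET), max_len))
    for j, ch in enumerate(sequence):
        idx = AA_INDEX.get(ch)
        if idx is not None:
            mat[idx, j] = 1.0
        # nonstandard residues (B/J/O/U/X/Z) stay all-zero
    return OneHotSequence(matrix=mat, true_length=len(sequence))


@dataclass
class CnnConfig:
    """Architecture of the sequence encoder.

    ``layers`` lists (filter count, filter width) per convolutional block;
    the final filter count is the encoder output dimension.
    """

    layers: tuple[tuple[int, int], ...] = ((64, 7), (64, 5))
    pool_window: int = 2
    leaky_slope: float = 0.01
    batch_norm: bool = True

    @property
    def out_dim(self) -> int:
        return self.layers[-1][0]


class CnnEncoder:
    """Stacked conv / (batch norm) / Leaky-ReLU / average-pool blocks with a
    masked global max pool producing one vector per sequence."""

    def __init__(self, config: CnnConfig, rng: np.random.Generator):
        self.config = config
        self.convs: list[_nn.Conv1D] = []
        self.norms: list[_nn.MaskedBatchNorm1D | None] = []
        self.acts: list[_nn.LeakyReLU] = []
        self.pools: list[_nn.AvgPool1D] = []
        in_ch = len(ALPHABET)
        for n_filters, width in config.layers:
            self.convs.append(_nn.Conv1D(in_ch, n_filters, width, rng))
            self.norms.append(
                _nn.MaskedBatchNorm1D(n_filters) if config.batch_norm else None
            )
            self.acts.append(_nn.LeakyReLU(config.leaky_slope))
            self.pools.append(_nn.AvgPool1D(config.pool_window))
            in_ch = n_filters

    @property
    def out_dim(self) -> int:
        return self.config.out_dim

    def forward(self, x: np.ndarray, lengths: np.ndarray,
                train: bool = False) -> np.ndarray:
        """Encode a batch (B, 20, L) with valid lengths to (B, out_dim)."""
        lengths = np.asarray(lengths, dtype=int)
        for conv, norm, act, pool in zip(
            self.convs, self.norms, self.acts, self.pools
        ):
            if (lengths < conv.width).any():
                raise ValueError(
                    f"filter width {conv.width} exceeds a remaining valid "
                    f"length (min {lengths.min()})"
                )
            x = conv.forward(x)
            lengths = lengths - conv.width + 1
            if norm is not None:
                x = norm.forward(x, _nn.length_mask(lengths, x.shape[2]), train)
            x = act.forward(x)
            x = pool.forward(x)
            lengths = lengths // pool.window
            if (lengths < 1).any():
                raise ValueError(
                    "a sequence has no valid positions after pooling; "
                    "input too short for this architecture"
                )
        self._pre_max_shape = x.shape
        out, self._argmax = _nn.masked_global_max(x, lengths)
        return out

    def backward(self, dout: np.ndarray) -> None:
        dx = _nn.masked_global_max_backward(
            dout, self._argmax, self._pre_max_shape
        )
        for conv, norm, act, pool in zip(
            reversed(self.convs), reversed(self.norms),
            reversed(self.acts), reversed(self.pools),
        ):
            dx = pool.backward(dx)
            dx = act.backward(dx)
            if norm is not None:
                dx = norm.backward(dx)
            dx = conv.backward(dx)

    # -- parameter plumbing ----------------------------------------------
    def weight_params(self):
        """(param, grad) pairs subject to L2 (conv filters and biases)."""
        items = []
        for conv in self.convs:
            items += conv.params()
        return items

    def norm_params(self):
        items = []
        for norm in self.norms:
            if norm is not None:
                items += norm.params()
        return items

    def zero_grad(self):
        for conv in self.convs:
            conv.zero_grad()
        for norm in self.norms:
            if norm is not None:
                norm.zero_grad()


def cnn_encode(x: OneHotSequence, encoder: CnnEncoder) -> np.ndarray:
    """Encode a single one-hot sequence to the encoder's output vector
    (inference mode; padding positions never reach the global max)."""
    batch = x.matrix[None, :, :]
    return encoder.forward(batch, np.array([x.true_length]), train=False)[0]


def kmer_frequency(sequence: str, k: int = 3) -> np.ndarray:
    """Normalized k-mer frequency vector of dimension 20**k.

    Windows containing nonstandard residues are skipped; counts are divided
    by the number of counted windows (entries sum to 1 when any window
    counted).  The 3-mer default yields the classic 8000-dimensional
    sequence feature.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sequence = sequence.upper()
    if len(sequence) < k:
        raise ValueError(f"sequence shorter than k={k}")
    dim = len(ALPHABET) ** k
    counts = np.zeros(dim)
    n_windows = 0
    for i in range(len(sequence) - k + 1):
        window = sequence[i : i + k]
        idx = 0
        for ch in window:
            j = AA_INDEX.get(ch)
            if j is None:
                idx = -1
                break
            idx = idx * len(ALPHABET) + j
        if idx >= 0:
            counts[idx] += 1
            n_windows += 1
    if n_windows:
        counts /= n_windows
    return counts
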