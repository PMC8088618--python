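"""Structure-vs-network similarity analysis.

Quantifies whether the similarity geometry of interactome embeddings is
redundant with classical molecular similarity: protein pairs are compared
by local sequence alignment score versus embedding cosine, compound pairs
by fingerprint Jaccard versus embedding cosine, and the relationship is
summarized by a scatter table plus the Pearson correlation coefficient.

The built-in protein similarity is Smith-Waterman local alignment with
BLOSUM62, gap open 11 / extend 1 (Biopython's PairwiseAligner); an
externally computed score table can be supplied instead wherever a
similarity callable is accepted.
"""

from __future__ import annotations

from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "sequence_similarity",
    "modality_scatter",
    "nearest_training_pair",
    "table_lookup",
]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def sequence_similarity(seq_a: str, seq_b: str) -> float:
    """Local alignment score of two amino-acid sequences (>= 0).

    Smith-Waterman with BLOSUM62 and affine gaps (open 11, extend 1); a
    pair with no positive-scoring local alignment scores 0.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    score = _ALIGNER.score(seq_a.upper(), seq_b.upper())
    return float(max(0.0, score))


def table_lookup(table: Mapping[tuple[str, str], float]
                 ) -> Callable[[str, str], float]:
    """Wrap an external (id_a, id_b) -> score table as a symmetric
    similarity callable (e.g. precomputed alignment bitscores)."""

    def sim(a: str, b: str) -> float:
        if (a, b) in table:
            return float(table[(a, b)])
        return float(table[(b, a)])

    return sim


def modality_scatter(
    pairs: Iterable[tuple[str, str]],
    sim_x: Callable[[str, str], float],
    sim_y: Callable[[str, str], float],
) -> tuple[pd.DataFrame, float]:
    """Per-pair (x, y) similarity table plus the Pearson correlation.

    ``sim_x`` is typically the molecular similarity (alignment score or
    fingerprint Jaccard), ``sim_y`` the embedding cosine.
    """
    rows = [
        {"entity_a": a, "entity_b": b, "x": sim_x(a, b), "y": sim_y(a, b)}
        for a, b in pairs
    ]
    if len(rows) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    frame = pd.DataFrame(rows)
    x, y = frame["x"].to_numpy(), frame["y"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a coordinate; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return frame, r


def nearest_training_pair(
    test_pair: tuple[str, str],
    training_pairs: Iterable[tuple[str, str]],
    protein_sim: Callable[[str, str], float],
    compound_sim: Callable[[str, str], float],
    top_k: int = 5,
) -> pd.DataFrame:
    """Rank training pairs by similarity to a test pair.

    The combined score is the product of the per-side similarities, each
    normalized by its maximum over the training set (so both sides carry
    equal weight regardless of scale).  Ties break by pair ID for a stable
    order.
    """
    training_pairs = list(training_pairs)
    if not training_pairs:
        raise ValueError("empty training set")
    tp, tc = test_pair
    psims = np.array([protein_sim(tp, p) for p, _ in training_pairs])
    csims = np.array([compound_sim(tc, c) for _, c in training_pairs])
    pmax = psims.max() if psims.max() > 0 else 1.0
    cmax = csims.max() if csims.max() > 0 else 1.0
    combined = (psims / pmax) * (csims / cmax)
    frame = pd.DataFrame(
        {
            "protein_id": [p for p, _ in training_pairs],
            "compound_id": [c for _, c in training_pairs],
            "protein_similarity": psims,
            "compound_similarity": csims,
            "combined": combined,
        }
    )
    frame = frame.sort_values(
        ["combined", "protein_id", "compound_id"],
        ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    return frame.head(top_k)
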