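"""Readers and containers for interactome-style link tables.

Handles whitespace/tab-delimited link files in the STITCH/STRING flat-file
dialect (two entity-ID columns followed by named integer confidence channels
on a 0-1000 scale), FASTA protein sequences, and two-column compound/SMILES
tables.  Edges are filtered on a single named confidence channel with a
"score >= threshold" retention rule; retained edges are weighted by
score / 1000, mapping the 0-1000 confidence scale into (0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "LabeledPairSet",
    "LinkFormatError",
    "read_links",
    "write_links",
    "read_positive_pairs",
    "sample_negatives",
    "restrict_to_common_entities",
    "RestrictionReport",
    "read_fasta",
    "read_compound_table",
    "write_compound_table",
    "write_fasta",
]


class LinkFormatError(ValueError):
    """Raised when a link table is malformed (missing channel, bad row)."""


class InteractionNetwork:
    """Weighted undirected network over opaque entity IDs.

    Wraps a :class:`networkx.Graph`; each edge carries a ``weight`` in (0, 1].
    A pair of entities is stored once regardless of input row direction.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    # -- construction -----------------------------------------------------
    def add_node(self, node: str) -> None:
        self.graph.add_node(node)

    def add_edge(self, u: str, v: str, weight: float) -> None:
        if u == v:
            raise ValueError(f"self-loop on {u!r} not allowed")
        if weight <= 0:
            raise ValueError("edge weight must be positive")
        if self.graph.has_edge(u, v):
            # directionality in input collapses to one edge keeping max weight
            weight = max(weight, self.graph[u][v]["weight"])
        self.graph.add_edge(u, v, weight=weight)

    # -- queries ----------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for u, v, d in self.graph.edges(data=True):
            yield u, v, d["weight"]

    def weight(self, u: str, v: str) -> float:
        return self.graph[u][v]["weight"]

    def neighbors(self, node: str) -> list[str]:
        return list(self.graph.neighbors(node))

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __repr__(self) -> str:  # pragma: no cover
        return f"InteractionNetwork({len(self)} nodes, {self.n_edges} edges)"


@dataclass(frozen=True)
class RestrictionReport:
    """Outcome of restricting a pair set to entities covered by all inputs."""

    pairs: "LabeledPairSet"
    n_kept: int
    n_dropped_protein: int
    n_dropped_compound: int


class LabeledPairSet:
    """Set of (protein, compound) pairs with binary labels and optional folds.

    Backed by a :class:`pandas.DataFrame` with columns
    ``protein_id, compound_id, label`` and optionally ``fold``.
    Duplicate (protein, compound) pairs are rejected.
    """

    COLUMNS = ("protein_id", "compound_id", "label")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        frame = frame.reset_index(drop=True).copy()
        if frame.duplicated(subset=["protein_id", "compound_id"]).any():
            raise ValueError("duplicate (protein_id, compound_id) pairs")
        labels = set(frame["label"].unique())
        if not labels <= {0, 1}:
            raise ValueError(f"labels must be binary, got {sorted(labels)}")
        frame["label"] = frame["label"].astype(int)
        if "fold" not in frame.columns:
            frame["fold"] = pd.array([pd.NA] * len(frame), dtype="Int64")
        else:
            frame["fold"] = frame["fold"].astype("Int64")
        self.frame = frame

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, int]]
    ) -> "LabeledPairSet":
        rows = list(records)
        return cls(
            pd.DataFrame(rows, columns=["protein_id", "compound_id", "label"])
            if rows
            else pd.DataFrame(columns=list(cls.COLUMNS))
        )

    # -- queries ----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self):
        return self.frame.itertuples(index=False)

    @property
    def proteins(self) -> set[str]:
        return set(self.frame["protein_id"])

    @property
    def compounds(self) -> set[str]:
        return set(self.frame["compound_id"])

    @property
    def pair_index(self) -> set[tuple[str, str]]:
        return set(
            zip(self.frame["protein_id"], self.frame["compound_id"])
        )

    def positives(self) -> "LabeledPairSet":
        return LabeledPairSet(self.frame[self.frame["label"] == 1])

    def subset(self, mask) -> "LabeledPairSet":
        return LabeledPairSet(self.frame[mask])

    # -- serialization ----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LabeledPairSet":
        return cls(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# link-table parsing


def _parse_link_rows(
    path: str | Path, score_channel: str, threshold: int
) -> Iterator[tuple[str, str, int]]:
    """Yield (id1, id2, score) for rows whose named channel passes threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if not header:
            raise LinkFormatError(f"{path}: empty file, expected a header")
        if score_channel not in header:
            raise LinkFormatError(
                f"{path}: no channel column named {score_channel!r}; "
                f"available: {header[2:]}"
            )
        col = header.index(score_channel)
        if col < 2:
            raise LinkFormatError(
                f"{path}: channel {score_channel!r} collides with ID columns"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != len(header):
                raise LinkFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(parts)}"
                )
            try:
                score = int(parts[col])
            except ValueError as exc:
                raise LinkFormatError(
                    f"{path}:{lineno}: non-integer score {parts[col]!r}"
                ) from exc
            if not 0 <= score <= 1000:
                raise LinkFormatError(
                    f"{path}:{lineno}: score {score} outside [0, 1000]"
                )
            if score >= threshold:
                yield parts[0], parts[1], score


def read_links(
    path: str | Path, score_channel: str, threshold: int
) -> InteractionNetwork:
    """Build a weighted network from a link table, filtering on one channel.

    Retains exactly the edges whose ``score_channel`` value is
    >= ``threshold``; edge weight is ``score / 1000``.  Self-loops,
    zero-score rows (no evidence, hence no positive weight) and duplicate
    edges (either direction) are dropped with a warning, keeping the
    maximum score for duplicates.
    """
    net = InteractionNetwork()
    n_self, n_dup, n_zero = 0, 0, 0
    for u, v, score in _parse_link_rows(path, score_channel, threshold):
        if score == 0:
            n_zero += 1
            continue
        if u == v:
            n_self += 1
            continue
        if net.graph.has_edge(u, v):
            n_dup += 1
        net.add_edge(u, v, weight=score / 1000.0)
    if n_self:
        logger.warning("%s: dropped %d self-loop rows", path, n_self)
    if n_zero:
        logger.warning("%s: dropped %d zero-score rows", path, n_zero)
    if n_dup:
        logger.warning(
            "%s: collapsed %d duplicate edges (kept max score)", path, n_dup
        )
    return net


def write_links(
    path: str | Path,
    edges: Iterable[tuple[str, str, int]],
    score_channel: str,
    id_columns: tuple[str, str] = ("item_id_a", "item_id_b"),
) -> None:
    """Write a minimal link table: two ID columns plus one channel column."""
    with open(path, "w") as fh:
        fh.write(f"{id_columns[0]}\t{id_columns[1]}\t{score_channel}\n")
        for u, v, score in edges:
            fh.write(f"{u}\t{v}\t{int(score)}\n")


def read_positive_pairs(
    path: str | Path, score_channel: str, threshold: int
) -> LabeledPairSet:
    """Read protein-compound pairs passing the channel threshold as positives.

    All returned records carry label 1; duplicates are collapsed.  The first
    ID column is taken as the protein, the second as the compound.
    """
    seen: dict[tuple[str, str], int] = {}
    for prot, comp, score in _parse_link_rows(path, score_channel, threshold):
        key = (prot, comp)
        if key in seen:
            seen[key] = max(seen[key], score)
        else:
            seen[key] = score
    return LabeledPairSet.from_records((p, c, 1) for p, c in seen)


# ---------------------------------------------------------------------------
# negative sampling


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def sample_negatives(
    positives: LabeledPairSet,
    proteins: Iterable[str],
    compounds: Iterable[str],
    ratio: float = 2.0,
    seed: int = 0,
) -> LabeledPairSet:
    """Augment positives with uniformly sampled non-interacting pairs.

    Draws ``round(ratio * n_positives)`` distinct (protein, compound) pairs,
    label 0, uniformly without replacement from the complement of the
    positive set over ``proteins x compounds``.  The 1:2 positive:negative
    design corresponds to the default ``ratio=2.0``.
    """
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    proteins = sorted(set(proteins))
    compounds = sorted(set(compounds))
    pos_pairs = positives.pair_index
    n_pos = len(positives)
    n_neg = _round_half_up(ratio * n_pos)
    universe = len(proteins) * len(compounds)
    n_pos_in_universe = sum(
        1 for p, c in pos_pairs if p in set(proteins) and c in set(compounds)
    )
    max_neg = universe - n_pos_in_universe
    if n_neg > max_neg:
        raise ValueError(
            f"requested {n_neg} negatives but only {max_neg} "
            f"non-positive pairs exist"
        )
    rng = np.random.default_rng(seed)
    chosen: set[tuple[str, str]] = set()
    # rejection sampling; falls back to enumeration when the complement is tight
    if n_neg > 0.5 * max_neg:
        complement = [
            (p, c)
            for p in proteins
            for c in compounds
            if (p, c) not in pos_pairs
        ]
        idx = rng.choice(len(complement), size=n_neg, replace=False)
        chosen = {complement[i] for i in idx}
    else:
        while len(chosen) < n_neg:
            p = proteins[rng.integers(len(proteins))]
            c = compounds[rng.integers(len(compounds))]
            if (p, c) not in pos_pairs and (p, c) not in chosen:
                chosen.add((p, c))
    records = [
        (r.protein_id, r.compound_id, int(r.label)) for r in positives
    ]
    records += [(p, c, 0) for p, c in sorted(chosen)]
    return LabeledPairSet.from_records(records)


def restrict_to_common_entities(
    pairs: LabeledPairSet,
    ppi: InteractionNetwork,
    cci: InteractionNetwork,
    sequences: Mapping[str, str],
    smiles: Mapping[str, str],
) -> RestrictionReport:
    """Keep pairs whose entities are covered by every required data source.

    A pair survives iff its protein is a PPI node with a known sequence and
    its compound is a CCI node with a known structure.  Returns the filtered
    set together with per-side dropped counts.
    """
    frame = pairs.frame
    prot_ok = frame["protein_id"].map(
        lambda p: p in ppi and p in sequences
    )
    comp_ok = frame["compound_id"].map(
        lambda c: c in cci and c in smiles
    )
    kept = LabeledPairSet(frame[prot_ok & comp_ok])
    report = RestrictionReport(
        pairs=kept,
        n_kept=len(kept),
        n_dropped_protein=int((~prot_ok).sum()),
        n_dropped_compound=int((~comp_ok).sum()),
    )
    logger.info(
        "restricted %d -> %d pairs (%d missing protein data, "
        "%d missing compound data)",
        len(pairs),
        report.n_kept,
        report.n_dropped_protein,
        report.n_dropped_compound,
    )
    return report


# ---------------------------------------------------------------------------
# molecular inputs


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences keyed by record ID (line wrapping tolerated)."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_compound_table(path: str | Path) -> dict[str, str]:
    """Read a two-column (compound_id, SMILES) TSV with header."""
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise LinkFormatError(f"{path}: expected two columns (id, SMILES)")
    return dict(zip(frame.iloc[:, 0].astype(str), frame.iloc[:, 1]))


def write_compound_table(path: str | Path, smiles: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("compound_id\tsmiles\n")
        for cid, smi in smiles.items():
            fh.write(f"{cid}\t{smi}\n")
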