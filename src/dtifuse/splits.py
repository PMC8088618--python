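"""Cross-validation split constructors for cold-start benchmarking.

Three k-fold designs of increasing difficulty:

* **baseline** — pairs are partitioned uniformly at random.
* **unseen compound** — compounds are partitioned into k groups so that no
  test fold shares a compound with any other fold; a pair's fold is its
  compound's group.  Groups are balanced by pair count with a seeded
  greedy largest-first pass.
* **hard** — proteins and compounds are independently partitioned into k
  groups; fold i tests on pairs with protein group i AND compound group i,
  and trains on pairs whose protein group != i and compound group != i.
  Pairs with mixed group membership relative to fold i would leak one
  entity into training and are excluded from that fold entirely.

Negative pairs follow the same entity-group rules as positives, so test
negatives are also unseen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import json
import numpy as np
import pandas as pd

from .interactome import LabeledPairSet

__all__ = [
    "FoldAssignment",
    "LeakageReport",
    "split_baseline",
    "split_unseen_compound",
    "split_hard",
    "audit_leakage",
]

Mode = Literal["baseline", "unseen", "hard"]


@dataclass
class FoldAssignment:
    """A k-fold assignment of labelled pairs.

    ``fold_of_pair`` maps (protein_id, compound_id) to a fold in [0, k).
    For hard splits, pairs unusable in some folds are tracked via
    ``excluded_of_fold``; ``train_pairs``/``test_pairs`` give the usable
    sets per fold for any mode.
    """

    k: int
    mode: Mode
    pairs: LabeledPairSet
    fold_of_pair: dict[tuple[str, str], int]
    fold_of_compound: dict[str, int] | None = None
    fold_of_protein: dict[str, int] | None = None

    def test_pairs(self, fold: int) -> LabeledPairSet:
        mask = self._pair_folds() == fold
        return self.pairs.subset(mask)

    def train_pairs(self, fold: int) -> LabeledPairSet:
        folds = self._pair_folds()
        if self.mode != "hard":
            return self.pairs.subset(folds != fold)
        pg, cg = self._group_arrays()
        mask = (pg != fold) & (cg != fold)
        return self.pairs.subset(mask)

    def excluded_count(self, fold: int) -> int:
        if self.mode != "hard":
            return 0
        pg, cg = self._group_arrays()
        test = (pg == fold) & (cg == fold)
        train = (pg != fold) & (cg != fold)
        return int((~test & ~train).sum())

    # -- internals --------------------------------------------------------
    def _pair_folds(self) -> np.ndarray:
        frame = self.pairs.frame
        return np.array(
            [
                self.fold_of_pair[(p, c)]
                for p, c in zip(frame["protein_id"], frame["compound_id"])
            ]
        )

    def _group_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        assert self.fold_of_protein is not None
        assert self.fold_of_compound is not None
        frame = self.pairs.frame
        pg = frame["protein_id"].map(self.fold_of_protein).to_numpy()
        cg = frame["compound_id"].map(self.fold_of_compound).to_numpy()
        return pg, cg

    # -- serialization ----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        frame = self.pairs.frame.copy()
        frame["fold"] = self._pair_folds()
        frame.to_csv(path, sep="\t", index=False)


@dataclass
class LeakageReport:
    passed: bool
    mode: Mode
    offending_entities: list[str] = field(default_factory=list)
    detail: str = ""

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "passed": self.passed,
                    "mode": self.mode,
                    "offending_entities": self.offending_entities,
                    "detail": self.detail,
                },
                indent=2,
            )
        )


def _check_k(k: int) -> None:
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")


def split_baseline(
    pairs: LabeledPairSet, k: int, seed: int = 0
) -> FoldAssignment:
    """Uniform random k-fold partition of the pairs; fold sizes differ <= 1."""
    _check_k(k)
    n = len(pairs)
    if n < k:
        raise ValueError(f"need at least k={k} pairs, have {n}")
    rng = np.random.default_rng(seed)
    folds = np.arange(n) % k
    rng.shuffle(folds)
    frame = pairs.frame
    fold_of_pair = {
        (p, c): int(f)
        for p, c, f in zip(frame["protein_id"], frame["compound_id"], folds)
    }
    return FoldAssignment(k=k, mode="baseline", pairs=pairs,
                          fold_of_pair=fold_of_pair)


def _greedy_group(
    entities: list[str], counts: dict[str, int], k: int, rng: np.random.Generator
) -> dict[str, int]:
    """Partition entities into k groups balancing total pair count.

    Seeded shuffle breaks ties among equal-count entities, then a greedy
    largest-first pass assigns each entity to the lightest group.
    """
    order = list(entities)
    rng.shuffle(order)
    order.sort(key=lambda e: -counts[e])
    loads = np.zeros(k)
    group: dict[str, int] = {}
    for e in order:
        g = int(np.argmin(loads))
        group[e] = g
        loads[g] += counts[e]
    return group


def split_unseen_compound(
    pairs: LabeledPairSet, k: int, seed: int = 0
) -> FoldAssignment:
    """k folds sharing no compounds; a pair's fold is its compound's group."""
    _check_k(k)
    frame = pairs.frame
    counts = frame["compound_id"].value_counts().to_dict()
    compounds = sorted(counts)
    if len(compounds) < k:
        raise ValueError(
            f"need at least k={k} distinct compounds, have {len(compounds)}"
        )
    rng = np.random.default_rng(seed)
    group = _greedy_group(compounds, counts, k, rng)
    fold_of_pair = {
        (p, c): group[c]
        for p, c in zip(frame["protein_id"], frame["compound_id"])
    }
    return FoldAssignment(
        k=k,
        mode="unseen",
        pairs=pairs,
        fold_of_pair=fold_of_pair,
        fold_of_compound=group,
    )


def split_hard(
    pairs: LabeledPairSet, k: int, seed: int = 0
) -> FoldAssignment:
    """k folds where test proteins AND compounds never appear in training.

    Proteins and compounds are independently partitioned (balanced by pair
    count); fold i's test set is pairs in protein group i and compound
    group i, its training set is pairs in neither group i.  Mixed pairs are
    excluded from fold i.
    """
    _check_k(k)
    frame = pairs.frame
    pcounts = frame["protein_id"].value_counts().to_dict()
    ccounts = frame["compound_id"].value_counts().to_dict()
    proteins, compounds = sorted(pcounts), sorted(ccounts)
    if len(proteins) < k or len(compounds) < k:
        raise ValueError(
            f"need >= k={k} distinct proteins and compounds, have "
            f"{len(proteins)} and {len(compounds)}"
        )
    rng = np.random.default_rng(seed)
    pgroup = _greedy_group(proteins, pcounts, k, rng)
    cgroup = _greedy_group(compounds, ccounts, k, rng)
    fold_of_pair: dict[tuple[str, str], int] = {}
    test_sizes = np.zeros(k, dtype=int)
    for p, c in zip(frame["protein_id"], frame["compound_id"]):
        if pgroup[p] == cgroup[c]:
            fold_of_pair[(p, c)] = pgroup[p]
            test_sizes[pgroup[p]] += 1
        else:
            fold_of_pair[(p, c)] = -1  # never in any test fold
    if (test_sizes == 0).any():
        empty = [i for i in range(k) if test_sizes[i] == 0]
        raise ValueError(
            f"hard split produced empty test folds {empty}; "
            f"try a different seed or smaller k"
        )
    return FoldAssignment(
        k=k,
        mode="hard",
        pairs=pairs,
        fold_of_pair=fold_of_pair,
        fold_of_protein=pgroup,
        fold_of_compound=cgroup,
    )


def audit_leakage(assignment: FoldAssignment, mode: Mode | None = None
                  ) -> LeakageReport:
    """Verify the entity-disjointness contracts of a fold assignment.

    baseline: folds must partition the pair set (always passes for a valid
    assignment).  unseen: no compound may occur in two folds.  hard: for
    every fold, test proteins/compounds must be absent from that fold's
    training pairs.
    """
    mode = mode or assignment.mode
    offenders: list[str] = []
    if mode == "baseline":
        folds = set(assignment.fold_of_pair.values())
        ok = folds <= set(range(assignment.k))
        return LeakageReport(
            passed=ok, mode=mode,
            detail="pairs partitioned into folds" if ok else "invalid fold ids",
        )
    if mode == "unseen":
        seen: dict[str, int] = {}
        for (p, c), f in assignment.fold_of_pair.items():
            if c in seen and seen[c] != f:
                offenders.append(c)
            seen.setdefault(c, f)
        offenders = sorted(set(offenders))
        return LeakageReport(
            passed=not offenders,
            mode=mode,
            offending_entities=offenders,
            detail="compounds shared between folds" if offenders else "",
        )
    if mode == "hard":
        for i in range(assignment.k):
            test = assignment.test_pairs(i)
            train = assignment.train_pairs(i)
            shared_p = test.proteins & train.proteins
            shared_c = test.compounds & train.compounds
            offenders += sorted(shared_p) + sorted(shared_c)
        return LeakageReport(
            passed=not offenders,
            mode=mode,
            offending_entities=offenders,
            detail="entities shared between train and test" if offenders else "",
        )
    raise ValueError(f"unknown mode {mode!r}")
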