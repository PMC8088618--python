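"""Self-contained synthetic benchmarks with planted multi-modal signal.

The generator emulates the statistical structure the prediction method
assumes, so every pipeline stage is testable without external databases:

* proteins and compounds each belong to hidden *network communities*;
  their interaction networks are stochastic block models (edge probability
  ``p_in`` within a community, ``p_out`` between), written as link tables
  with confidence-channel scores chosen so that the stated thresholds
  retain exactly the planted edges (plus sub-threshold decoy rows);
* each entity also has a *molecular community*: protein sequences carry a
  community motif with probability ``motif_insert_prob``, and compound
  fingerprints are noisy copies of a community template bit pattern.  A
  configurable ``decouple_fraction`` of entities is assigned a molecular
  community independent of its network community, so neither modality
  alone carries the full label signal;
* a hidden K x L compatibility matrix C with +/-1 entries defines the
  interaction propensity; a pair (i, j) is labelled interacting with
  probability sigmoid(alpha * C[net_i, net_j] + beta * C[mol_i, mol_j] +
  bias), where the bias is solved by bisection to hit the target positive
  rate.

Toy SMILES are drawn from a fixed list of simple valid structures so that
fingerprint I/O paths can be exercised with a real chemistry toolkit; they
are deliberately not chemically meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .interactome import (
    InteractionNetwork,
    LabeledPairSet,
    write_compound_table,
    write_fasta,
    write_links,
)
from .protein_features import ALPHABET

__all__ = ["SyntheticConfig", "Benchmark", "GroundTruth",
           "generate_benchmark", "ground_truth", "write_benchmark"]

# simple, valid, structurally varied toy molecules
TEMPLATE_SMILES = [
    "CCO", "CCCO", "CCN", "CC(C)O", "CCCC", "CC(C)C", "CCOC", "CCC=O",
    "c1ccccc1", "Cc1ccccc1", "c1ccncc1", "c1ccoc1", "CC(=O)O", "CC(=O)N",
    "C1CCCCC1", "C1CCNCC1", "OCC(O)CO", "NCCO", "CSC", "CC#N",
]

PPI_CHANNEL, PPI_THRESHOLD = "experimental", 150
CCI_CHANNEL, CCI_THRESHOLD = "similarity", 150
PC_CHANNEL, PC_THRESHOLD = "experimental", 700


@dataclass
class SyntheticConfig:
    n_proteins: int = 100
    n_compounds: int = 100
    k_protein_communities: int = 4
    l_compound_communities: int = 4
    p_in: float = 0.3
    p_out: float = 0.02
    motif_length: int = 8
    motif_insert_prob: float = 0.9
    seq_length: tuple[int, int] = (40, 80)
    alpha: float = 2.5  # network signal weight
    beta: float = 2.5  # molecular signal weight
    positive_rate: float = 1 / 3
    decouple_fraction: float = 0.5
    n_pairs: int | None = None  # default 6 * max(n_proteins, n_compounds)
    fingerprint_bits: int = 256
    fingerprint_flip_prob: float = 0.05
    decoy_fraction: float = 0.15  # sub-threshold rows added to link tables
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if self.k_protein_communities > self.n_proteins:
            raise ValueError("more protein communities than proteins")
        if self.l_compound_communities > self.n_compounds:
            raise ValueError("more compound communities than compounds")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if not 0 < self.positive_rate < 1:
            raise ValueError(
                f"positive_rate {self.positive_rate} infeasible; "
                "must be strictly between 0 and 1"
            )


@dataclass
class GroundTruth:
    """Hidden generator state exposed for diagnostics."""

    protein_network_community: np.ndarray
    protein_molecular_community: np.ndarray
    compound_network_community: np.ndarray
    compound_molecular_community: np.ndarray
    compatibility: np.ndarray  # K x L, +/- 1
    bias: float
    motifs: list[str]


@dataclass
class Benchmark:
    config: SyntheticConfig
    sequences: dict[str, str]
    smiles: dict[str, str]
    fingerprints: dict[str, np.ndarray]
    ppi: InteractionNetwork
    cci: InteractionNetwork
    ppi_rows: list[tuple[str, str, int]] = field(repr=False, default_factory=list)
    cci_rows: list[tuple[str, str, int]] = field(repr=False, default_factory=list)
    pc_rows: list[tuple[str, str, int]] = field(repr=False, default_factory=list)
    pairs: LabeledPairSet | None = None
    truth: GroundTruth | None = None


def _sbm_network(
    ids: list[str],
    communities: np.ndarray,
    p_in: float,
    p_out: float,
    threshold: int,
    decoy_fraction: float,
    rng: np.random.Generator,
) -> tuple[InteractionNetwork, list[tuple[str, str, int]]]:
    """Stochastic-block-model network plus link-table rows (edges scored at
    or above the threshold, decoys strictly below)."""
    net = InteractionNetwork()
    for e in ids:
        net.add_node(e)
    rows: list[tuple[str, str, int]] = []
    n = len(ids)
    non_edges: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            p = p_in if communities[i] == communities[j] else p_out
            if rng.random() < p:
                score = int(rng.integers(threshold, 1001))
                net.add_edge(ids[i], ids[j], weight=score / 1000.0)
                rows.append((ids[i], ids[j], score))
            else:
                non_edges.append((i, j))
    n_decoys = int(decoy_fraction * len(rows))
    if n_decoys and non_edges:
        pick = rng.choice(len(non_edges), size=min(n_decoys, len(non_edges)),
                          replace=False)
        for k in pick:
            i, j = non_edges[k]
            rows.append((ids[i], ids[j], int(rng.integers(0, threshold))))
    rng.shuffle(rows)
    return net, rows


def _random_sequence(length: int, rng: np.random.Generator) -> list[str]:
    return [ALPHABET[i] for i in rng.integers(0, len(ALPHABET), size=length)]


def _solve_bias(logits: np.ndarray, target: float) -> float:
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = (lo + hi) / 2
        rate = float(np.mean(1.0 / (1.0 + np.exp(-(logits + mid)))))
        if rate < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def generate_benchmark(cfg: SyntheticConfig) -> Benchmark:
    """Generate networks, sequences, compounds and labelled pairs."""
    rng = np.random.default_rng(cfg.seed)
    K, L = cfg.k_protein_communities, cfg.l_compound_communities
    prot_ids = [f"P{i:04d}" for i in range(cfg.n_proteins)]
    comp_ids = [f"C{i:04d}" for i in range(cfg.n_compounds)]

    p_net = rng.integers(0, K, size=cfg.n_proteins)
    c_net = rng.integers(0, L, size=cfg.n_compounds)
    # molecular community = network community, partially decoupled
    p_mol = p_net.copy()
    decouple_p = rng.random(cfg.n_proteins) < cfg.decouple_fraction
    p_mol[decouple_p] = rng.integers(0, K, size=int(decouple_p.sum()))
    c_mol = c_net.copy()
    decouple_c = rng.random(cfg.n_compounds) < cfg.decouple_fraction
    c_mol[decouple_c] = rng.integers(0, L, size=int(decouple_c.sum()))

    # networks
    ppi, ppi_rows = _sbm_network(
        prot_ids, p_net, cfg.p_in, cfg.p_out, PPI_THRESHOLD,
        cfg.decoy_fraction, rng,
    )
    cci, cci_rows = _sbm_network(
        comp_ids, c_net, cfg.p_in, cfg.p_out, CCI_THRESHOLD,
        cfg.decoy_fraction, rng,
    )

    # sequences with community motifs
    motifs = [
        "".join(_random_sequence(cfg.motif_length, rng)) for _ in range(K)
    ]
    lo, hi = cfg.seq_length
    sequences: dict[str, str] = {}
    for i, pid in enumerate(prot_ids):
        length = int(rng.integers(lo, hi + 1))
        seq = _random_sequence(length, rng)
        if rng.random() < cfg.motif_insert_prob:
            motif = motifs[p_mol[i]]
            start = int(rng.integers(0, length - cfg.motif_length + 1))
            seq[start : start + cfg.motif_length] = list(motif)
        sequences[pid] = "".join(seq)

    # compound fingerprints from community templates, plus toy SMILES
    templates = (rng.random((L, cfg.fingerprint_bits)) < 0.3).astype(np.uint8)
    fingerprints: dict[str, np.ndarray] = {}
    smiles: dict[str, str] = {}
    for j, cid in enumerate(comp_ids):
        fp = templates[c_mol[j]].copy()
        flips = rng.random(cfg.fingerprint_bits) < cfg.fingerprint_flip_prob
        fp[flips] ^= 1
        fingerprints[cid] = fp
        smiles[cid] = TEMPLATE_SMILES[
            (int(c_mol[j]) * 7 + j) % len(TEMPLATE_SMILES)
        ]

    # labels from the hidden compatibility matrix
    compat = rng.choice([-1.0, 1.0], size=(K, L))
    n_pairs = cfg.n_pairs or 6 * max(cfg.n_proteins, cfg.n_compounds)
    universe = cfg.n_proteins * cfg.n_compounds
    n_pairs = min(n_pairs, universe)
    flat = rng.choice(universe, size=n_pairs, replace=False)
    pi, cj = flat // cfg.n_compounds, flat % cfg.n_compounds
    logits = (
        cfg.alpha * compat[p_net[pi], c_net[cj]]
        + cfg.beta * compat[p_mol[pi], c_mol[cj]]
    )
    bias = _solve_bias(logits, cfg.positive_rate)
    probs = 1.0 / (1.0 + np.exp(-(logits + bias)))
    labels = (rng.random(n_pairs) < probs).astype(int)
    pairs = LabeledPairSet.from_records(
        (prot_ids[i], comp_ids[j], int(y))
        for i, j, y in zip(pi, cj, labels)
    )

    # protein-chemical link rows: positives scored >= 700, decoys below
    pc_rows: list[tuple[str, str, int]] = []
    for i, j, y in zip(pi, cj, labels):
        if y == 1:
            pc_rows.append(
                (prot_ids[i], comp_ids[j], int(rng.integers(PC_THRESHOLD, 1001)))
            )
        elif rng.random() < cfg.decoy_fraction:
            pc_rows.append(
                (prot_ids[i], comp_ids[j], int(rng.integers(0, 150)))
            )
    rng.shuffle(pc_rows)

    truth = GroundTruth(
        protein_network_community=p_net,
        protein_molecular_community=p_mol,
        compound_network_community=c_net,
        compound_molecular_community=c_mol,
        compatibility=compat,
        bias=bias,
        motifs=motifs,
    )
    return Benchmark(
        config=cfg,
        sequences=sequences,
        smiles=smiles,
        fingerprints=fingerprints,
        ppi=ppi,
        cci=cci,
        ppi_rows=ppi_rows,
        cci_rows=cci_rows,
        pc_rows=pc_rows,
        pairs=pairs,
        truth=truth,
    )


def ground_truth(benchmark: Benchmark) -> GroundTruth:
    """Hidden community assignments and compatibility matrix."""
    if benchmark.truth is None:
        raise ValueError("benchmark carries no ground truth")
    return benchmark.truth


def write_benchmark(benchmark: Benchmark, outdir: str | Path) -> None:
    """Emit the benchmark in the link-table / FASTA / TSV dialects consumed
    by the readers, plus a manifest with the generating configuration."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "sequences.fasta", benchmark.sequences)
    write_compound_table(outdir / "compounds.tsv", benchmark.smiles)
    write_links(outdir / "ppi_links.txt", benchmark.ppi_rows, PPI_CHANNEL,
                ("protein1", "protein2"))
    write_links(outdir / "cci_links.txt", benchmark.cci_rows, CCI_CHANNEL,
                ("chemical1", "chemical2"))
    write_links(outdir / "pc_links.txt", benchmark.pc_rows, PC_CHANNEL,
                ("protein", "chemical"))
    if benchmark.pairs is not None:
        benchmark.pairs.to_tsv(outdir / "pairs.tsv")
    with open(outdir / "fingerprints.tsv", "w") as fh:
        fh.write("compound_id\tbits\n")
        for cid, fp in benchmark.fingerprints.items():
            fh.write(cid + "\t" + "".join(map(str, fp.tolist())) + "\n")
    cfg = asdict(benchmark.config)
    cfg["seq_length"] = list(cfg["seq_length"])
    (outdir / "manifest.json").write_text(
        json.dumps({"config": cfg, "channels": {
            "ppi": [PPI_CHANNEL, PPI_THRESHOLD],
            "cci": [CCI_CHANNEL, CCI_THRESHOLD],
            "pc": [PC_CHANNEL, PC_THRESHOLD],
        }}, indent=2)
    )


def read_fingerprints(path: str | Path) -> dict[str, np.ndarray]:
    """Read the fingerprint table written by :func:`write_benchmark`."""
    out: dict[str, np.ndarray] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            cid, bits = line.split()
            out[cid] = np.array([int(b) for b in bits], dtype=np.uint8)
    return out
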