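"""node2vec feature learning on interaction networks.

Second-order biased random walks (return parameter ``p``, in-out parameter
``q``, edge-weight-proportional transitions) feed a skip-gram model trained
with negative sampling.  With ``p = q = 1`` the walks reduce to weighted
first-order random walks.  Defaults follow the standard node2vec setting:
128 dimensions, walk length 80, 10 walks per node, p = q = 1, weighted
transitions.

The skip-gram trainer is mini-batched stochastic gradient descent over
(center, context) pairs from the walks with a fixed context window,
negative samples drawn from the unigram^0.75 node distribution, and a
linearly decaying learning rate; seeded and single-threaded, so the
embedding is reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .interactome import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "WalkConfig",
    "EmbeddingTable",
    "generate_walks",
    "embed_network",
    "cosine",
]


@dataclass
class WalkConfig:
    dimensions: int = 128
    walk_length: int = 80
    num_walks: int = 10
    p: float = 1.0
    q: float = 1.0
    use_weights: bool = True
    window: int = 10
    negative_samples: int = 5
    epochs: int = 5
    learning_rate: float = 0.025
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self):
        if self.walk_length < 1 or self.num_walks < 1:
            raise ValueError("walk_length and num_walks must be >= 1")
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be > 0")


class EmbeddingTable:
    """Entity ID -> d-dimensional embedding vector."""

    def __init__(self, ids: list[str], matrix: np.ndarray):
        if len(ids) != matrix.shape[0]:
            raise ValueError("ids and matrix rows differ")
        self.ids = list(ids)
        self.matrix = np.asarray(matrix, dtype=float)
        self._index = {e: i for i, e in enumerate(self.ids)}

    @property
    def dimension(self) -> int:
        return self.matrix.shape[1]

    def __contains__(self, entity: str) -> bool:
        return entity in self._index

    def __len__(self) -> int:
        return len(self.ids)

    def vector(self, entity: str) -> np.ndarray:
        return self.matrix[self._index[entity]]

    def __getitem__(self, entity: str) -> np.ndarray:
        return self.vector(entity)

    # word2vec text format: "count dim" header then "id v1 ... vd" rows
    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)} {self.dimension}\n")
            for e, row in zip(self.ids, self.matrix):
                fh.write(e + " " + " ".join(f"{v:.6g}" for v in row) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingTable":
        with open(path) as fh:
            n, d = map(int, fh.readline().split())
            ids, rows = [], []
            for line in fh:
                parts = line.split()
                ids.append(parts[0])
                rows.append([float(v) for v in parts[1 : d + 1]])
        if len(ids) != n:
            raise ValueError(f"{path}: header claims {n} rows, found {len(ids)}")
        return cls(ids, np.array(rows))


def _neighbor_arrays(net: InteractionNetwork, use_weights: bool
                     ) -> tuple[list[str], dict[str, tuple[list[str], np.ndarray]]]:
    nodes = sorted(net.nodes)
    nbrs: dict[str, tuple[list[str], np.ndarray]] = {}
    for node in nodes:
        neigh = sorted(net.neighbors(node))
        if neigh:
            w = (
                np.array([net.weight(node, v) for v in neigh])
                if use_weights
                else np.ones(len(neigh))
            )
        else:
            w = np.empty(0)
        nbrs[node] = (neigh, w)
    return nodes, nbrs


def generate_walks(net: InteractionNetwork, cfg: WalkConfig
                   ) -> list[list[str]]:
    """num_walks biased random walks starting from every node.

    Transition bias for stepping from ``cur`` (having come from ``prev``)
    to neighbour ``x``: edge weight times 1/p if x == prev, 1 if x is also
    a neighbour of prev, and 1/q otherwise.  A walk stops early at a node
    with no neighbours; isolated nodes yield length-1 walks.
    """
    if len(net) == 0:
        raise ValueError("network is empty")
    rng = np.random.default_rng(cfg.seed)
    nodes, nbrs = _neighbor_arrays(net, cfg.use_weights)
    walks: list[list[str]] = []
    for _ in range(cfg.num_walks):
        start_order = list(nodes)
        rng.shuffle(start_order)
        for start in start_order:
            walk = [start]
            while len(walk) < cfg.walk_length:
                cur = walk[-1]
                neigh, w = nbrs[cur]
                if not neigh:
                    break
                if len(walk) == 1 or (cfg.p == 1.0 and cfg.q == 1.0):
                    probs = w / w.sum()
                else:
                    prev = walk[-2]
                    prev_neigh = set(nbrs[prev][0])
                    bias = np.array(
                        [
                            1.0 / cfg.p
                            if x == prev
                            else (1.0 if x in prev_neigh else 1.0 / cfg.q)
                            for x in neigh
                        ]
                    )
                    probs = w * bias
                    probs = probs / probs.sum()
                walk.append(neigh[rng.choice(len(neigh), p=probs)])
            walks.append(walk)
    return walks


def _skipgram_train(
    walks_idx: list[np.ndarray],
    n_nodes: int,
    cfg: WalkConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    d = cfg.dimensions
    W_in = (rng.random((n_nodes, d)) - 0.5) / d
    W_out = np.zeros((n_nodes, d))

    # unigram^0.75 negative-sampling distribution
    counts = np.zeros(n_nodes)
    for walk in walks_idx:
        np.add.at(counts, walk, 1)
    noise = counts**0.75
    noise /= noise.sum()

    # all (center, context) pairs with a fixed window
    centers, contexts = [], []
    for walk in walks_idx:
        L = len(walk)
        for i in range(L):
            lo, hi = max(0, i - cfg.window), min(L, i + cfg.window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(walk[i])
                    contexts.append(walk[j])
    if not centers:
        return W_in
    centers = np.array(centers)
    contexts = np.array(contexts)

    n_pairs = len(centers)
    total_batches = max(1, -(-n_pairs // cfg.batch_size)) * cfg.epochs
    batch_no = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(n_pairs)
        for s in range(0, n_pairs, cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            lr = cfg.learning_rate * max(
                1e-4 / cfg.learning_rate, 1.0 - batch_no / total_batches
            )
            batch_no += 1
            c, o = centers[idx], contexts[idx]
            neg = rng.choice(
                n_nodes, size=(len(idx), cfg.negative_samples), p=noise
            )
            vc = W_in[c]  # (B, d)
            targets = np.concatenate([o[:, None], neg], axis=1)  # (B, 1+k)
            vt = W_out[targets]  # (B, 1+k, d)
            score = np.einsum("bd,bkd->bk", vc, vt)
            sig = 1.0 / (1.0 + np.exp(-np.clip(score, -30, 30)))
            label = np.zeros_like(sig)
            label[:, 0] = 1.0
            err = sig - label  # (B, 1+k)
            dvc = np.einsum("bk,bkd->bd", err, vt)
            dvt = err[:, :, None] * vc[:, None, :]
            # per-row mean of colliding gradients keeps the update magnitude
            # of per-pair SGD regardless of batch size
            g_in = np.zeros_like(W_in)
            np.add.at(g_in, c, dvc)
            cnt_in = np.bincount(c, minlength=n_nodes)
            rows = cnt_in > 0
            W_in[rows] -= lr * g_in[rows] / cnt_in[rows, None]
            g_out = np.zeros_like(W_out)
            tflat = targets.ravel()
            np.add.at(g_out, tflat, dvt.reshape(-1, d))
            cnt_out = np.bincount(tflat, minlength=n_nodes)
            rows = cnt_out > 0
            W_out[rows] -= lr * g_out[rows] / cnt_out[rows, None]
    return W_in


def embed_network(net: InteractionNetwork, cfg: WalkConfig | None = None
                  ) -> EmbeddingTable:
    """Learn a d-dimensional embedding for every node of the network."""
    cfg = cfg or WalkConfig()
    walks = generate_walks(net, cfg)
    nodes = sorted(net.nodes)
    index = {e: i for i, e in enumerate(nodes)}
    walks_idx = [np.array([index[v] for v in walk]) for walk in walks]
    rng = np.random.default_rng(cfg.seed + 1)
    W = _skipgram_train(walks_idx, len(nodes), cfg, rng)
    return EmbeddingTable(nodes, W)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity u.v / (|u||v|); errors on zero vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("dimension mismatch")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine undefined for zero vectors")
    return float(np.dot(u, v) / (nu * nv))
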