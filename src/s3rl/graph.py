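"""Signed graph construction: spatial kNN plus semantic positive/negative edges.

The spatial kNN graph encodes local context (neighboring spots tend to share
a domain).  It is augmented with *signed* semantic edges: for each spot, a
positive edge to its most similar spot(s) and a negative edge to its least
similar spot(s), computed separately from visual features and from
expression profiles.  Positives merge with the spatial edges into E′ (used
for message passing and attraction); negatives form E− (used for repulsion),
after removing any pair that already carries positive evidence.

All edge sets are undirected, stored as sets of (i, j) tuples with i < j,
and all rankings break ties toward the lowest node index, so construction is
bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SignedGraph",
    "build_spatial_knn",
    "extract_signed_edges",
    "merge_graphs",
    "build_signed_graph",
    "write_edges",
    "read_edges",
]

EdgeSet = set  # of (i, j) tuples, i < j


def _canon(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


@dataclass
class SignedGraph:
    n_nodes: int
    E_spatial: EdgeSet = field(default_factory=set)
    Ep_pos: EdgeSet = field(default_factory=set)
    Ep_neg: EdgeSet = field(default_factory=set)
    Eg_pos: EdgeSet = field(default_factory=set)
    Eg_neg: EdgeSet = field(default_factory=set)
    E_prime: EdgeSet = field(default_factory=set)
    E_minus: EdgeSet = field(default_factory=set)

    def __post_init__(self):
        for name in ("E_spatial", "Ep_pos", "Ep_neg", "Eg_pos", "Eg_neg",
                     "E_prime", "E_minus"):
            edges = getattr(self, name)
            if any(i == j for i, j in edges):
                raise ValueError(f"self-loop in {name}")
            if any(not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes)
                   for i, j in edges):
                raise ValueError(f"node index out of range in {name}")

    def directed_pairs(self, which: str = "E_prime") -> np.ndarray:
        """Both orientations of each undirected edge, as an (2|E|, 2) array
        of (src, dst) rows — the message-passing form."""
        edges = sorted(getattr(self, which))
        if not edges:
            return np.empty((0, 2), dtype=np.intp)
        e = np.asarray(edges, dtype=np.intp)
        return np.concatenate([e, e[:, ::-1]], axis=0)

    def edge_array(self, which: str) -> np.ndarray:
        edges = sorted(getattr(self, which))
        return np.asarray(edges, dtype=np.intp).reshape(-1, 2)


def build_spatial_knn(S: np.ndarray, k: int = 6) -> EdgeSet:
    """Undirected kNN edges under Euclidean distance, union-symmetrized.

    k = 6 by default, matching the hexagonal packing of Visium spots.
    Distance ties break toward the lower node index.
    """
    S = np.asarray(S, dtype=np.float64)
    n = S.shape[0]
    if k <= 0 or k >= n:
        raise ValueError(f"k must satisfy 0 < k < n_spots (got k={k}, n={n})")
    d2 = ((S[:, None, :] - S[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")  # stable ⇒ lowest index on ties
    edges: EdgeSet = set()
    for i in range(n):
        for j in order[i, :k]:
            edges.add(_canon(i, int(j)))
    return edges


def _similarity_matrix(F: np.ndarray, metric: str) -> np.ndarray:
    F = np.asarray(F, dtype=np.float64)
    if metric == "pearson":
        F = F - F.mean(axis=1, keepdims=True)
    elif metric != "cosine":
        raise ValueError(f"unknown similarity metric: {metric!r}")
    norms = np.linalg.norm(F, axis=1)
    zero = norms == 0
    if zero.any():
        logger.warning("%d zero-norm feature rows; their similarities are 0",
                       int(zero.sum()))
    safe = np.where(zero, 1.0, norms)
    Fn = F / safe[:, None]
    sim = Fn @ Fn.T
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    return sim


def extract_signed_edges(F: np.ndarray, n_pos: int = 1, n_neg: int = 1,
                         metric: str = "cosine") -> tuple[EdgeSet, EdgeSet]:
    """Per-spot top-``n_pos`` / bottom-``n_neg`` similarity edges.

    For each spot the ``n_neg`` least similar spots are drawn from candidates
    not already selected as that spot's positives, so the per-spot choices
    are disjoint; cross-spot conflicts are resolved later in
    :func:`merge_graphs`.  Both sets are union-symmetrized.
    """
    F = np.asarray(F, dtype=np.float64)
    n = F.shape[0]
    if n_pos + n_neg >= n:
        raise ValueError("n_pos + n_neg must be < n_spots")
    sim = _similarity_matrix(F, metric)
    np.fill_diagonal(sim, np.nan)
    pos: EdgeSet = set()
    neg: EdgeSet = set()
    for i in range(n):
        others = np.flatnonzero(~np.isnan(sim[i]))
        desc = others[np.argsort(-sim[i, others], kind="stable")]
        top = desc[:n_pos]
        for j in top:
            pos.add(_canon(i, int(j)))
        asc = others[np.argsort(sim[i, others], kind="stable")]
        taken = set(int(j) for j in top)
        picked = 0
        for j in asc:
            if int(j) in taken:
                continue
            neg.add(_canon(i, int(j)))
            picked += 1
            if picked == n_neg:
                break
    return pos, neg


def merge_graphs(E_spatial: EdgeSet, Ep_pos: EdgeSet = frozenset(),
                 Ep_neg: EdgeSet = frozenset(), Eg_pos: EdgeSet = frozenset(),
                 Eg_neg: EdgeSet = frozenset(), n_nodes: int | None = None) -> SignedGraph:
    """Combine edge sets into the final signed graph.

    E′ = E_spatial ∪ Ep⁺ ∪ Eg⁺.  E− = (Ep⁻ ∪ Eg⁻) \\ E′: a pair with any
    positive evidence is dropped from the negative set, because the
    topological loss would otherwise both attract and repel it.
    """
    E_spatial, Ep_pos, Ep_neg = set(E_spatial), set(Ep_pos), set(Ep_neg)
    Eg_pos, Eg_neg = set(Eg_pos), set(Eg_neg)
    if n_nodes is None:
        all_edges = E_spatial | Ep_pos | Ep_neg | Eg_pos | Eg_neg
        n_nodes = 1 + max((max(i, j) for i, j in all_edges), default=-1)
    E_prime = E_spatial | Ep_pos | Eg_pos
    raw_neg = Ep_neg | Eg_neg
    E_minus = raw_neg - E_prime
    dropped = len(raw_neg) - len(E_minus)
    if dropped:
        logger.info("dropped %d negative pairs that carry positive evidence", dropped)
    return SignedGraph(n_nodes=n_nodes, E_spatial=E_spatial, Ep_pos=Ep_pos,
                       Ep_neg=Ep_neg, Eg_pos=Eg_pos, Eg_neg=Eg_neg,
                       E_prime=E_prime, E_minus=E_minus)


def build_signed_graph(S: np.ndarray, expression: np.ndarray | None = None,
                       visual: np.ndarray | None = None, k: int = 6,
                       n_pos: int = 1, n_neg: int = 1,
                       visual_n_pos: int | None = None,
                       visual_n_neg: int | None = None,
                       metric: str = "cosine") -> SignedGraph:
    """Full construction: spatial kNN plus signed edges from each available
    modality.  Passing ``visual=None`` reproduces the no-histology ablation
    (E′ = E_spatial ∪ Eg⁺ exactly).

    ``visual_n_pos``/``visual_n_neg`` override the per-spot edge counts for
    the visual modality only (default: same as ``n_pos``/``n_neg``).  The
    override exists because histology similarity is typically a far cleaner
    domain signal than expression similarity, so a denser visual edge set
    can be justified where a denser expression one would add noise.
    """
    E_spatial = build_spatial_knn(S, k=k)
    Ep_pos: EdgeSet = set()
    Ep_neg: EdgeSet = set()
    Eg_pos: EdgeSet = set()
    Eg_neg: EdgeSet = set()
    if visual is not None:
        Ep_pos, Ep_neg = extract_signed_edges(
            visual,
            n_pos if visual_n_pos is None else visual_n_pos,
            n_neg if visual_n_neg is None else visual_n_neg, metric)
    if expression is not None:
        Eg_pos, Eg_neg = extract_signed_edges(expression, n_pos, n_neg, metric)
    return merge_graphs(E_spatial, Ep_pos, Ep_neg, Eg_pos, Eg_neg,
                        n_nodes=np.asarray(S).shape[0])


def write_edges(graph: SignedGraph, path) -> None:
    """Serialize all primitive edge sets as TSV (node_i, node_j, sign, source)."""
    rows = []
    for name, sign, source in [("E_spatial", "+", "spatial"),
                               ("Ep_pos", "+", "visual"), ("Ep_neg", "-", "visual"),
                               ("Eg_pos", "+", "expression"), ("Eg_neg", "-", "expression")]:
        for i, j in sorted(getattr(graph, name)):
            rows.append((i, j, sign, source))
    df = pd.DataFrame(rows, columns=["node_i", "node_j", "sign", "source"])
    df.to_csv(path, sep="\t", index=False)


def read_edges(path, n_nodes: int) -> SignedGraph:
    df = pd.read_csv(Path(path), sep="\t")
    sets = {"E_spatial": set(), "Ep_pos": set(), "Ep_neg": set(),
            "Eg_pos": set(), "Eg_neg": set()}
    key = {("+", "spatial"): "E_spatial", ("+", "visual"): "Ep_pos",
           ("-", "visual"): "Ep_neg", ("+", "expression"): "Eg_pos",
           ("-", "expression"): "Eg_neg"}
    for _, r in df.iterrows():
        sets[key[(r["sign"], r["source"])]].add(_canon(int(r["node_i"]), int(r["node_j"])))
    return merge_graphs(n_nodes=n_nodes, **sets)
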