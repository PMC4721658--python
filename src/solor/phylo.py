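"""Promoter conservation: Tamura-Nei distances, neighbor-joining, ranking.

A promoter allele panel's overall variability is summarised as the mean
pairwise Tamura-Nei (TN93) distance over its multi-alignment; genes are
then ranked from most varied to most conserved.  TN93 distinguishes the two
transition classes (A<->G within purines, C<->T within pyrimidines) from
transversions and allows unequal base frequencies:

    d = -k1 ln w1 - k2 ln w2 - k3 ln w3
    k1 = 2 pA pG / pR          w1 = 1 - P1/k1 - Q/(2 pR)
    k2 = 2 pC pT / pY          w2 = 1 - P2/k2 - Q/(2 pY)
    k3 = 2 (pR pY - pA pG pY/pR - pC pT pR/pY)
                               w3 = 1 - Q/(2 pR pY)

with P1, P2 the two transition proportions, Q the transversion proportion,
and pR = pA+pG, pY = pC+pT.  Columns holding a gap or N in either row are
excluded pairwise; base frequencies are averaged over the pair by default
(``freq_mode="alignment"`` uses the whole alignment instead).

Neighbor joining follows the Saitou-Nei agglomeration with deterministic
lexicographic tie-breaking; negative branch lengths are retained but
flagged, as is conventional for distance trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Tn93Result",
    "DistanceMatrix",
    "PhyloTree",
    "ConservationScore",
    "SaturatedPairError",
    "tn93_distance",
    "build_distance_matrix",
    "neighbor_joining",
    "mean_pairwise_distance",
    "rank_by_conservation",
]

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


class SaturatedPairError(ValueError):
    """TN93 log argument fell to zero or below (distance undefined)."""


@dataclass
class Tn93Result:
    distance: float
    P1: float
    P2: float
    Q: float
    base_freqs: np.ndarray
    sites_used: int


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray
    flagged: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


# ---------------------------------------------------------------------------
# TN93
# ---------------------------------------------------------------------------

def _pair_counts(a: str, b: str) -> tuple[np.ndarray, int, int, int, int]:
    """Base-pair tallies over pairwise-complete columns.

    Returns (per-sequence-pair base counts (2,4), transitions AG, CT,
    transversions, sites)."""
    counts = np.zeros((2, 4))
    ag = ct = tv = used = 0
    for x, y in zip(a.upper(), b.upper()):
        i = _BASE_IDX.get(x)
        j = _BASE_IDX.get(y)
        if i is None or j is None:
            continue
        used += 1
        counts[0, i] += 1
        counts[1, j] += 1
        if i != j:
            pair = {x, y}
            if pair == {"A", "G"}:
                ag += 1
            elif pair == {"C", "T"}:
                ct += 1
            else:
                tv += 1
    return counts, ag, ct, tv, used


def _tn93_closed_form(
    P1: float, P2: float, Q: float, freqs: np.ndarray
) -> tuple[float, float, float, float]:
    """Evaluate the TN93 closed form; returns (d, w1, w2, w3)."""
    pA, pC, pG, pT = freqs
    pR, pY = pA + pG, pC + pT
    if pR <= 0 or pY <= 0:
        raise SaturatedPairError("purine or pyrimidine frequency is zero")
    k1 = 2 * pA * pG / pR
    k2 = 2 * pC * pT / pY
    k3 = 2 * (pR * pY - pA * pG * pY / pR - pC * pT * pR / pY)
    w3 = 1 - Q / (2 * pR * pY)

    def _term(k: float, P: float, w: float | None) -> float:
        if k == 0:
            if P > 0:
                raise SaturatedPairError(
                    "transition observed in a base class with zero frequency"
                )
            return 0.0
        if w is None or w <= 0:
            raise SaturatedPairError("log argument <= 0 (pair saturated)")
        return -k * math.log(w)

    w1 = None if k1 == 0 else 1 - P1 / k1 - Q / (2 * pR)
    w2 = None if k2 == 0 else 1 - P2 / k2 - Q / (2 * pY)
    d = _term(k1, P1, w1) + _term(k2, P2, w2)
    if k3 != 0:
        if w3 <= 0:
            raise SaturatedPairError("log argument <= 0 (pair saturated)")
        d += -k3 * math.log(w3)
    elif Q > 0:
        raise SaturatedPairError("transversion observed with k3 = 0")
    return d, (w1 or 1.0), (w2 or 1.0), w3


def tn93_distance(
    a: str,
    b: str,
    freq_mode: str = "pair",
    alignment_freqs: np.ndarray | None = None,
) -> Tn93Result:
    """TN93 distance between two rows of one alignment (pairwise deletion).

    ``freq_mode="pair"`` (default) averages base frequencies over the two
    rows; ``"alignment"`` uses ``alignment_freqs`` supplied by the caller.
    Raises :class:`SaturatedPairError` when the distance is undefined and
    ``ValueError`` when no comparable site remains.
    """
    if len(a) != len(b):
        raise ValueError("rows must come from one alignment (equal length)")
    counts, ag, ct, tv, used = _pair_counts(a, b)
    if used == 0:
        raise ValueError("no pairwise-complete columns")
    P1, P2, Q = ag / used, ct / used, tv / used
    if freq_mode == "pair":
        freqs = counts.sum(axis=0) / counts.sum()
    elif freq_mode == "alignment":
        if alignment_freqs is None:
            raise ValueError("alignment_freqs required for freq_mode='alignment'")
        freqs = np.asarray(alignment_freqs, float)
    else:
        raise ValueError(f"unknown freq_mode {freq_mode!r}")
    if P1 == P2 == Q == 0:
        return Tn93Result(0.0, 0.0, 0.0, 0.0, freqs, used)
    d, *_ = _tn93_closed_form(P1, P2, Q, freqs)
    return Tn93Result(d, P1, P2, Q, freqs, used)


def build_distance_matrix(
    rows: Mapping[str, str], freq_mode: str = "pair"
) -> DistanceMatrix:
    """All-pairs TN93 matrix from aligned rows (id -> gapped string).

    Pairs whose distance is undefined are flagged; downstream operations
    reject flagged matrices.
    """
    ids = list(rows)
    if len(ids) < 3:
        raise ValueError("need at least 3 rows")
    afreqs = None
    if freq_mode == "alignment":
        counts = np.zeros(4)
        for s in rows.values():
            for c in s.upper():
                i = _BASE_IDX.get(c)
                if i is not None:
                    counts[i] += 1
        afreqs = counts / counts.sum()
    n = len(ids)
    vals = np.zeros((n, n))
    flagged: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            try:
                r = tn93_distance(rows[ids[i]], rows[ids[j]], freq_mode, afreqs)
                vals[i, j] = vals[j, i] = r.distance
            except SaturatedPairError:
                vals[i, j] = vals[j, i] = np.nan
                flagged.add((ids[i], ids[j]))
    return DistanceMatrix(ids, np.nan_to_num(vals), flagged)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """Unrooted NJ tree as an edge list plus leaf set.

    ``edges`` maps frozenset({u, v}) -> branch length; internal nodes are
    synthetic string ids.  ``joins`` records the agglomeration order (used
    as a progressive-alignment guide)."""

    leaves: list[str]
    edges: dict[frozenset, float]
    joins: list[tuple[str, str, str]]
    newick: str
    has_negative_branches: bool

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the unique a-b path."""
        adj: dict[str, list[tuple[str, float]]] = {}
        for e, w in self.edges.items():
            u, v = tuple(e)
            adj.setdefault(u, []).append((v, w))
            adj.setdefault(v, []).append((u, w))
        stack = [(a, None, 0.0)]
        while stack:
            node, parent, acc = stack.pop()
            if node == b:
                return acc
            for nxt, w in adj.get(node, ()):
                if nxt != parent:
                    stack.append((nxt, node, acc + w))
        raise ValueError(f"no path between {a} and {b}")


def neighbor_joining(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties on the Q criterion are broken by the lexicographically smallest id
    pair.  For three taxa the unique unrooted topology with
    ``v_i = (d_ij + d_ik - d_jk) / 2`` is returned.
    """
    if matrix.flagged:
        raise ValueError("matrix contains flagged (undefined) entries")
    ids = list(matrix.ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 taxa")
    D: dict[tuple[str, str], float] = {}
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            D[(a, b)] = float(matrix.values[i, j])

    active = sorted(ids)
    edges: dict[frozenset, float] = {}
    joins: list[tuple[str, str, str]] = []
    children: dict[str, tuple[str, str]] = {}
    counter = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(D[(a, b)] for b in active if b != a) for a in active}
        best = None
        for ia in range(n):
            for ib in range(ia + 1, n):
                a, b = active[ia], active[ib]
                q = (n - 2) * D[(a, b)] - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        new = f"_nj{counter}"
        counter += 1
        d_ab = D[(a, b)]
        va = 0.5 * d_ab + (r[a] - r[b]) / (2 * (n - 2))
        vb = d_ab - va
        edges[frozenset((a, new))] = va
        edges[frozenset((b, new))] = vb
        children[new] = (a, b)
        joins.append((a, b, new))
        for c in active:
            if c in (a, b):
                continue
            d = 0.5 * (D[(a, c)] + D[(b, c)] - d_ab)
            D[(new, c)] = D[(c, new)] = d
        D[(new, new)] = 0.0
        active = sorted([c for c in active if c not in (a, b)] + [new])

    a, b, c = active
    va = 0.5 * (D[(a, b)] + D[(a, c)] - D[(b, c)])
    vb = 0.5 * (D[(a, b)] + D[(b, c)] - D[(a, c)])
    vc = 0.5 * (D[(a, c)] + D[(b, c)] - D[(a, b)])
    hub = f"_nj{counter}"
    edges[frozenset((a, hub))] = va
    edges[frozenset((b, hub))] = vb
    edges[frozenset((c, hub))] = vc
    children[hub] = (a, b, c)  # type: ignore[assignment]
    joins.append((a, b, hub))
    joins.append((hub, c, hub))

    def _newick(node: str, parent_edge: float | None) -> str:
        if node not in children:
            label = node
        else:
            subs = ",".join(
                _newick(ch, edges[frozenset((ch, node))]) for ch in children[node]
            )
            label = f"({subs})"
        if parent_edge is None:
            return label
        return f"{label}:{parent_edge:.6f}"

    newick = _newick(hub, None) + ";"
    return PhyloTree(
        leaves=ids,
        edges=edges,
        joins=joins,
        newick=newick,
        has_negative_branches=any(w < 0 for w in edges.values()),
    )


# ---------------------------------------------------------------------------
# Conservation score and ranking
# ---------------------------------------------------------------------------

@dataclass
class ConservationScore:
    gene_id: str
    mean_pairwise_distance: float
    n_pairs: int


def mean_pairwise_distance(
    matrix: DistanceMatrix, gene_id: str = ""
) -> ConservationScore:
    """Arithmetic mean of the strict upper triangle of the matrix."""
    if matrix.flagged:
        raise ValueError("matrix contains flagged (undefined) entries")
    n = len(matrix.ids)
    iu = np.triu_indices(n, k=1)
    vals = matrix.values[iu]
    return ConservationScore(gene_id, float(vals.mean()), len(vals))


def rank_by_conservation(
    scores: Sequence[ConservationScore],
) -> list[ConservationScore]:
    """Stable sort, most varied (largest mean distance) first; ties broken
    by gene_id."""
    if not scores:
        raise ValueError("no scores to rank")
    return sorted(
        scores, key=lambda s: (-s.mean_pairwise_distance, s.gene_id)
    )
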