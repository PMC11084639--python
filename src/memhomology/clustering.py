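"""Family clustering: bit-score distances with Ward linkage, and
structure-space clustering from TM-score distances.

The sequence-space tree is built from a self-normalised bit-score distance,

    d(i, j) = 1 - b(i, j) / min(b(i, i), b(j, j)),   clipped to [0, 1],

clustered with the Ward minimum-variance criterion; the agglomerative
coefficient AC = mean over leaves of (1 - h_first / h_final) summarises how
strongly clustered the data are (AC near 1: tight clusters).  The
structure-space distance is d = (1 - TM-score)^2, so a TM-score of 0.8
corresponds to d = 0.04, and clusters are read off an average-linkage tree
cut at that threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core_io import ValidationError
from .pairwise import ScoringScheme, bitscore_evalue, get_scheme, sw_score


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        n = len(self.labels)
        if m.shape != (n, n):
            raise ValidationError("matrix shape does not match label count")
        if not np.all(np.isfinite(m)):
            raise ValidationError("distances must be finite")
        if np.any(m < 0):
            raise ValidationError("distances must be non-negative")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValidationError("matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValidationError("diagonal must be zero")


@dataclass(frozen=True)
class Dendrogram:
    """Merge tree: entry k merges nodes (a, b) at the given height.

    Node ids follow the usual convention: leaves are 0..n-1, the cluster
    created by merge k is node n+k.
    """

    merges: tuple[tuple[int, int, float], ...]
    labels: tuple[str, ...]
    method: str
    agglomerative_coefficient: float

    def leaf_sets(self) -> dict[int, frozenset]:
        n = len(self.labels)
        sets = {i: frozenset([self.labels[i]]) for i in range(n)}
        for k, (a, b, _) in enumerate(self.merges):
            sets[n + k] = sets[a] | sets[b]
        return sets

    def cut(self, n_clusters: int) -> list[frozenset]:
        """Leaf-label sets obtained by undoing the last merges."""
        n = len(self.labels)
        if not (1 <= n_clusters <= n):
            raise ValidationError("bad cluster count")
        active = set(range(n))
        sets = self.leaf_sets()
        for k, (a, b, _) in enumerate(self.merges):
            if len(active) <= n_clusters:
                break
            active -= {a, b}
            active.add(n + k)
        return [sets[i] for i in sorted(active)]


def bitscore_distance_matrix(seqs, scheme: ScoringScheme | None = None
                             ) -> tuple[DistanceMatrix, np.ndarray]:
    """Pairwise self-normalised bit-score distances.

    Returns the distance matrix and the raw symmetric bit-score matrix
    (exported so alternative transforms can be explored).
    """
    seqs = list(seqs)
    if len(seqs) < 3:
        raise ValidationError("need at least 3 sequences to cluster")
    scheme = scheme or get_scheme()
    n = len(seqs)
    labels = tuple(getattr(s, "id", f"seq{i}") for i, s in enumerate(seqs))
    bits = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            raw = sw_score(seqs[i], seqs[j], scheme)
            if raw <= 0:  # nothing aligned: bit score floored to 0, d -> 1
                continue
            li = len(seqs[i].residues if hasattr(seqs[i], "residues") else seqs[i])
            lj = len(seqs[j].residues if hasattr(seqs[j], "residues") else seqs[j])
            b, _ = bitscore_evalue(raw, li, lj, scheme)
            bits[i, j] = bits[j, i] = b
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(bits[i, i], bits[j, j])
            val = 1.0 - bits[i, j] / denom if denom > 0 else 1.0
            d[i, j] = d[j, i] = float(np.clip(val, 0.0, 1.0))
    return DistanceMatrix(labels, d), bits


def _agglomerative_coefficient(merges, n: int) -> float:
    """AC = mean over leaves of (1 - first-merge height / final height)."""
    h_final = merges[-1][2]
    if h_final <= 0:
        return 0.0
    h_first = {}
    member_leaves = {i: [i] for i in range(n)}
    for k, (a, b, h) in enumerate(merges):
        for node in (a, b):
            for leaf in member_leaves[node]:
                if leaf not in h_first:
                    h_first[leaf] = h
        member_leaves[n + k] = member_leaves[a] + member_leaves[b]
    # a leaf's first merge is the first merge of any node containing it
    return float(np.mean([1.0 - h_first[i] / h_final for i in range(n)]))


def ward_tree(dm: DistanceMatrix) -> Dendrogram:
    """Ward minimum-variance hierarchical clustering via Lance–Williams.

    The update treats the input distances as Euclidean:

        d(s+t, w) = sqrt(((n_s+n_w) d(s,w)^2 + (n_t+n_w) d(t,w)^2
                          - n_w d(s,t)^2) / (n_s+n_t+n_w))

    Heights are the merge distances; ties break on the smallest node ids.
    """
    n = len(dm.labels)
    d = {(i, j): dm.matrix[i, j] for i in range(n) for j in range(i + 1, n)}
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    merges: list[tuple[int, int, float]] = []
    next_id = n

    def dist(a: int, b: int) -> float:
        return d[(a, b) if a < b else (b, a)]

    while len(active) > 1:
        best = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a, b = active[ii], active[jj]
                val = dist(a, b)
                if best is None or val < best[0] - 1e-15:
                    best = (val, a, b)
        h, s, t = best
        u = next_id
        next_id += 1
        ns, nt = sizes[s], sizes[t]
        for w in active:
            if w in (s, t):
                continue
            nw = sizes[w]
            val = np.sqrt(
                ((ns + nw) * dist(s, w) ** 2 + (nt + nw) * dist(t, w) ** 2
                 - nw * h ** 2) / (ns + nt + nw)
            )
            d[(w, u) if w < u else (u, w)] = float(val)
        sizes[u] = ns + nt
        active = [x for x in active if x not in (s, t)] + [u]
        merges.append((s, t, float(h)))

    ac = _agglomerative_coefficient(merges, n)
    return Dendrogram(tuple(merges), dm.labels, "ward", ac)


def structure_distance(tm_score: float) -> float:
    """The TM-score distance transform d = (1 - TM-score)^2."""
    if not (0.0 <= tm_score <= 1.0):
        raise ValidationError("TM-score must lie in [0, 1]")
    return (1.0 - tm_score) ** 2


def average_linkage_clusters(dm: DistanceMatrix, cut: float) -> list[frozenset]:
    """Average-linkage tree cut at a distance threshold.

    With ``cut = structure_distance(0.8) = 0.04`` this groups structure
    pairs of TM-score >= 0.8, the convention used for structure-space
    cluster assignment.
    """
    if cut < 0:
        raise ValidationError("cut must be non-negative")
    Z = hierarchy.linkage(squareform(dm.matrix, checks=False), method="average")
    assign = hierarchy.fcluster(Z, t=cut, criterion="distance")
    clusters: dict[int, set] = {}
    for label, c in zip(dm.labels, assign):
        clusters.setdefault(int(c), set()).add(label)
    return [frozenset(v) for _, v in sorted(clusters.items())]
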