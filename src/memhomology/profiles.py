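"""Family-level comparison through per-column frequency profiles.

Two families are compared by aligning frequency profiles built from their
MSAs with a log-odds column score, and the resulting score is made
interpretable by the same topology-preserving shuffle/GEV machinery used at
the sequence level: the subject MSA's columns are permuted within their
consensus-topology segments, the query profile is re-aligned against each
decoy, and the observed score is referred to the fitted GEV.

The column score between profile columns f1 and f2 is

    s(c1, c2) = log2 sum_a f1(a) * f2(a) / bg(a)          [bits]

with affine gap costs in bits.  This frequency-profile score is a
self-contained stand-in for HMM-HMM comparison scores; the statistic that
carries the inference weight is the shuffle-null GEV p-value, not the raw
score convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .composition import BACKGROUND_VECTOR
from .core_io import AA20, Topology, ValidationError, spawn_rng
from .shuffle_gev import (
    GEVFit,
    ShuffleNullResult,
    fit_gev,
    gev_pvalue,
    msa_column_permutation,
)

logger = logging.getLogger("memhomology")

DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_GAP_OPEN_BITS = 2.5
DEFAULT_GAP_EXTEND_BITS = 0.5
GAP_FLAG_FRACTION = 0.3

_AA_INDEX = {a: i for i, a in enumerate(AA20)}


@dataclass(frozen=True)
class Profile:
    """Per-column residue frequencies of an aligned family."""

    freqs: np.ndarray          # (ncol, 20), rows sum to 1
    gap_fraction: np.ndarray   # (ncol,)
    flagged: np.ndarray        # (ncol,) bool: gap fraction > 0.3
    topology: Topology         # consensus segment labels on columns
    msa_id: str = ""

    @property
    def ncol(self) -> int:
        return self.freqs.shape[0]

    def subset(self, columns: np.ndarray) -> "Profile":
        """A positional subset (used to restrict to membrane columns)."""
        kinds = _column_kinds(self.topology, self.ncol)[columns]
        return Profile(self.freqs[columns], self.gap_fraction[columns],
                       self.flagged[columns], _topology_from_kinds(kinds),
                       self.msa_id)


def _column_kinds(topology: Topology, ncol: int) -> np.ndarray:
    kinds = np.array(["LOOP"] * ncol, dtype=object)
    for seg in topology.segments:
        kinds[seg.start:seg.end] = seg.kind
    return kinds


def _topology_from_kinds(kinds: np.ndarray) -> Topology:
    from .core_io import Segment

    segs, start = [], 0
    for i in range(1, len(kinds) + 1):
        if i == len(kinds) or kinds[i] != kinds[start]:
            segs.append(Segment(start, i, str(kinds[start])))
            start = i
    return Topology(tuple(segs))


def build_profile(rows, topology: Topology, pseudocount_weight: float = DEFAULT_PSEUDOCOUNT,
                  msa_id: str = "") -> Profile:
    """Column frequencies with background pseudocounts.

    freq(a) = (count(a) + w * bg(a)) / (n_nongap + w); 'X' and gaps carry no
    count.  Columns with more than 30% gaps are flagged (they are excluded
    from family comparison, mirroring the usual poorly-aligned-column
    trimming).
    """
    rows = list(rows)
    if not rows:
        raise ValidationError("empty MSA")
    ncol = len(rows[0].residues)
    if any(len(r.residues) != ncol for r in rows):
        raise ValidationError("MSA rows have unequal lengths")
    if len(rows) < 5:
        logger.warning("profile built from only %d rows; frequencies will be noisy", len(rows))
    counts = np.zeros((ncol, 20))
    gaps = np.zeros(ncol)
    for row in rows:
        for j, c in enumerate(row.residues):
            if c == "-":
                gaps[j] += 1
            elif c != "X":
                counts[j, _AA_INDEX[c]] += 1
    n_eff = counts.sum(axis=1, keepdims=True)
    freqs = (counts + pseudocount_weight * BACKGROUND_VECTOR) / (n_eff + pseudocount_weight)
    gap_fraction = gaps / len(rows)
    return Profile(freqs, gap_fraction, gap_fraction > GAP_FLAG_FRACTION,
                   topology, msa_id)


# ---------------------------------------------------------------------------
# Seed-gap injection
# ---------------------------------------------------------------------------

def _seed_row(rows, seed_id: str):
    for i, r in enumerate(rows):
        if r.id == seed_id:
            return i, r
    raise ValidationError(f"seed sequence {seed_id!r} not found in MSA")


def _residue_columns(row) -> list[int]:
    return [j for j, c in enumerate(row.residues) if c != "-"]


def _insert_all_gap_columns(rows, at: int, width: int):
    out = []
    for r in rows:
        s = r.residues
        out.append(type(r)(r.id, s[:at] + "-" * width + s[at:], r.description))
    return out


def inject_seed_gaps(msaA, msaB, seed_aln):
    """Project a pairwise seed alignment's gapping into two family MSAs.

    Wherever the seed pair's Smith–Waterman alignment skips k residues of
    one seed (a k-column gap on the other side), k all-gap columns are
    inserted into the other family's MSA at the corresponding column, so the
    two MSAs acquire compatible column geometries over the seed-aligned
    region.  The seed sequences must be rows of their MSAs.
    """
    msaA, msaB = list(msaA), list(msaB)
    _, rowA = _seed_row(msaA, seed_aln.query_id)
    _, rowB = _seed_row(msaB, seed_aln.subject_id)
    colsA = _residue_columns(rowA)
    colsB = _residue_columns(rowB)

    # Walk the aligned pairs; a jump of k on one side inserts k columns on the
    # other.  Insertions are collected first (positions refer to the original
    # column frames) and applied right-to-left so indices stay valid.
    ins_a: list[tuple[int, int]] = []  # (column in msaA, width)
    ins_b: list[tuple[int, int]] = []
    pairs = seed_aln.pairs
    for (q0, s0), (q1, s1) in zip(pairs, pairs[1:]):
        dq, ds = q1 - q0, s1 - s0
        if ds > 1:  # subject residues skipped: gap columns into msaA
            ins_a.append((colsA[q0] + 1, ds - 1))
        if dq > 1:
            ins_b.append((colsB[s0] + 1, dq - 1))
    for at, width in sorted(ins_a, reverse=True):
        msaA = _insert_all_gap_columns(msaA, at, width)
    for at, width in sorted(ins_b, reverse=True):
        msaB = _insert_all_gap_columns(msaB, at, width)
    return msaA, msaB


# ---------------------------------------------------------------------------
# Profile-profile alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileAlignment:
    """A local profile-profile alignment in bits."""

    pairs: tuple[tuple[int, int], ...]
    score: float
    column_scores: tuple[float, ...]


def column_score_matrix(p1: Profile, p2: Profile) -> np.ndarray:
    """Log-odds column scores between all column pairs of two profiles.

    Disjoint zero-pseudocount columns would give log2(0); they are floored
    far below any reachable alignment score instead.
    """
    ratio2 = p2.freqs / BACKGROUND_VECTOR
    return np.log2(np.maximum(p1.freqs @ ratio2.T, 1e-300))


def _sw_score_matrix(S: np.ndarray, gap_open: float, gap_extend: float) -> float:
    """Score-only local DP over a precomputed column-score matrix.

    Vectorized over anti-diagonals (the affine-gap recurrences couple only
    adjacent diagonals), which keeps the decoy re-alignments of the shuffle
    null fast without any compiled extension.
    """
    n, m = S.shape
    NEG = -1e30
    H1 = np.zeros(n + 1)   # diagonal k-1
    H2 = np.zeros(n + 1)   # diagonal k-2
    E1 = np.full(n + 1, NEG)
    F1 = np.full(n + 1, NEG)
    best = 0.0
    for k in range(2, n + m + 1):
        lo = max(1, k - m)
        hi = min(n, k - 1)
        if lo > hi:
            continue
        i = np.arange(lo, hi + 1)
        j = k - i
        E = np.maximum(H1[i] - gap_open, E1[i] - gap_extend)
        F = np.maximum(H1[i - 1] - gap_open, F1[i - 1] - gap_extend)
        H = np.maximum.reduce([
            np.zeros(len(i)),
            H2[i - 1] + S[i - 1, j - 1],
            E,
            F,
        ])
        best = max(best, float(H.max()))
        H2, H1 = H1, np.zeros(n + 1)
        E1 = np.full(n + 1, NEG)
        F1 = np.full(n + 1, NEG)
        H1[i] = H
        E1[i] = E
        F1[i] = F
    return best


def _sw_traceback(S: np.ndarray, gap_open: float, gap_extend: float):
    """Full local DP with traceback (used once per observed comparison)."""
    n, m = S.shape
    NEG = -1e30
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    for i in range(1, n + 1):
        Si = S[i - 1]
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            H[i, j] = max(0.0, H[i - 1, j - 1] + Si[j - 1], E[i, j], F[i, j])
    best = float(H.max())
    if best <= 0.0:
        return (), 0.0, ()
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    pairs: list[tuple[int, int]] = []
    col_scores: list[float] = []
    state = "H"
    while H[i, j] > 0.0 if state == "H" else True:
        if state == "H":
            if H[i, j] == H[i - 1, j - 1] + S[i - 1, j - 1]:
                pairs.append((i - 1, j - 1))
                col_scores.append(float(S[i - 1, j - 1]))
                i, j = i - 1, j - 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            if E[i, j] == H[i, j - 1] - gap_open:
                state = "H"
            j -= 1
        else:
            if F[i, j] == H[i - 1, j] - gap_open:
                state = "H"
            i -= 1
        if i == 0 or j == 0:
            break
    pairs.reverse()
    col_scores.reverse()
    return tuple(pairs), best, tuple(col_scores)


def profile_profile_align(p1: Profile, p2: Profile,
                          gap_open: float = DEFAULT_GAP_OPEN_BITS,
                          gap_extend: float = DEFAULT_GAP_EXTEND_BITS) -> ProfileAlignment:
    """Optimal local alignment between two profiles (scores in bits)."""
    if p1.ncol == 0 or p2.ncol == 0:
        raise ValidationError("cannot align an empty profile")
    S = column_score_matrix(p1, p2)
    pairs, score, col_scores = _sw_traceback(S, gap_open, gap_extend)
    return ProfileAlignment(pairs, score, col_scores)


# ---------------------------------------------------------------------------
# Family comparison with the shuffled-MSA null
# ---------------------------------------------------------------------------

def _included_columns(profile: Profile, include_loops: bool) -> np.ndarray:
    kinds = _column_kinds(profile.topology, profile.ncol)
    keep = ~profile.flagged
    if not include_loops:
        keep &= (kinds == "TMS") | (kinds == "RL")
    return np.nonzero(keep)[0]


def family_compare(msaA, msaB, topoA: Topology, topoB: Topology,
                   n_shuffles: int = 10_000, seed: int = 0,
                   pseudocount_weight: float = DEFAULT_PSEUDOCOUNT,
                   gap_open: float = DEFAULT_GAP_OPEN_BITS,
                   gap_extend: float = DEFAULT_GAP_EXTEND_BITS,
                   include_loops: bool = False) -> ShuffleNullResult:
    """Profile-compare two family MSAs with a shuffled-subject-MSA null.

    The observed score is the local profile-profile alignment score between
    the two family profiles (membrane-region columns by default).  Decoys
    permute the subject MSA's columns within their consensus segments; since
    a column permutation permutes profile columns, each decoy re-alignment
    reuses the precomputed column-score matrix.
    """
    if n_shuffles < 100:
        raise ValidationError("at least 100 shuffles are required")
    pA = build_profile(msaA, topoA, pseudocount_weight, msa_id="A")
    pB = build_profile(msaB, topoB, pseudocount_weight, msa_id="B")
    incA = _included_columns(pA, include_loops)
    kindsB = _column_kinds(pB.topology, pB.ncol)
    posB = np.arange(pB.ncol)
    if not include_loops:
        posB = posB[(kindsB == "TMS") | (kindsB == "RL")]

    def subject_columns(perm: np.ndarray) -> np.ndarray:
        # Gap flags travel with the permuted columns, so the decoy's usable
        # column set is the permuted image of the kind filter minus flagged.
        cols = perm[posB]
        return cols[~pB.flagged[cols]]

    incB = subject_columns(np.arange(pB.ncol))
    if len(incA) == 0 or len(incB) == 0:
        raise ValidationError("no comparable columns after filtering")
    S = column_score_matrix(pA, pB)
    observed = _sw_score_matrix(S[np.ix_(incA, incB)], gap_open, gap_extend)
    rng = spawn_rng(seed, "family-compare")
    null = np.empty(n_shuffles)
    for t in range(n_shuffles):
        perm = msa_column_permutation(topoB, pB.ncol, rng)
        null[t] = _sw_score_matrix(S[np.ix_(incA, subject_columns(perm))], gap_open, gap_extend)
    fit = fit_gev(null)
    return ShuffleNullResult(observed, fit, n_shuffles, gev_pvalue(observed, fit), seed)
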