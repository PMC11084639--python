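"""Smith–Waterman local alignment, Karlin–Altschul statistics, coverage
filters, redundancy reduction and transitivity paths.

The aligner is Biopython's C ``PairwiseAligner`` in local mode with affine
gaps (a gap of length k costs ``open + (k-1)*extend``).  Raw scores are
converted to bit scores and pairwise E-values with the Karlin–Altschul
formulae; E-values use the two sequences' lengths (m*n), not a database
size, so every decision in the pipeline is self-contained.

Homology between families that show no direct similarity is assembled from
chains of pairwise links (if A~B, B~C and C~D overlap sufficiently on the
shared proteins, A and D are inferred homologous): see
:func:`assemble_transitive_path`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .core_io import AnnotatedSequence, SequenceRecord, Topology, ValidationError


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus gap penalties and Karlin–Altschul parameters.

    The default is BLOSUM62 with gap open 11 / extend 1 and the standard
    gapped parameters lambda = 0.267, K = 0.041.  A BLOSUM50 10/2 preset
    (the SSEARCH default matrix) is available via :func:`get_scheme`;
    its Karlin–Altschul values are approximate gapped estimates.
    """

    name: str = "blosum62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lam: float = 0.267
    k: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValidationError("gap penalties must be positive")
        if self.lam <= 0 or self.k <= 0:
            raise ValidationError("Karlin-Altschul parameters must be positive")

    @property
    def matrix_name(self) -> str:
        return {"blosum62": "BLOSUM62", "blosum50": "BLOSUM50"}[self.name]


_PRESETS = {
    "blosum62": ScoringScheme("blosum62", 11.0, 1.0, 0.267, 0.041),
    # SSEARCH-style preset; lambda/K are approximate gapped estimates.
    "blosum50": ScoringScheme("blosum50", 10.0, 2.0, 0.232, 0.110),
}


def get_scheme(name: str = "blosum62") -> ScoringScheme:
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValidationError(f"unknown scoring scheme {name!r}") from None


@lru_cache(maxsize=8)
def _aligner(name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    matrix = substitution_matrices.load(
        {"blosum62": "BLOSUM62", "blosum50": "BLOSUM50"}[name]
    )
    # 'X' is an unknown residue: score 0 against everything.
    if "X" in matrix.alphabet:
        xi = matrix.alphabet.index("X")
        for j in range(len(matrix.alphabet)):
            matrix[xi, j] = 0.0
            matrix[j, xi] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def aligner_for(scheme: ScoringScheme) -> Align.PairwiseAligner:
    return _aligner(scheme.name, scheme.gap_open, scheme.gap_extend)


@dataclass(frozen=True)
class LocalAlignment:
    """A scored local alignment with its aligned-column mapping.

    ``pairs`` lists residue-residue columns as (query, subject) positions,
    strictly increasing on both sides; gap columns are the jumps between
    consecutive pairs.  ``empty`` flags the degenerate all-negative case
    (raw score 0, nothing aligned).
    """

    query_id: str
    subject_id: str
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    pairs: tuple[tuple[int, int], ...]
    raw: float
    bits: float
    evalue: float
    identity_pct: float
    coverage: float
    empty: bool = False

    def junction_interval(self, protein_id: str) -> tuple[int, int]:
        if protein_id == self.query_id:
            return self.query_interval
        if protein_id == self.subject_id:
            return self.subject_interval
        raise KeyError(f"{protein_id} is not part of this alignment")


def bitscore_evalue(raw: float, m: int, n: int, scheme: ScoringScheme) -> tuple[float, float]:
    """Karlin–Altschul statistics for a raw local-alignment score.

    bits = (lambda*raw - ln K) / ln 2, floored at 0 (a negative bit score is
    reported as 0); E = K * m * n * exp(-lambda*raw) with m, n the two
    sequence lengths.
    """
    if raw < 0:
        raise ValidationError("raw score must be non-negative")
    bits = (scheme.lam * raw - math.log(scheme.k)) / math.log(2.0)
    evalue = scheme.k * m * n * math.exp(-scheme.lam * raw)
    return max(bits, 0.0), evalue


def _residues(seq) -> str:
    return seq if isinstance(seq, str) else seq.residues


def sw_score(a, b, scheme: ScoringScheme | None = None) -> float:
    """Raw Smith–Waterman score only (the fast path for shuffle nulls)."""
    scheme = scheme or get_scheme()
    return float(aligner_for(scheme).score(_residues(a), _residues(b)))


def smith_waterman(a, b, scheme: ScoringScheme | None = None) -> LocalAlignment:
    """Optimal local alignment of two sequences under affine gap costs.

    Accepts :class:`SequenceRecord`, :class:`AnnotatedSequence` or plain
    strings.  If every cell of the DP matrix is non-positive the result is an
    empty alignment flagged with raw score 0.
    """
    scheme = scheme or get_scheme()
    sa, sb = _residues(a), _residues(b)
    if not sa or not sb:
        raise ValidationError("cannot align an empty sequence")
    qid = getattr(a, "id", "query")
    sid = getattr(b, "id", "subject")
    aligner = aligner_for(scheme)
    score = float(aligner.score(sa, sb))
    if score <= 0.0:
        bits, evalue = bitscore_evalue(0.0, len(sa), len(sb), scheme)
        return LocalAlignment(qid, sid, (0, 0), (0, 0), (), 0.0, bits, evalue,
                              0.0, 0.0, empty=True)
    alignment = next(iter(aligner.align(sa, sb)))
    pairs: list[tuple[int, int]] = []
    for (qs, qe), (ss, se) in zip(*alignment.aligned):
        pairs.extend((qs + i, ss + i) for i in range(qe - qs))
    q0, q1 = pairs[0][0], pairs[-1][0] + 1
    s0, s1 = pairs[0][1], pairs[-1][1] + 1
    matches = sum(1 for qp, sp in pairs if sa[qp] == sb[sp])
    columns = len(pairs) + ((q1 - q0) - len(pairs)) + ((s1 - s0) - len(pairs))
    identity = 100.0 * matches / columns
    shorter = min(len(sa), len(sb))
    span = (q1 - q0) if len(sa) <= len(sb) else (s1 - s0)
    coverage = span / shorter
    bits, evalue = bitscore_evalue(score, len(sa), len(sb), scheme)
    return LocalAlignment(qid, sid, (q0, q1), (s0, s1), tuple(pairs),
                          score, bits, evalue, identity, coverage)


# ---------------------------------------------------------------------------
# Coverage filter
# ---------------------------------------------------------------------------

def tms_coverage_filter(aln: LocalAlignment, topoA: Topology, topoB: Topology,
                        min_tms: int = 3) -> tuple[bool, tuple[int, int]]:
    """Accept an alignment only if it spans enough membrane segments.

    A membrane segment counts as covered when at least 50% of its residues
    fall inside the aligned interval on its own sequence; the alignment is
    accepted when both sides reach ``min_tms`` covered segments.
    """
    def covered(topo: Topology, interval: tuple[int, int]) -> int:
        lo, hi = interval
        count = 0
        for seg in topo.membrane_segments():
            overlap = max(0, min(seg.end, hi) - max(seg.start, lo))
            if overlap >= 0.5 * len(seg):
                count += 1
        return count

    ca = covered(topoA, aln.query_interval)
    cb = covered(topoB, aln.subject_interval)
    return (ca >= min_tms and cb >= min_tms), (ca, cb)


# ---------------------------------------------------------------------------
# Redundancy reduction
# ---------------------------------------------------------------------------

def reduce_redundancy(seqs, identity_threshold: float = 0.9,
                      scheme: ScoringScheme | None = None) -> list:
    """Greedy redundancy reduction by descending length.

    A sequence is dropped when its Smith–Waterman identity to an already
    retained sequence reaches the threshold.  Identity follows the CD-HIT
    convention — identical aligned residues divided by the length of the
    shorter sequence — so a perfect two-residue micro-alignment between
    otherwise unrelated proteins does not count as redundancy.
    """
    if not (0.0 < identity_threshold <= 1.0):
        raise ValidationError("identity threshold must lie in (0, 1]")
    scheme = scheme or get_scheme()
    ordered = sorted(seqs, key=lambda s: len(_residues(s)), reverse=True)
    retained: list = []
    for cand in ordered:
        keep = True
        for ref in retained:
            aln = smith_waterman(cand, ref, scheme)
            if aln.empty:
                continue
            shorter = min(len(_residues(cand)), len(_residues(ref)))
            matches = sum(1 for q, s in aln.pairs
                          if _residues(cand)[q] == _residues(ref)[s])
            if matches / shorter >= identity_threshold:
                keep = False
                break
        if keep:
            retained.append(cand)
    return retained


# ---------------------------------------------------------------------------
# Transitivity paths
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitivityPath:
    """An A -> B -> C -> ... homology chain with per-junction overlaps."""

    protein_ids: tuple[str, ...]
    links: tuple[LocalAlignment, ...]
    junction_overlaps: tuple[int, ...]
    accepted: bool

    @property
    def link_evalues(self) -> tuple[float, ...]:
        return tuple(l.evalue for l in self.links)


def assemble_transitive_path(links, min_junction_overlap: int = 30) -> TransitivityPath:
    """Chain pairwise alignments into a transitivity path.

    Consecutive links must share a protein (link i's subject is link i+1's
    query).  At every shared protein the two alignment intervals must overlap
    by at least ``min_junction_overlap`` residues for the path to be
    accepted; homology of the two chain ends is then inferred by
    transitivity.
    """
    links = tuple(links)
    if len(links) < 2:
        raise ValidationError("a transitivity path needs at least 2 links")
    ids = [links[0].query_id]
    for i, (left, right) in enumerate(zip(links, links[1:])):
        if left.subject_id != right.query_id:
            raise ValidationError(
                f"broken chain at junction {i}: link {i} ends at "
                f"{left.subject_id!r} but link {i + 1} starts at {right.query_id!r}"
            )
        ids.append(left.subject_id)
    ids.append(links[-1].subject_id)

    overlaps = []
    for left, right in zip(links, links[1:]):
        a0, a1 = left.subject_interval
        b0, b1 = right.query_interval
        overlaps.append(max(0, min(a1, b1) - max(a0, b0)))
    accepted = all(ov >= min_junction_overlap for ov in overlaps)
    return TransitivityPath(tuple(ids), links, tuple(overlaps), accepted)
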