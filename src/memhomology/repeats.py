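"""Internal-repeat detection by cutting a family MSA and cross-aligning
the halves.

A tandem-duplicated channel (e.g. a 3-TMS unit repeated into a 3+1+3 or
6-TMS architecture) betrays itself when the MSA is cut inside the loop
following the last membrane segment of the putative first unit and every
sequence's first half is aligned against every sequence's second half:
significant alignments covering the membrane segments of both halves
support the repeat.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_io import (
    GappedRecord,
    Segment,
    SequenceRecord,
    Topology,
    ValidationError,
)
from .pairwise import (
    LocalAlignment,
    ScoringScheme,
    get_scheme,
    smith_waterman,
    tms_coverage_filter,
)

DEFAULT_EVALUE_MAX = 1e-3


@dataclass(frozen=True)
class SplitMSA:
    """The two degapped halves of a cut MSA with per-row topologies."""

    half_a: tuple[SequenceRecord, ...]
    half_b: tuple[SequenceRecord, ...]
    cut_column: int
    topo_a: dict  # row id -> Topology on half-A residue coordinates
    topo_b: dict


@dataclass(frozen=True)
class RepeatHit:
    """One retained cross-half alignment and its support verdict.

    ``gev_p`` is the topology-preserving shuffle-null GEV p-value of the
    cross-half score (None when verification was skipped or the coverage
    rule already failed).
    """

    row_a: str
    row_b: str
    alignment: LocalAlignment
    covered: tuple[int, int]
    supported: bool
    gev_p: float | None = None


def _column_kinds(topology: Topology, ncol: int) -> list[str]:
    kinds = ["LOOP"] * ncol
    for seg in topology.segments:
        for j in range(seg.start, seg.end):
            kinds[j] = seg.kind
    return kinds


def _degap(row, columns, kinds) -> tuple[SequenceRecord | None, Topology]:
    residues, res_kinds = [], []
    for j in columns:
        c = row.residues[j]
        if c != "-":
            residues.append(c)
            res_kinds.append(kinds[j])
    if not residues:
        return None, Topology(())
    segs, start = [], 0
    for i in range(1, len(res_kinds) + 1):
        if i == len(res_kinds) or res_kinds[i] != res_kinds[start]:
            segs.append(Segment(start, i, res_kinds[start]))
            start = i
    return (SequenceRecord(row.id, "".join(residues), row.description),
            Topology(tuple(segs)))


def split_msa_at_loop(msa, consensus_topology: Topology, after_segment: int) -> SplitMSA:
    """Cut an MSA at the midpoint of the loop after a membrane segment.

    ``after_segment`` is the 1-based ordinal of the membrane segment ending
    the first putative repeat unit.  Rows are degapped within each half so
    they can be compared pairwise; each row's topology is projected onto its
    half coordinates from the consensus column labels.
    """
    rows = list(msa)
    if not rows:
        raise ValidationError("empty MSA")
    ncol = len(rows[0].residues)
    membrane = consensus_topology.membrane_segments()
    if after_segment < 1 or after_segment > len(membrane):
        raise ValidationError(
            f"after_segment={after_segment} but consensus has {len(membrane)} membrane segments"
        )
    anchor = membrane[after_segment - 1]
    loop = None
    for seg in consensus_topology.segments:
        if seg.kind == "LOOP" and seg.start >= anchor.end:
            loop = seg
            break
    if loop is None:
        if after_segment == len(membrane):
            raise ValidationError("no loop after the designated membrane segment")
        # implicit loop between explicit membrane segments
        nxt = membrane[after_segment]
        if nxt.start <= anchor.end:
            raise ValidationError("no loop after the designated membrane segment")
        loop = Segment(anchor.end, nxt.start, "LOOP")
    cut = (loop.start + loop.end) // 2
    kinds = _column_kinds(consensus_topology, ncol)

    half_a, half_b, topo_a, topo_b = [], [], {}, {}
    for row in rows:
        rec_a, ta = _degap(row, range(0, cut), kinds)
        rec_b, tb = _degap(row, range(cut, ncol), kinds)
        if rec_a is not None:
            half_a.append(rec_a)
            topo_a[row.id] = ta
        if rec_b is not None:
            half_b.append(rec_b)
            topo_b[row.id] = tb
    return SplitMSA(tuple(half_a), tuple(half_b), cut, topo_a, topo_b)


def cross_align_halves(half_a, half_b, scheme: ScoringScheme | None = None,
                       evalue_max: float = DEFAULT_EVALUE_MAX) -> list[LocalAlignment]:
    """All-vs-all local alignments between halves, E-value filtered."""
    if not half_a or not half_b:
        raise ValidationError("both halves must be non-empty")
    scheme = scheme or get_scheme()
    retained = []
    for a in half_a:
        for b in half_b:
            aln = smith_waterman(a, b, scheme)
            if not aln.empty and aln.evalue < evalue_max:
                retained.append(aln)
    return retained


def call_repeat_support(alignments, topo_a: dict, topo_b: dict,
                        min_segments: int = 3,
                        records_a: dict | None = None,
                        records_b: dict | None = None,
                        verify_shuffles: int = 300,
                        gev_p_max: float = 1e-3,
                        seed: int = 0) -> list[RepeatHit]:
    """Flag alignments whose membrane segments are covered on both halves.

    An alignment supports the repeat when at least ``min_segments`` membrane
    segments are >= 50%-covered on both sides (the same residue-coverage
    rule used for the cross-family filters) AND — when half records are
    available and ``verify_shuffles`` > 0 — its score survives the
    topology-preserving shuffle null (GEV p <= ``gev_p_max``).  The
    verification step is essential: compositionally biased hydrophobic
    halves reach nominally significant E-values by chance, which is
    precisely the failure mode the shuffle null exists to catch.
    """
    from .core_io import AnnotatedSequence
    from .shuffle_gev import mpsat_compare

    hits = []
    for aln in alignments:
        ta = topo_a.get(aln.query_id)
        tb = topo_b.get(aln.subject_id)
        if ta is None or tb is None:
            continue
        ok, counts = tms_coverage_filter(aln, ta, tb, min_segments)
        gev_p = None
        if ok and verify_shuffles and records_a is not None and records_b is not None:
            q = AnnotatedSequence(records_a[aln.query_id], ta)
            s = AnnotatedSequence(records_b[aln.subject_id], tb)
            null = mpsat_compare(q, s, verify_shuffles, seed=seed)
            gev_p = null.p_value
            ok = gev_p <= gev_p_max
        hits.append(RepeatHit(aln.query_id, aln.subject_id, aln, counts, ok, gev_p))
    return hits


def find_repeats(msa, consensus_topology: Topology, after_segment: int,
                 scheme: ScoringScheme | None = None,
                 evalue_max: float = DEFAULT_EVALUE_MAX,
                 min_segments: int = 3,
                 verify_shuffles: int = 300,
                 gev_p_max: float = 1e-3,
                 seed: int = 0) -> tuple[SplitMSA, list[RepeatHit]]:
    """The full cut / cross-align / verify procedure; returns all hits."""
    split = split_msa_at_loop(msa, consensus_topology, after_segment)
    alns = cross_align_halves(split.half_a, split.half_b, scheme, evalue_max)
    hits = call_repeat_support(
        alns, split.topo_a, split.topo_b, min_segments,
        records_a={r.id: r for r in split.half_a},
        records_b={r.id: r for r in split.half_b},
        verify_shuffles=verify_shuffles, gev_p_max=gev_p_max, seed=seed,
    )
    return split, hits
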