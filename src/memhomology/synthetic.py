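"""Synthetic membrane-protein families with known ground truth.

Every downstream stage of the pipeline is exercised on families produced
here: ancestors with exact topologies and hydrophobic-biased membrane
composition, families evolved by class-conditional substitution with
loop-only indels, matched-topology non-homolog controls, motif implants,
tandem duplications and fusions, and toy CA-trace structures.

The model is deliberately simple: substitutions hit each site independently
with probability 1 - exp(-divergence) and resample the residue from its
segment-class distribution; indels occur only inside loops (geometric
lengths, mean 3) so the membrane architecture of every member matches the
ancestor's.  Each member records, per residue, the ancestor coordinate it
descends from, which lets :func:`family_msa` emit a ground-truth multiple
alignment without any external aligner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .composition import LOOP_VECTOR, TMS_VECTOR, sample_residues
from .core_io import (
    AnnotatedSequence,
    GappedRecord,
    Segment,
    SequenceRecord,
    StructureChain,
    Topology,
    ValidationError,
    spawn_rng,
)

INDEL_RATE_PER_DIVERGENCE = 0.05  # per loop site, split evenly ins/del
INDEL_MEAN_LENGTH = 3.0


# ---------------------------------------------------------------------------
# Specs and truth records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TopologySpec:
    """An architecture blueprint: ordered (kind, length) segments.

    ``label`` names the membrane-segment grouping ("3+1", "4", "3+1+3", ...).
    """

    segments: tuple[tuple[str, int], ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValidationError("empty topology spec")
        for kind, length in self.segments:
            if kind not in ("TMS", "RL", "LOOP"):
                raise ValidationError(f"unknown segment kind {kind!r}")
            if length < 1:
                raise ValidationError(f"non-positive segment length {length}")
        for (ka, _), (kb, _) in zip(self.segments, self.segments[1:]):
            if (ka == "LOOP") == (kb == "LOOP"):
                raise ValidationError(
                    "spec must alternate membrane segments and loops"
                )

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.segments)

    def to_topology(self) -> Topology:
        segs, pos = [], 0
        for kind, length in self.segments:
            segs.append(Segment(pos, pos + length, kind))
            pos += length
        return Topology(tuple(segs))


def three_plus_one_spec(tms: int = 21, short_loop: int = 15, long_loop: int = 120,
                        nterm: int = 25, cterm: int = 15) -> TopologySpec:
    """The pLIC/GIC-style "3+1" blueprint: three clustered TMSs, a long
    hydrophilic region, then a fourth TMS."""
    return TopologySpec((
        ("LOOP", nterm), ("TMS", tms), ("LOOP", short_loop), ("TMS", tms),
        ("LOOP", short_loop), ("TMS", tms), ("LOOP", long_loop), ("TMS", tms),
        ("LOOP", cterm),
    ), label="3+1")


def four_tight_spec(tms: int = 21, short_loop: int = 15,
                    nterm: int = 25, cterm: int = 15) -> TopologySpec:
    """The VPC-style "4" blueprint: four TMSs with only short connectors."""
    return TopologySpec((
        ("LOOP", nterm), ("TMS", tms), ("LOOP", short_loop), ("TMS", tms),
        ("LOOP", short_loop), ("TMS", tms), ("LOOP", short_loop), ("TMS", tms),
        ("LOOP", cterm),
    ), label="4")


def three_tms_unit_spec(tms: int = 21, short_loop: int = 15,
                        nterm: int = 20, cterm: int = 20) -> TopologySpec:
    """A single 3-TMS channel unit, the building block of tandem repeats."""
    return TopologySpec((
        ("LOOP", nterm), ("TMS", tms), ("LOOP", short_loop), ("TMS", tms),
        ("LOOP", short_loop), ("TMS", tms), ("LOOP", cterm),
    ), label="3")


@dataclass
class FamilyTruth:
    """Ground truth attached to a generated family."""

    family_id: str
    member_ids: tuple[str, ...]
    homologous: dict = field(default_factory=dict)  # (id, id) -> bool
    implants: dict = field(default_factory=dict)    # id -> (start, end)
    duplication_breakpoint: int | None = None
    fusion_breakpoint: int | None = None

    def is_homologous(self, a: str, b: str) -> bool:
        return self.homologous.get((a, b), self.homologous.get((b, a), False))

    def set_homologous(self, a: str, b: str, flag: bool) -> None:
        self.homologous[(a, b)] = flag
        self.homologous[(b, a)] = flag


# ---------------------------------------------------------------------------
# Ancestors and families
# ---------------------------------------------------------------------------

def sample_ancestor(spec: TopologySpec, seed: int, seq_id: str = "anc") -> AnnotatedSequence:
    """Draw an ancestor: membrane segments from the hydrophobic-biased
    distribution, loops from the soluble background; topology exact."""
    rng = spawn_rng(seed, "ancestor")
    parts = []
    for kind, length in spec.segments:
        vec = TMS_VECTOR if kind in ("TMS", "RL") else LOOP_VECTOR
        parts.append(sample_residues(length, vec, rng))
    residues = "".join(parts)
    return AnnotatedSequence(
        SequenceRecord(seq_id, residues, description=f"architecture {spec.label}"),
        spec.to_topology(),
        ancestor_map=tuple(range(len(residues))),
    )


def _class_vector(kind: str) -> np.ndarray:
    return TMS_VECTOR if kind in ("TMS", "RL") else LOOP_VECTOR


def _geometric_length(rng: np.random.Generator) -> int:
    return int(rng.geometric(1.0 / INDEL_MEAN_LENGTH))


def _evolve_once(ancestor: AnnotatedSequence, divergence: float,
                 rng: np.random.Generator, member_id: str) -> AnnotatedSequence:
    p_sub = 1.0 - math.exp(-divergence)
    p_indel = INDEL_RATE_PER_DIVERGENCE * divergence
    topo = ancestor.topology
    anc = ancestor.residues
    out_res: list[str] = []
    out_kind: list[str] = []
    amap: list[int | None] = []

    for seg in topo.segments:
        vec = _class_vector(seg.kind)
        p = seg.start
        while p < seg.end:
            if seg.kind == "LOOP" and rng.random() < p_indel:
                if rng.random() < 0.5:  # insertion before this site
                    ins = _geometric_length(rng)
                    ins_res = sample_residues(ins, vec, rng)
                    out_res.extend(ins_res)
                    out_kind.extend([seg.kind] * ins)
                    amap.extend([None] * ins)
                else:  # deletion: keep at least one residue of the loop
                    dele = min(_geometric_length(rng), seg.end - p - 1)
                    p += dele
                    if p >= seg.end:
                        break
            r = anc[p]
            if rng.random() < p_sub:
                r = sample_residues(1, vec, rng)
            out_res.append(r)
            out_kind.append(seg.kind)
            amap.append(p)
            p += 1

    # Rebuild the topology from the per-residue kinds.
    segs: list[Segment] = []
    start = 0
    for i in range(1, len(out_kind) + 1):
        if i == len(out_kind) or out_kind[i] != out_kind[start]:
            segs.append(Segment(start, i, out_kind[start]))
            start = i
    return AnnotatedSequence(
        SequenceRecord(member_id, "".join(out_res)),
        Topology(tuple(segs)),
        ancestor_map=tuple(amap),
    )


def evolve_family(ancestor: AnnotatedSequence, n: int, divergence: float,
                  seed: int, family_id: str = "fam") -> tuple[list[AnnotatedSequence], FamilyTruth]:
    """Derive ``n`` members independently from the ancestor.

    Substitutions are class-conditional resamples; indels stay inside loops,
    so every member keeps the ancestor's membrane-segment count.
    """
    if n < 1:
        raise ValidationError("family size must be >= 1")
    if divergence < 0:
        raise ValidationError("divergence must be non-negative")
    members = []
    for i in range(n):
        rng = spawn_rng(seed, "evolve", family_id, i)
        members.append(_evolve_once(ancestor, divergence, rng, f"{family_id}_m{i:02d}"))
    truth = FamilyTruth(family_id, tuple(m.id for m in members))
    for a in members:
        for b in members:
            if a.id < b.id:
                truth.set_homologous(a.id, b.id, True)
    return members, truth


def make_nonhomolog_pair(spec: TopologySpec, seed: int,
                         sub_seeds: tuple[int, int] | None = None
                         ) -> tuple[AnnotatedSequence, AnnotatedSequence]:
    """Two independent draws with identical topology and composition model.

    This is the matched-topology negative control: any alignment signal
    between the two can only come from shared composition and architecture,
    never from common ancestry.
    """
    if sub_seeds is None:
        ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x6E686F6D])
        s1, s2 = (int(x) for x in ss.generate_state(2) >> 1)
    else:
        s1, s2 = sub_seeds
    if s1 == s2:
        raise ValidationError("identical sub-seeds would produce identical 'non-homologs'")
    a = sample_ancestor(spec, s1, seq_id=f"nh{seed}_a")
    b = sample_ancestor(spec, s2, seq_id=f"nh{seed}_b")
    return a, b


# ---------------------------------------------------------------------------
# Motif implants
# ---------------------------------------------------------------------------

def implant_motif(family: list[AnnotatedSequence], pwm, segment_index: int,
                  fraction: float, seed: int,
                  truth: FamilyTruth | None = None) -> tuple[list[AnnotatedSequence], FamilyTruth]:
    """Replace the central window of one topology segment by a PWM sample in
    ``round(fraction * n)`` randomly chosen members.

    ``segment_index`` indexes the member's topology segments (0-based), so an
    implant can target a specific TMS or the long loop.  Implant coordinates
    are recorded in the returned truth table.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValidationError("fraction must lie in [0, 1]")
    width = pwm.width
    for m in family:
        seg = m.topology.segments[segment_index]
        if width > len(seg):
            raise ValidationError(
                f"{m.id}: motif width {width} exceeds segment length {len(seg)}"
            )
    rng = spawn_rng(seed, "implant")
    n_implant = round(fraction * len(family))
    chosen = set(rng.choice(len(family), size=n_implant, replace=False).tolist())
    if truth is None:
        truth = FamilyTruth("implant", tuple(m.id for m in family))
    out = []
    for i, m in enumerate(family):
        if i not in chosen:
            out.append(m)
            continue
        seg = m.topology.segments[segment_index]
        start = seg.start + (len(seg) - width) // 2
        sampled = pwm.sample(rng)
        residues = m.residues[:start] + sampled + m.residues[start + width:]
        out.append(AnnotatedSequence(
            SequenceRecord(m.id, residues, m.record.description),
            m.topology,
            ancestor_map=m.ancestor_map,
        ))
        truth.implants[m.id] = (start, start + width)
    return out, truth


# ---------------------------------------------------------------------------
# Tandem repeats, fusions, RL conversions
# ---------------------------------------------------------------------------

def _concat_topologies(topoA: Topology, lenA: int, linker: int, topoB: Topology) -> Topology:
    segs = list(topoA.segments)
    if linker > 0:
        segs.append(Segment(lenA, lenA + linker, "LOOP"))
    for s in topoB.segments:
        segs.append(Segment(s.start + lenA + linker, s.end + lenA + linker, s.kind))
    # merge runs of adjacent LOOP segments created by the concatenation
    merged: list[Segment] = []
    for s in segs:
        if merged and merged[-1].kind == s.kind == "LOOP" and merged[-1].end == s.start:
            merged[-1] = Segment(merged[-1].start, s.end, "LOOP")
        else:
            merged.append(s)
    return Topology(tuple(merged))


def compose_architectures(partA: AnnotatedSequence, partB: AnnotatedSequence | None,
                          mode: str, linker: int = 20, divergence: float = 0.5,
                          seed: int = 0) -> tuple[AnnotatedSequence, int]:
    """Concatenate two parts with a loop linker; returns (protein, breakpoint).

    ``mode='tandem'`` emulates an internal duplication: ``partB`` defaults to
    a fresh evolution of ``partA`` at the given divergence, so the two halves
    are true internal repeats.  ``mode='fusion'`` joins two given proteins
    (e.g. members of two different families).  The breakpoint is the 0-based
    position where the second part begins.
    """
    if mode not in ("tandem", "fusion"):
        raise ValidationError(f"unknown composition mode {mode!r}")
    if mode == "tandem":
        rng = spawn_rng(seed, "tandem-unit")
        partB = _evolve_once(partA, divergence, rng, f"{partA.id}_dup")
    elif partB is None:
        raise ValidationError("fusion mode needs an explicit partB")
    rng = spawn_rng(seed, "linker")
    linker_res = sample_residues(linker, LOOP_VECTOR, rng)
    residues = partA.residues + linker_res + partB.residues
    topo = _concat_topologies(partA.topology, len(partA), linker, partB.topology)
    breakpoint = len(partA) + linker
    rec = SequenceRecord(f"{partA.id}+{partB.id}", residues,
                         description=f"{mode} breakpoint {breakpoint + 1}")
    return AnnotatedSequence(rec, topo), breakpoint


def convert_tms_to_rl(seq: AnnotatedSequence, membrane_index: int) -> AnnotatedSequence:
    """Relabel one membrane segment as a reentrant loop (sequence unchanged).

    Models the evolutionary scenario in which a hydrophobic segment stops
    crossing the membrane but keeps its composition, so sequence-level
    comparisons still see it as a hydrophobic peak.
    """
    membrane = seq.topology.membrane_segments()
    target = membrane[membrane_index]
    segs = tuple(
        Segment(s.start, s.end, "RL") if s == target else s
        for s in seq.topology.segments
    )
    return AnnotatedSequence(seq.record, Topology(segs, source=seq.topology.source),
                             ancestor_map=seq.ancestor_map)


# ---------------------------------------------------------------------------
# Ground-truth MSAs
# ---------------------------------------------------------------------------

def family_msa(members: list[AnnotatedSequence], ancestor_length: int
               ) -> tuple[list[SequenceRecord], list[int | None]]:
    """Build the true MSA of a family from recorded ancestor coordinates.

    Returns aligned rows (gapped records) plus a per-column map to ancestor
    coordinates (None for insertion columns).  Insertions from different
    members are left-justified within their insertion block, the usual MSA
    convention for unalignable regions.
    """
    for m in members:
        if m.ancestor_map is None:
            raise ValidationError(f"{m.id} lacks an ancestor map")
    # per member: residue aligned to each ancestor position + insertion runs
    match: list[dict[int, str]] = []
    inserts: list[dict[int, list[str]]] = []
    for m in members:
        mm: dict[int, str] = {}
        ii: dict[int, list[str]] = {}
        anchor = -1
        for res, pos in zip(m.residues, m.ancestor_map):
            if pos is None:
                ii.setdefault(anchor, []).append(res)
            else:
                mm[pos] = res
                anchor = pos
        match.append(mm)
        inserts.append(ii)

    rows = [[] for _ in members]
    col_anc: list[int | None] = []

    def emit_insert_block(anchor: int) -> None:
        width = max((len(ins.get(anchor, ())) for ins in inserts), default=0)
        for k in range(width):
            for r, ins in zip(rows, inserts):
                run = ins.get(anchor, [])
                r.append(run[k] if k < len(run) else "-")
            col_anc.append(None)

    emit_insert_block(-1)
    for p in range(ancestor_length):
        for r, mm in zip(rows, match):
            r.append(mm.get(p, "-"))
        col_anc.append(p)
        emit_insert_block(p)

    aligned = [
        GappedRecord(m.id, "".join(r), m.record.description)
        for m, r in zip(members, rows)
    ]
    return aligned, col_anc


def msa_consensus_topology(ancestor: AnnotatedSequence,
                           col_anc: list[int | None]) -> Topology:
    """Project the ancestor's topology onto MSA columns.

    Match columns inherit the ancestor's segment kind at their position;
    insertion columns are loops (insertions only ever occur in loops).
    """
    kinds = []
    for pos in col_anc:
        if pos is None:
            kinds.append("LOOP")
        else:
            seg = ancestor.topology.segment_at(pos)
            kinds.append(seg.kind if seg is not None else "LOOP")
    segs: list[Segment] = []
    start = 0
    for i in range(1, len(kinds) + 1):
        if i == len(kinds) or kinds[i] != kinds[start]:
            segs.append(Segment(start, i, kinds[start]))
            start = i
    return Topology(tuple(segs))


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------

_HELIX_RISE = 1.5     # Angstrom per residue along the axis
_HELIX_RADIUS = 2.3   # Angstrom
_HELIX_TURN = 100.0   # degrees per residue
_CA_STEP = 3.8        # Angstrom, canonical CA-CA distance


def _helix_points(n: int, origin: np.ndarray, axis_sign: float, phase: float) -> np.ndarray:
    t = np.arange(n)
    ang = np.deg2rad(_HELIX_TURN * t + phase)
    pts = np.stack([
        _HELIX_RADIUS * np.cos(ang),
        _HELIX_RADIUS * np.sin(ang),
        axis_sign * _HELIX_RISE * t,
    ], axis=1)
    return pts - pts[0] + origin


def make_toy_structure(spec: TopologySpec, rl_shape: str = "helix_loop",
                       seed: int = 0) -> StructureChain:
    """An idealised CA trace realising a topology blueprint.

    TMSs are ideal alpha-helices (rise 1.5 Å, radius 2.3 Å, 100°/residue)
    crossing a notional membrane slab, alternating direction; loops are
    extended traces outside the slab.  Reentrant loops enter and leave on
    the same side, either as a helix + loop hairpin (``helix_loop``) or as
    two sub-helices separated by a 2-residue Gly/Glu turn (``helix_helix``).
    Residue letters are drawn from the segment-class composition models.
    """
    if rl_shape not in ("helix_loop", "helix_helix"):
        raise ValidationError(f"unknown reentrant-loop shape {rl_shape!r}")
    rng = spawn_rng(seed, "toy-structure", rl_shape)
    coords: list[np.ndarray] = []
    labels: list[str] = []
    seq_parts: list[str] = []
    pos = np.zeros(3)
    direction = -1.0  # next membrane crossing goes downward
    lateral = np.array([1.0, 0.0, 0.0])

    def extend(points: np.ndarray, kind: str, letters: str) -> None:
        nonlocal pos
        coords.extend(points)
        labels.extend([kind] * len(points))
        seq_parts.append(letters)
        pos = points[-1]

    first = True
    for kind, length in spec.segments:
        if kind == "TMS":
            start = pos if first else pos + _CA_STEP * np.array([0.0, 0.0, direction])
            pts = _helix_points(length, start, direction, phase=rng.uniform(0, 360))
            extend(pts, "TMS", sample_residues(length, TMS_VECTOR, rng))
            direction *= -1.0
        elif kind == "RL":
            # enter the membrane and come back on the same side
            n_turn = 2
            n_in = (length - n_turn) // 2
            n_out = length - n_turn - n_in
            start = pos + _CA_STEP * np.array([0.0, 0.0, direction])
            if rl_shape == "helix_helix":
                pts_in = _helix_points(n_in, start, direction, phase=rng.uniform(0, 360))
                seq_in = sample_residues(n_in, TMS_VECTOR, rng)
            else:
                pts_in = _helix_points(n_in, start, direction, phase=rng.uniform(0, 360))
                seq_in = sample_residues(n_in, TMS_VECTOR, rng)
            extend(pts_in, "RL", seq_in)
            t1 = pos + _CA_STEP * lateral
            t2 = t1 + _CA_STEP * lateral
            extend(np.stack([t1, t2]), "RL", "GE")
            back = pos + _CA_STEP * np.array([0.0, 0.0, -direction])
            if rl_shape == "helix_helix":
                pts_out = _helix_points(n_out, back, -direction, phase=rng.uniform(0, 360))
            else:  # loop back out: straight diagonal trace
                step = np.array([0.15, 0.0, -direction])
                step = _CA_STEP * step / np.linalg.norm(step)
                pts_out = back + np.arange(n_out)[:, None] * step
            extend(pts_out, "RL", sample_residues(n_out, TMS_VECTOR, rng))
            # direction unchanged: we are back on the side we entered from
        else:  # LOOP: extended trace parallel to the membrane plane
            start = pos if first else pos + _CA_STEP * lateral
            step = _CA_STEP * lateral
            pts = start + np.arange(length)[:, None] * step
            extend(pts, "LOOP", sample_residues(length, LOOP_VECTOR, rng))
        first = False

    arr = np.array(coords) + rng.normal(0.0, 0.03, size=(len(coords), 3))
    return StructureChain(arr, tuple(range(1, len(coords) + 1)),
                          labels=tuple(labels), sequence="".join(seq_parts))
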