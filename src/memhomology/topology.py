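"""Hydropathy profiles, transmembrane-segment calling and architectures.

A membrane protein's architecture is summarised as "+"-joined group sizes of
its membrane segments: four TMSs split 3/1 by a long hydrophilic region is
"3+1" (the pLIC/GIC pattern), four closely spaced TMSs is "4" (VPC), a
tandem-duplicated channel is "3+1+3", and so on.

Reentrant loops are never called from sequence here: they can be as
hydrophobic as true TMSs, so hydropathy cannot distinguish them.  RL labels
come only from annotation (input TSVs or toy structures).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import (
    AnnotatedSequence,
    Segment,
    SequenceRecord,
    Topology,
    ValidationError,
)

#: Kyte–Doolittle hydropathy scale.  'X' is assigned 0 (uninformative).
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}

#: Defaults of the TMS caller.  DEFAULT_THRESHOLD is the hydropathy level a
#: candidate crossing must exceed on average; it sits between the mean
#: Kyte–Doolittle values of the membrane (~1.9) and loop (~-0.3)
#: composition models, placed below the midpoint because missing a genuine
#: crossing costs more than admitting a marginal one (false crossings are
#: additionally suppressed by the placement penalty).
DEFAULT_WINDOW = 19
DEFAULT_THRESHOLD = 0.57
DEFAULT_MIN_LEN = 15
MAX_TMS_LEN = 35
MIN_TMS_GAP = 4  # residues required between consecutive called TMSs
#: Score a candidate crossing must clear before it is worth placing
#: (hydropathy * residues); the entry/exit cost of the two-state decoder.
SEGMENT_PENALTY = 5.0
#: Loops at least this long count as "long hydrophilic regions" when
#: grouping membrane segments into an architecture label.
DEFAULT_LONG_LOOP = 50


@dataclass(frozen=True)
class HydropathyProfile:
    """Per-position smoothed hydropathy values (Kyte–Doolittle units)."""

    values: np.ndarray
    window: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)


def hydropathy_profile(seq: SequenceRecord | str, window: int = DEFAULT_WINDOW) -> HydropathyProfile:
    """Sliding-window mean Kyte–Doolittle hydropathy.

    The window must be odd so each value is centred on a residue.  Positions
    whose window would run off the sequence carry the nearest full-window
    value, so the profile has exactly one value per residue.
    """
    residues = seq if isinstance(seq, str) else seq.residues
    n = len(residues)
    if window % 2 == 0:
        raise ValidationError("window must be odd")
    if window < 7:
        raise ValidationError("window must be at least 7")
    if window > n:
        raise ValidationError(f"window {window} exceeds sequence length {n}")
    raw = np.array([KYTE_DOOLITTLE[c] for c in residues])
    kernel = np.ones(window) / window
    centre = np.convolve(raw, kernel, mode="valid")  # length n - window + 1
    half = window // 2
    values = np.empty(n)
    values[half:n - half] = centre
    values[:half] = centre[0]
    values[n - half:] = centre[-1]
    return HydropathyProfile(values, window)


def predict_tms(
    profile: HydropathyProfile,
    threshold: float = DEFAULT_THRESHOLD,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = MAX_TMS_LEN,
    min_gap: int = MIN_TMS_GAP,
    segment_penalty: float = SEGMENT_PENALTY,
) -> Topology:
    """Call TMSs by matched-filter segmentation of the hydropathy profile.

    The caller places non-overlapping segments of ``min_len``..``max_len``
    residues (at least ``min_gap`` apart) so as to maximise the summed
    hydropathy excess over ``threshold``; a segment is only worth placing
    where the profile averages above the threshold, so loops contribute
    nothing.  This is the Viterbi decoding of a two-state
    (membrane / loop) model with Gaussian emissions of equal variance and
    hard duration bounds — the length cap (no single crossing exceeds 35
    residues) is what splits long hydrophobic stretches into multiple
    crossings.  Everything not covered by a segment is implicitly LOOP.
    """
    values = profile.values
    n = len(values)
    excess = values - threshold
    ps = np.concatenate([[0.0], np.cumsum(excess)])  # prefix sums

    # F[i]: best total score over positions [0, i); choice[i] reconstructs.
    F = np.zeros(n + 1)
    choice: list[tuple[int, int] | None] = [None] * (n + 1)
    for i in range(1, n + 1):
        F[i] = F[i - 1]
        choice[i] = None
        for length in range(min_len, min(max_len, i) + 1):
            a = i - length
            prev = F[max(a - min_gap, 0)] if a > 0 else 0.0
            score = prev + ps[i] - ps[a] - segment_penalty
            if score > F[i] + 1e-12:
                F[i] = score
                choice[i] = (a, i)
    segments: list[Segment] = []
    i = n
    while i > 0:
        if choice[i] is None:
            i -= 1
        else:
            a, b = choice[i]
            segments.append(Segment(a, b, "TMS"))
            i = max(a - min_gap, 0)
    segments.reverse()
    return Topology(tuple(segments), source="predicted")


def classify_architecture(topo: Topology, long_loop: int = DEFAULT_LONG_LOOP) -> str:
    """Group membrane segments separated by short loops; label "3+1" style.

    Membrane segments (TMS and RL alike — both appear as hydrophobic peaks)
    are grouped together when the gap between consecutive segments is shorter
    than ``long_loop`` residues; the label joins group sizes with '+'.
    """
    membrane = topo.membrane_segments()
    if not membrane:
        return "0"
    groups = [1]
    for prev, cur in zip(membrane, membrane[1:]):
        if cur.start - prev.end < long_loop:
            groups[-1] += 1
        else:
            groups.append(1)
    return "+".join(str(g) for g in groups)


@dataclass(frozen=True)
class SegmentLengthSummary:
    kind: str
    mean: float
    sd: float
    n: int


def segment_lengths(topos, kind: str) -> SegmentLengthSummary:
    """Mean and sample SD of segment lengths of one kind across topologies."""
    lengths = [len(s) for topo in topos for s in topo.of_kind(kind)]
    if not lengths:
        raise ValidationError(f"no segments of kind {kind}")
    arr = np.array(lengths, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return SegmentLengthSummary(kind, float(arr.mean()), sd, len(arr))


def mean_segment_hydropathy(seq: AnnotatedSequence, kinds=("TMS", "RL")) -> float:
    """Mean raw Kyte–Doolittle value over residues of the given segment kinds."""
    vals = [
        KYTE_DOOLITTLE[seq.residues[i]]
        for seg in seq.topology.segments
        if seg.kind in kinds
        for i in range(seg.start, seg.end)
    ]
    if not vals:
        raise ValidationError(f"no residues of kinds {kinds}")
    return float(np.mean(vals))


def mean_loop_hydropathy(seq: AnnotatedSequence) -> float:
    """Mean raw Kyte–Doolittle value over residues outside membrane segments."""
    covered = np.zeros(len(seq), dtype=bool)
    for seg in seq.topology.membrane_segments():
        covered[seg.start:seg.end] = True
    vals = [KYTE_DOOLITTLE[c] for c, inside in zip(seq.residues, covered) if not inside]
    if not vals:
        raise ValidationError("no loop residues")
    return float(np.mean(vals))
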