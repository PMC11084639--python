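"""Core domain types, on-disk formats, configuration and seeded randomness.

This module is the type hub of the package: sequence records, topology
segments, annotated sequences, CA-trace chains and the run configuration all
live here so that the analysis modules can share them without import cycles.

Coordinate convention: everything in memory is 0-based, half-open
``[start, end)``.  Everything on disk (topology TSVs, result tables) is
1-based, inclusive — the common convention of sequence-analysis tools.
Conversion happens only inside the readers and writers of this module.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger("memhomology")

#: The twenty standard amino acids, in the conventional alphabetical order.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: Alphabet accepted in sequence records ('X' marks an unknown residue).
AA_ALPHABET = AA20 + "X"

SEGMENT_KINDS = ("TMS", "RL", "LOOP")
#: Segment kinds that sit inside the membrane (reentrant loops are pooled
#: with transmembrane segments: both are hydrophobic environments).
MEMBRANE_KINDS = ("TMS", "RL")


class FormatError(ValueError):
    """A file did not conform to its expected on-disk format."""


class ValidationError(ValueError):
    """An in-memory object violated one of its invariants."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence: identifier, residues, free-text description."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record needs a non-empty id")
        if not self.residues:
            raise ValidationError(f"{self.id}: empty residue string")
        bad = set(self.residues) - set(AA_ALPHABET)
        if bad:
            pos = next(i for i, c in enumerate(self.residues) if c in bad)
            raise ValidationError(
                f"{self.id}: illegal residue {self.residues[pos]!r} at position {pos + 1}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Segment:
    """One topology segment, 0-based half-open."""

    start: int
    end: int
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ValidationError(f"unknown segment kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(f"bad segment bounds [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def is_membrane(self) -> bool:
        return self.kind in MEMBRANE_KINDS


@dataclass(frozen=True)
class Topology:
    """Ordered, disjoint typed segments over one sequence.

    Positions not covered by any stored segment are implicitly LOOP; readers
    may therefore store only TMS/RL segments.  ``source`` records whether the
    assignment came from an input annotation or from ``topology.predict_tms``.
    """

    segments: tuple[Segment, ...]
    source: str = "annotated"

    def __post_init__(self) -> None:
        segs = tuple(sorted(self.segments, key=lambda s: s.start))
        object.__setattr__(self, "segments", segs)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"overlapping segments [{a.start},{a.end}) and [{b.start},{b.end})"
                )
            if b.start == a.end and a.kind == b.kind:
                raise ValidationError(
                    f"adjacent segments of identical kind {a.kind} at {a.end}"
                )
        if self.source not in ("annotated", "predicted"):
            raise ValidationError(f"unknown topology source {self.source!r}")

    def membrane_segments(self) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.is_membrane)

    def of_kind(self, kind: str) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.kind == kind)

    def segment_at(self, pos: int) -> Segment | None:
        """The stored segment containing ``pos``, or None (implicit loop)."""
        for s in self.segments:
            if s.start <= pos < s.end:
                return s
        return None

    def class_of(self, pos: int) -> str:
        """'membrane' or 'loop' for a position (RL counts as membrane)."""
        seg = self.segment_at(pos)
        return "membrane" if seg is not None and seg.is_membrane else "loop"

    def check_bounds(self, length: int) -> None:
        if self.segments and self.segments[-1].end > length:
            raise ValidationError(
                f"segment [{self.segments[-1].start},{self.segments[-1].end}) "
                f"exceeds sequence length {length}"
            )

    def shifted(self, offset: int) -> "Topology":
        return Topology(
            tuple(Segment(s.start + offset, s.end + offset, s.kind) for s in self.segments),
            source=self.source,
        )


@dataclass(frozen=True)
class AnnotatedSequence:
    """A sequence with its topology; optionally a map to ancestor coordinates.

    ``ancestor_map`` is used by the synthetic generator: entry i is the
    ancestor position from which residue i descends, or None for an inserted
    residue.  Real inputs leave it None.
    """

    record: SequenceRecord
    topology: Topology
    ancestor_map: tuple | None = None

    def __post_init__(self) -> None:
        self.topology.check_bounds(len(self.record))
        if self.ancestor_map is not None and len(self.ancestor_map) != len(self.record):
            raise ValidationError("ancestor_map length mismatch")

    @property
    def id(self) -> str:
        return self.record.id

    @property
    def residues(self) -> str:
        return self.record.residues

    def __len__(self) -> int:
        return len(self.record)


@dataclass(frozen=True)
class StructureChain:
    """An ordered CA trace with residue numbers and optional segment labels.

    ``sequence``, when present, carries one residue letter per CA (toy
    structures emitted by the synthetic generator fill it in).
    """

    coords: np.ndarray  # (n, 3) Angstroms
    residue_numbers: tuple[int, ...]
    labels: tuple[str, ...] | None = None
    chain_id: str = "A"
    sequence: str | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValidationError("coords must be an (n, 3) array")
        if coords.shape[0] != len(self.residue_numbers):
            raise ValidationError("coordinate count != residue-number count")
        if coords.shape[0] == 0:
            raise ValidationError("empty chain")
        nums = np.asarray(self.residue_numbers)
        if np.any(np.diff(nums) <= 0):
            raise ValidationError("residue numbers must be strictly increasing")
        if self.labels is not None and len(self.labels) != coords.shape[0]:
            raise ValidationError("label count != coordinate count")

    def __len__(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class RunConfig:
    """Global knobs shared across the pipeline.

    Thresholds mirror the significance cut-offs used throughout the evidence
    lines: pairwise E-value 1e-4, repeat-filter E-value 1e-3, motif-scan
    E-value 1e-4, GEV p-value 1e-3.
    """

    scoring_scheme: str = "blosum62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    n_shuffles: int = 10_000
    evalue_threshold: float = 1e-4
    repeat_evalue_threshold: float = 1e-3
    motif_evalue_threshold: float = 1e-4
    gev_p_threshold: float = 1e-3
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValidationError("gap penalties must be positive")
        if self.n_shuffles < 100:
            raise ValidationError("shuffle count must be at least 100")
        for name in ("evalue_threshold", "repeat_evalue_threshold",
                     "motif_evalue_threshold", "gev_p_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must lie in (0, 1)")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Seeded randomness
# ---------------------------------------------------------------------------

def spawn_rng(master_seed: int, *labels) -> np.random.Generator:
    """A generator for one named random stream.

    Streams are derived from ``(master_seed, crc32(label), ...)`` through
    :class:`numpy.random.SeedSequence`, so every pipeline stage gets an
    independent, reproducible stream and two runs with the same master seed
    are identical.
    """
    entropy = [int(master_seed) & 0x7FFFFFFF]
    for lab in labels:
        if isinstance(lab, (int, np.integer)):
            entropy.append(int(lab) & 0xFFFFFFFF)
        else:
            entropy.append(zlib.crc32(str(lab).encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def digest(data: str | bytes) -> str:
    """Short sha256 digest used when logging stage inputs."""
    if isinstance(data, str):
        data = data.encode()
    return hashlib.sha256(data).hexdigest()[:12]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(r"^>(\S+)\s*(.*)$")


def parse_fasta(path: str | Path, allow_gaps: bool = False) -> list[SequenceRecord]:
    """Read a plain (or, with ``allow_gaps``, aligned) FASTA file.

    Residues are uppercased; record order is preserved.  '-' is legal only
    when ``allow_gaps`` is set (reading MSAs), and gap columns are kept.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    current_id: str | None = None
    current_desc = ""
    chunks: list[str] = []

    def flush() -> None:
        nonlocal current_id
        if current_id is None:
            return
        seq = "".join(chunks).upper()
        allowed = set(AA_ALPHABET) | ({"-"} if allow_gaps else set())
        for i, c in enumerate(seq):
            if c not in allowed:
                raise FormatError(
                    f"{path}: record {current_id!r}: illegal character {c!r} "
                    f"at sequence position {i + 1}"
                )
        if not seq:
            raise FormatError(f"{path}: record {current_id!r} has no residues")
        if allow_gaps:
            records.append(GappedRecord(current_id, seq, current_desc))
        else:
            records.append(SequenceRecord(current_id, seq, current_desc))
        current_id = None
        chunks.clear()

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                m = _HEADER_RE.match(line)
                if not m:
                    raise FormatError(f"{path}:{lineno}: malformed header {line!r}")
                current_id, current_desc = m.group(1), m.group(2)
            else:
                if current_id is None:
                    raise FormatError(f"{path}:{lineno}: sequence data before any header")
                chunks.append(line.strip())
        flush()
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


class GappedRecord(SequenceRecord):
    """SequenceRecord that tolerates '-' (aligned FASTA rows)."""

    def __post_init__(self) -> None:  # relaxed alphabet check
        if not self.id:
            raise ValidationError("sequence record needs a non-empty id")
        if not self.residues:
            raise ValidationError(f"{self.id}: empty residue string")
        bad = set(self.residues) - set(AA_ALPHABET) - {"-"}
        if bad:
            raise ValidationError(f"{self.id}: illegal characters {sorted(bad)}")


def parse_msa(path: str | Path) -> list[SequenceRecord]:
    """Read an aligned FASTA file; all rows must have equal length."""
    rows = parse_fasta(path, allow_gaps=True)
    lengths = {len(r.residues) for r in rows}
    if len(lengths) != 1:
        raise FormatError(f"{path}: MSA rows have unequal lengths {sorted(lengths)}")
    return rows


def emit_fasta(records: Sequence[SequenceRecord], path: str | Path, width: int = 60) -> Path:
    """Write records as FASTA wrapped at ``width`` characters."""
    if not records:
        raise ValidationError("refusing to write an empty FASTA file")
    if width < 1:
        raise ValidationError("width must be positive")
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# Topology tables
# ---------------------------------------------------------------------------

def read_topology_table(path: str | Path) -> dict[str, Topology]:
    """Read a TSV of segments: columns id, start, end, kind (1-based inclusive).

    Returns a mapping id -> Topology in internal 0-based half-open
    coordinates.  Rows may arrive unsorted; overlaps are rejected naming the
    offending row.
    """
    path = Path(path)
    per_id: dict[str, list[Segment]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#") or line.lower().startswith("id\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            sid, start_s, end_s, kind = parts[0], parts[1], parts[2], parts[3].upper()
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end1 < start1 or start1 < 1:
                raise ValidationError(f"{path}:{lineno}: bad interval {start1}..{end1}")
            if kind not in SEGMENT_KINDS:
                raise FormatError(f"{path}:{lineno}: unknown segment kind {kind!r}")
            per_id.setdefault(sid, []).append(Segment(start1 - 1, end1, kind))
    result: dict[str, Topology] = {}
    for sid, segs in per_id.items():
        try:
            result[sid] = Topology(tuple(segs))
        except ValidationError as exc:
            raise ValidationError(f"{path}: {sid}: {exc}") from exc
    return result


def write_topology_table(topologies: Mapping[str, Topology], path: str | Path) -> Path:
    """Inverse of :func:`read_topology_table` (1-based inclusive on disk)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("id\tstart\tend\tkind\n")
        for sid, topo in topologies.items():
            for seg in topo.segments:
                fh.write(f"{sid}\t{seg.start + 1}\t{seg.end}\t{seg.kind}\n")
    return path


# ---------------------------------------------------------------------------
# Structures (CA traces)
# ---------------------------------------------------------------------------

def read_ca_coordinates(path: str | Path, chain: str) -> StructureChain:
    """Read the alpha-carbon trace of one chain from a PDB or mmCIF file.

    Altlocs are resolved to the highest-occupancy conformer; one coordinate
    per residue is returned, in residue order.
    """
    import gemmi

    path = Path(path)
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    model = structure[0]
    target = None
    for ch in model:
        if ch.name == chain:
            target = ch
            break
    if target is None:
        raise LookupError(
            f"{path}: chain {chain!r} not found (have {[c.name for c in model]})"
        )
    coords, numbers = [], []
    for residue in target:
        best = None
        for atom in residue:
            if atom.name == "CA":
                if best is None or atom.occ > best.occ:
                    best = atom
        if best is not None:
            coords.append([best.pos.x, best.pos.y, best.pos.z])
            numbers.append(residue.seqid.num)
    if not coords:
        raise ValidationError(f"{path}: chain {chain!r} has no CA atoms")
    return StructureChain(np.array(coords), tuple(numbers), chain_id=chain)


def write_ca_pdb(chain: StructureChain, path: str | Path) -> Path:
    """Write a CA-only PDB file (enough for round-tripping toy structures)."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, (xyz, num) in enumerate(zip(chain.coords, chain.residue_numbers), 1):
            fh.write(
                f"ATOM  {i:5d}  CA  ALA {chain.chain_id}{num:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")
    return path


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def _quote_label(label: str) -> str:
    if re.search(r"[\s()\[\]{}:;,']", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree, path: str | Path) -> Path:
    """Write a :class:`memhomology.clustering.Dendrogram` as Newick.

    Branch lengths are merge-height differences (parent height minus child
    height; leaves sit at height zero), which makes the file readable by any
    standard Newick consumer.
    """
    labels = list(tree.labels)
    if len(labels) < 2:
        raise ValidationError("tree must have at least 2 leaves")
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate leaf labels")
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    newick = {i: _quote_label(labels[i]) for i in range(n)}
    for k, (a, b, h) in enumerate(tree.merges):
        node = n + k
        la = f"{newick[a]}:{h - heights[a]:.6g}"
        lb = f"{newick[b]}:{h - heights[b]:.6g}"
        newick[node] = f"({la},{lb})"
        heights[node] = h
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(newick[n + len(tree.merges) - 1] + ";\n")
    return path
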