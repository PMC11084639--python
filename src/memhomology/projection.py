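"""Domain projection: transfer an annotated domain interval to a homolog
through a pairwise alignment.

When a protein family carries a characteristic domain that direct detection
cannot find in a candidate relative, the domain's coordinates can be mapped
through a pairwise alignment onto the relative ("projection").  A
projection is trusted only when enough of the domain's residues are
actually matched (non-gap) in the alignment, and — at the pipeline level —
only projections succeeding in a single iteration (depth 1) are used.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_io import ValidationError
from .pairwise import LocalAlignment


@dataclass(frozen=True)
class DomainAnnotation:
    """A named domain interval on a carrier protein (0-based half-open)."""

    name: str
    carrier_id: str
    interval: tuple[int, int]
    score_tag: str = "direct"       # 'direct' or 'projected'
    path: tuple[str, ...] = ()      # alignment ids traversed
    depth: int = 0                  # 0 = direct annotation

    def __post_init__(self) -> None:
        s, e = self.interval
        if not (0 <= s < e):
            raise ValidationError(f"bad domain interval [{s}, {e})")
        if self.depth < 0:
            raise ValidationError("depth must be non-negative")


@dataclass(frozen=True)
class ProjectionResult:
    accepted: bool
    mapped_fraction: float
    annotation: DomainAnnotation | None  # None on rejection


def project_domain(dom: DomainAnnotation, aln: LocalAlignment,
                   min_fraction: float = 0.5) -> ProjectionResult:
    """Map a domain interval through an alignment onto the partner protein.

    Counts the domain residues matched to partner residues (gap columns do
    not map); accepts when the mapped fraction reaches ``min_fraction`` of
    the domain length, returning the image interval on the partner with the
    projection depth incremented and the alignment appended to the path.
    """
    if dom.carrier_id == aln.query_id:
        own, other = 0, 1
        partner = aln.subject_id
    elif dom.carrier_id == aln.subject_id:
        own, other = 1, 0
        partner = aln.query_id
    else:
        raise ValidationError(
            f"domain carrier {dom.carrier_id!r} is not part of alignment "
            f"{aln.query_id!r} vs {aln.subject_id!r}"
        )
    s, e = dom.interval
    mapped = [p[other] for p in aln.pairs if s <= p[own] < e]
    fraction = len(mapped) / (e - s)
    if fraction < min_fraction:
        return ProjectionResult(False, fraction, None)
    aln_id = f"{aln.query_id}~{aln.subject_id}"
    projected = DomainAnnotation(
        dom.name, partner, (min(mapped), max(mapped) + 1),
        score_tag="projected", path=dom.path + (aln_id,), depth=dom.depth + 1,
    )
    return ProjectionResult(True, fraction, projected)
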