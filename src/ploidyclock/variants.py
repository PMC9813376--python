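"""Variant containers: somatic SNVs/indels and SV breakpoint pairs."""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional

from .exceptions import ValidationError


@dataclass(frozen=True, order=True)
class VariantRecord:
    """One somatic small variant with its read evidence.

    Positions are 1-based (VCF convention). ``alt_reads`` and
    ``total_depth`` are the raw evidence used downstream for VAF and
    multiplicity assignment.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_reads: int = 0
    total_depth: int = 0
    caller_id: str = ""

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValidationError(f"{self.chrom}:{self.pos} ref == alt ({self.ref!r})")
        if not (0 <= self.alt_reads <= self.total_depth):
            raise ValidationError(
                f"{self.chrom}:{self.pos} requires 0 <= alt_reads <= total_depth, "
                f"got alt_reads={self.alt_reads}, total_depth={self.total_depth}"
            )

    @property
    def vaf(self) -> float:
        """Variant allele fraction; 0.0 at zero depth."""
        return self.alt_reads / self.total_depth if self.total_depth else 0.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity used for exact consensus matching."""
        return (self.chrom, self.pos, self.ref, self.alt)

    def with_caller(self, caller_id: str) -> "VariantRecord":
        return replace(self, caller_id=caller_id)


class TimingClass(str, Enum):
    """Placement of a mutation relative to the genome doubling(s)."""

    PRE_WGD = "pre_wgd"
    BETWEEN_WGD = "between_wgd"  # only with two doublings
    POST_WGD = "post_wgd"
    UNINFORMATIVE = "uninformative"


@dataclass
class SomaticMutation:
    """A somatic SNV annotated along the timing pipeline.

    ``multiplicity`` (m) is the number of chromosome copies carrying the
    mutation; ``None`` until assigned. ``true_multiplicity`` is only set
    by the simulator and never consulted by estimators.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_reads: int
    total_depth: int
    caller_id: str = ""
    multiplicity: Optional[int] = None
    timing_class: TimingClass = TimingClass.UNINFORMATIVE
    true_multiplicity: Optional[int] = None

    @property
    def vaf(self) -> float:
        return self.alt_reads / self.total_depth if self.total_depth else 0.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def to_record(self) -> VariantRecord:
        return VariantRecord(
            self.chrom, self.pos, self.ref, self.alt,
            self.alt_reads, self.total_depth, self.caller_id,
        )

    @classmethod
    def from_record(cls, rec: VariantRecord) -> "SomaticMutation":
        return cls(rec.chrom, rec.pos, rec.ref, rec.alt,
                   rec.alt_reads, rec.total_depth, rec.caller_id)


class SVType(str, Enum):
    """Structural-variant classes by breakpoint-junction orientation."""

    DELETION_LIKE = "deletion-like"        # 3to5 junction
    DUPLICATION_LIKE = "duplication-like"  # 5to3 junction
    INV_HEAD_TO_HEAD = "head-to-head inversion"  # 3to3
    INV_TAIL_TO_TAIL = "tail-to-tail inversion"  # 5to5
    TRANSLOCATION = "translocation"


@dataclass(frozen=True)
class SVBreakpointPair:
    """A structural variant as two oriented breakpoints.

    Breakpoints are ``(chrom, pos, strand)`` with 1-based positions and
    strand in ``{"+", "-"}``. Intrachromosomal events store bp1 <= bp2
    in genome order.
    """

    sv_type: SVType
    bp1: tuple[str, int, str]
    bp2: tuple[str, int, str]
    caller_id: str = ""

    def __post_init__(self):
        for bp in (self.bp1, self.bp2):
            if bp[2] not in ("+", "-"):
                raise ValidationError(f"strand must be '+' or '-', got {bp[2]!r}")
        if self.bp1[0] == self.bp2[0] and self.bp1[1] > self.bp2[1]:
            raise ValidationError("intrachromosomal breakpoints must be in genome order")
        if self.sv_type is SVType.TRANSLOCATION:
            if self.bp1[0] == self.bp2[0]:
                raise ValidationError("translocation breakpoints must be on different chromosomes")
        elif self.bp1[0] != self.bp2[0]:
            raise ValidationError(f"{self.sv_type.value} must be intrachromosomal")

    @property
    def strands(self) -> tuple[str, str]:
        return (self.bp1[2], self.bp2[2])
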