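"""Allele-specific copy-number segments and per-sample profiles.

A :class:`Segment` carries the integer copy number of the two parental
alleles over a genomic interval; ``major_cn`` is the more amplified
allele, so ``major_cn >= minor_cn`` always. Intervals are 0-based
half-open. A :class:`SegmentProfile` bundles a sample's segments with
its tumor purity and is the substrate for ploidy, SCNA classes, LOH
queries and WGD calling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

from .exceptions import UncoveredLocusError, ValidationError
from .genome import GenomeSpec


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    major_cn: int
    minor_cn: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError(f"segment {self.chrom}:{self.start}-{self.end} has end <= start")
        if self.minor_cn < 0 or self.major_cn < self.minor_cn:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end} needs major_cn >= minor_cn >= 0, "
                f"got ({self.major_cn}, {self.minor_cn})"
            )

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and self.end > start


@dataclass
class SegmentProfile:
    """A sample's allele-specific copy-number profile.

    Segments are stored sorted by (chrom, start) and must not overlap
    within a chromosome; gaps (uncovered genome) are allowed and are
    excluded from all length-weighted statistics.
    """

    sample_id: str
    purity: float
    segments: list[Segment] = field(default_factory=list)
    genome: Optional[GenomeSpec] = None

    def __post_init__(self):
        if not (0.0 < self.purity <= 1.0):
            raise ValidationError(f"purity must be in (0, 1], got {self.purity}")
        self.segments = sorted(self.segments, key=lambda s: (s.chrom, s.start))
        self._check_no_overlap()

    def _check_no_overlap(self):
        offenders = []
        for a, b in zip(self.segments, self.segments[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                offenders.append((a, b))
        if offenders:
            desc = "; ".join(
                f"{a.chrom}:{a.start}-{a.end} overlaps {b.chrom}:{b.start}-{b.end}"
                for a, b in offenders
            )
            raise ValidationError(f"overlapping segments: {desc}")
        if self.genome is not None:
            for s in self.segments:
                if not self.genome.contains_interval(s.chrom, s.start, s.end):
                    raise ValidationError(
                        f"segment {s.chrom}:{s.start}-{s.end} outside genome bounds"
                    )

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    @property
    def covered_length(self) -> int:
        return sum(s.length for s in self.segments)

    def overlapping(self, chrom: str, start: int, end: int) -> list[Segment]:
        """Segments intersecting the 0-based half-open query interval."""
        return [s for s in self.segments if s.overlaps(chrom, start, end)]

    def segment_at(self, chrom: str, pos: int) -> Segment:
        """The segment covering 1-based position ``pos`` (VCF convention)."""
        hits = self.overlapping(chrom, pos - 1, pos)
        if not hits:
            raise UncoveredLocusError(f"{chrom}:{pos} not covered by any segment")
        return hits[0]

    def doubled(self) -> "SegmentProfile":
        """The profile after an in-silico whole-genome doubling."""
        return SegmentProfile(
            self.sample_id,
            self.purity,
            [Segment(s.chrom, s.start, s.end, 2 * s.major_cn, 2 * s.minor_cn)
             for s in self.segments],
            self.genome,
        )


def make_profile(
    sample_id: str,
    purity: float,
    rows: Iterable[tuple[str, int, int, int, int]],
    genome: Optional[GenomeSpec] = None,
    swap_warn: Callable[[str], None] | None = None,
) -> SegmentProfile:
    """Build a profile from (chrom, start, end, major, minor) rows.

    Rows with major < minor are auto-swapped (the major allele is by
    definition the more amplified one) with a warning.
    """
    segs = []
    for chrom, start, end, major, minor in rows:
        if major < minor:
            msg = (f"segment {chrom}:{start}-{end} has major_cn < minor_cn "
                   f"({major} < {minor}); swapping")
            (swap_warn or (lambda m: warnings.warn(m, stacklevel=3)))(msg)
            major, minor = minor, major
        segs.append(Segment(str(chrom), int(start), int(end), int(major), int(minor)))
    return SegmentProfile(sample_id, purity, segs, genome)
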