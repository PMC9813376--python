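"""Allele-specific copy-number reasoning.

Implements the genome-fraction machinery, tumor ploidy, the SCNA
classification used for plotting/summaries, whole-genome-doubling (WGD)
calling and locus-level LOH queries, plus the parsimony argument that
orders an allelic loss relative to a WGD.

WGD rule: a sample underwent at least one doubling when the major
allele has copy number >= 2 over at least half of the (covered) genome;
the k-th doubling generalises this to major >= 2**k over at least half
of the genome. A sample is flagged polyploid when its length-weighted
mean total copy number is >= 2.5. Thresholds are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable

from .exceptions import EmptyProfileError, UncoveredLocusError
from .segments import Segment, SegmentProfile

POLYPLOID_PLOIDY = 2.5
WGD_GENOME_FRACTION = 0.5
MAX_WGD = 2


class SCNAClass(str, Enum):
    """Per-segment SCNA classes from (total, minor) copy number.

    The first five classes follow the conventional scheme (Neutral,
    Neutral-LoH, Hemizygous, Hom-del, Amp-LoH); ``GAIN`` is our
    extension covering total > 2 with a retained minor allele, which
    the five-class scheme leaves out. It is reported separately so the
    five named classes stay bit-comparable with the convention.
    """

    NEUTRAL = "Neutral"            # total = 2, minor = 1
    NEUTRAL_LOH = "Neutral-LoH"    # total = 2, minor = 0
    HEMIZYGOUS = "Hemizygous"      # total = 1
    HOM_DEL = "Hom-del"            # total = 0
    AMP_LOH = "Amp-LoH"            # total > 2, minor = 0
    GAIN = "Gain"                  # total > 2, minor >= 1 (extension)


class LossWGDOrder(str, Enum):
    """Verdict on whether an allelic loss preceded the genome doubling."""

    LOSS_BEFORE_WGD_LIKELY = "loss_before_wgd_likely"
    LOSS_AFTER_WGD_POSSIBLE = "loss_after_wgd_possible"
    NO_LOH = "no_loh"
    NO_WGD = "no_wgd"


@dataclass(frozen=True)
class WGDCall:
    """Result of WGD calling on one profile."""

    n_wgd: int
    fraction_major_ge2: float
    fraction_major_ge4: float
    ploidy: float
    polyploid: bool

    def as_dict(self) -> dict:
        return {
            "n_wgd": self.n_wgd,
            "fraction_major_ge2": self.fraction_major_ge2,
            "fraction_major_ge4": self.fraction_major_ge4,
            "ploidy": self.ploidy,
            "polyploid": self.polyploid,
        }


def genome_fraction(profile: SegmentProfile, predicate: Callable[[Segment], bool]) -> float:
    """Length-weighted fraction of the covered genome where ``predicate`` holds."""
    total = profile.covered_length
    if total == 0:
        raise EmptyProfileError("genome fraction undefined on an empty profile")
    hit = sum(s.length for s in profile if predicate(s))
    return hit / total


def compute_ploidy(profile: SegmentProfile) -> float:
    """Length-weighted mean total copy number over the covered genome."""
    total = profile.covered_length
    if total == 0:
        raise EmptyProfileError("ploidy undefined on an empty profile")
    return sum(s.length * s.total_cn for s in profile) / total


def classify_scna(segment: Segment) -> SCNAClass:
    """Classify one segment; total over (major, minor) pairs."""
    total, minor = segment.total_cn, segment.minor_cn
    if total == 0:
        return SCNAClass.HOM_DEL
    if total == 1:
        return SCNAClass.HEMIZYGOUS
    if total == 2:
        return SCNAClass.NEUTRAL if minor == 1 else SCNAClass.NEUTRAL_LOH
    return SCNAClass.AMP_LOH if minor == 0 else SCNAClass.GAIN


def scna_fractions(profile: SegmentProfile) -> dict[str, float]:
    """Genome fraction occupied by each SCNA class (sums to 1)."""
    return {
        cls.value: genome_fraction(profile, lambda s, c=cls: classify_scna(s) is c)
        for cls in SCNAClass
    }


def call_wgd(profile: SegmentProfile, threshold: float = WGD_GENOME_FRACTION) -> WGDCall:
    """Call the number of WGD events (0, 1 or 2) on a profile.

    The k-th doubling is called when the major allele is >= 2**k over at
    least ``threshold`` of the covered genome (inclusive boundary).
    """
    frac_ge2 = genome_fraction(profile, lambda s: s.major_cn >= 2)
    frac_ge4 = genome_fraction(profile, lambda s: s.major_cn >= 4)
    n_wgd = 0
    if frac_ge2 >= threshold:
        n_wgd = 1
        if frac_ge4 >= threshold:
            n_wgd = 2
    ploidy = compute_ploidy(profile)
    return WGDCall(
        n_wgd=n_wgd,
        fraction_major_ge2=frac_ge2,
        fraction_major_ge4=frac_ge4,
        ploidy=ploidy,
        polyploid=ploidy >= POLYPLOID_PLOIDY,
    )


def loh_at_locus(profile: SegmentProfile, chrom: str, start: int, end: int
                 ) -> tuple[bool, list[Segment]]:
    """Is the locus (0-based half-open) under LOH?

    True iff every segment overlapping the locus has minor_cn = 0.
    Raises :class:`UncoveredLocusError` when nothing overlaps — an
    uncovered locus is not evidence of heterozygosity.
    """
    hits = profile.overlapping(chrom, start, end)
    if not hits:
        raise UncoveredLocusError(f"locus {chrom}:{start}-{end} not covered by any segment")
    return all(s.minor_cn == 0 for s in hits), hits


def infer_loss_vs_wgd_order(profile: SegmentProfile, chrom: str, start: int, end: int
                            ) -> LossWGDOrder:
    """Order an allelic loss at a locus relative to the genome doubling.

    In a doubled genome, LOH with major >= 2 means the retained allele
    was itself duplicated — a single loss before the doubling explains
    it, whereas loss after doubling would need two independent losses.
    LOH with major = 1 is consistent with losses after the doubling.
    """
    if call_wgd(profile).n_wgd < 1:
        return LossWGDOrder.NO_WGD
    is_loh, hits = loh_at_locus(profile, chrom, start, end)
    if not is_loh:
        return LossWGDOrder.NO_LOH
    if all(s.major_cn >= 2 for s in hits):
        return LossWGDOrder.LOSS_BEFORE_WGD_LIKELY
    return LossWGDOrder.LOSS_AFTER_WGD_POSSIBLE
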