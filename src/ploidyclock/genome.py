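"""Genome description used by the simulator and coordinate checks."""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import ValidationError


@dataclass(frozen=True)
class GenomeSpec:
    """An ordered set of chromosomes with their lengths in bp.

    Parameters
    ----------
    chromosomes
        List of ``(name, length)`` pairs. Names must be unique and
        lengths strictly positive.
    """

    chromosomes: tuple[tuple[str, int], ...]
    _lengths: dict[str, int] = field(init=False, repr=False, compare=False, hash=False, default=None)

    def __init__(self, chromosomes):
        chromosomes = tuple((str(n), int(l)) for n, l in chromosomes)
        names = [n for n, _ in chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names in genome")
        if any(l <= 0 for _, l in chromosomes):
            raise ValidationError("chromosome lengths must be > 0")
        object.__setattr__(self, "chromosomes", chromosomes)
        object.__setattr__(self, "_lengths", dict(chromosomes))

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def contains_interval(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) is a valid interval on ``chrom`` (0-based half-open)."""
        return chrom in self._lengths and 0 <= start < end <= self._lengths[chrom]


def toy_genome(n_chroms: int = 4, chrom_length: int = 50_000_000) -> GenomeSpec:
    """Small synthetic genome used throughout the tests and simulations."""
    return GenomeSpec([(f"chr{i + 1}", chrom_length) for i in range(n_chroms)])


def parse_locus(text: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (1-based inclusive) into 0-based half-open.

    ``chr17:4945650-4949088`` -> ``("chr17", 4945649, 4949088)``.
    """
    try:
        chrom, span = text.rsplit(":", 1)
        lo, hi = span.replace(",", "").split("-")
        start1, end1 = int(lo), int(hi)
    except ValueError:
        raise ValidationError(f"cannot parse locus {text!r}; expected chrom:start-end") from None
    if start1 < 1 or end1 < start1:
        raise ValidationError(f"invalid locus coordinates in {text!r}")
    return chrom, start1 - 1, end1


def format_locus(chrom: str, start: int, end: int) -> str:
    """Inverse of :func:`parse_locus` (0-based half-open -> 1-based inclusive)."""
    return f"{chrom}:{start + 1}-{end}"
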