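"""Multi-caller consensus filtering for SNVs and structural variants.

Small variants are matched by exact (chrom, pos, ref, alt) identity —
indels included, since callers report them allele-resolved. Structural
variants are matched breakpoint-tolerantly: same type, same chromosome
pair, concordant strands and both breakpoints within a tolerance
(default ±100 bp), then single-linkage clustered. A variant or cluster
is retained when supported by at least ``min_callers`` *distinct*
callers (the default 2 mirrors "2 of 3" SNV and "2 of 4" SV filtering).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .exceptions import ValidationError
from .variants import SVBreakpointPair, VariantRecord

DEFAULT_MIN_CALLERS = 2
DEFAULT_SV_TOLERANCE_BP = 100


@dataclass(frozen=True)
class ConsensusVariant:
    """A retained small variant with its per-caller support."""

    record: VariantRecord
    support: int
    callers: tuple[str, ...]


@dataclass(frozen=True)
class ConsensusSV:
    """A retained SV cluster: median-breakpoint representative + support."""

    representative: SVBreakpointPair
    support: int
    callers: tuple[str, ...]
    members: tuple[SVBreakpointPair, ...]


def merge_snv_calls(
    callsets: Sequence[Sequence[VariantRecord]],
    min_callers: int = DEFAULT_MIN_CALLERS,
) -> list[ConsensusVariant]:
    """Keep variants called by >= ``min_callers`` of the supplied callsets.

    Matching is by exact (chrom, pos, ref, alt). Within one callset,
    duplicate keys count once. The representative record is the one
    with the highest total depth (the best-covered observation); output
    is sorted by genomic key and independent of callset order.
    """
    if min_callers > len(callsets):
        raise ValidationError(
            f"min_callers={min_callers} exceeds number of callsets ({len(callsets)})"
        )
    by_key: dict[tuple, dict[str, VariantRecord]] = {}
    for idx, callset in enumerate(callsets):
        for rec in callset:
            caller = rec.caller_id or f"caller{idx}"
            slot = by_key.setdefault(rec.key, {})
            prev = slot.get(caller)
            if prev is None or rec.total_depth > prev.total_depth:
                slot[caller] = rec
    out = []
    for key in sorted(by_key):
        callers = by_key[key]
        if len(callers) < min_callers:
            continue
        rep = max(callers.values(), key=lambda r: (r.total_depth, r.caller_id))
        out.append(ConsensusVariant(rep, len(callers), tuple(sorted(callers))))
    return out


def match_sv(a: SVBreakpointPair, b: SVBreakpointPair,
             tolerance_bp: int = DEFAULT_SV_TOLERANCE_BP) -> bool:
    """True iff two SVs describe the same junction within tolerance.

    Requires identical type, the same chromosome pair, concordant
    strands and both breakpoints within ``tolerance_bp`` (inclusive).
    """
    if tolerance_bp < 0:
        raise ValidationError("tolerance_bp must be >= 0")
    if a.sv_type is not b.sv_type:
        return False
    if (a.bp1[0], a.bp2[0]) != (b.bp1[0], b.bp2[0]):
        return False
    if a.strands != b.strands:
        return False
    return (abs(a.bp1[1] - b.bp1[1]) <= tolerance_bp
            and abs(a.bp2[1] - b.bp2[1]) <= tolerance_bp)


def _low_median(values: Sequence[int]) -> int:
    """Median; the lower middle value on even counts (deterministic)."""
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def merge_sv_calls(
    callsets: Sequence[Sequence[SVBreakpointPair]],
    min_callers: int = DEFAULT_MIN_CALLERS,
    tolerance_bp: int = DEFAULT_SV_TOLERANCE_BP,
) -> list[ConsensusSV]:
    """Single-linkage cluster SVs under :func:`match_sv`; keep clusters
    supported by >= ``min_callers`` distinct callers.

    The cluster representative takes the coordinate-wise (low-)median of
    member breakpoints; type/chromosomes/strands are shared by
    construction. Output order and content are independent of callset
    order.
    """
    if min_callers > len(callsets):
        raise ValidationError(
            f"min_callers={min_callers} exceeds number of callsets ({len(callsets)})"
        )
    labeled: list[tuple[str, SVBreakpointPair]] = []
    for idx, callset in enumerate(callsets):
        for sv in callset:
            labeled.append((sv.caller_id or f"caller{idx}", sv))
    # canonical order so clustering is permutation-invariant
    labeled.sort(key=lambda t: (t[1].bp1[0], t[1].bp1[1], t[1].bp2[0], t[1].bp2[1],
                                t[1].sv_type.value, t[1].strands, t[0]))
    n = len(labeled)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = labeled[i][1], labeled[j][1]
            if b.bp1[0] != a.bp1[0] or b.bp1[1] - a.bp1[1] > tolerance_bp:
                break  # sorted by bp1: nothing further can match i
            if match_sv(a, b, tolerance_bp):
                parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    out = []
    for members_idx in clusters.values():
        members = [labeled[i] for i in members_idx]
        callers = sorted({c for c, _ in members})
        if len(callers) < min_callers:
            continue
        svs = [sv for _, sv in members]
        rep = SVBreakpointPair(
            svs[0].sv_type,
            (svs[0].bp1[0], _low_median([s.bp1[1] for s in svs]), svs[0].bp1[2]),
            (svs[0].bp2[0], _low_median([s.bp2[1] for s in svs]), svs[0].bp2[2]),
            caller_id="consensus",
        )
        out.append(ConsensusSV(rep, len(callers), tuple(callers), tuple(svs)))
    out.sort(key=lambda c: (c.representative.bp1[0], c.representative.bp1[1],
                            c.representative.bp2[0], c.representative.bp2[1],
                            c.representative.sv_type.value))
    return out
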