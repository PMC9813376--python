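"""Synthetic tumor genomes with a known evolutionary history.

The generator realises a deliberately simple clonal model so that every
downstream stage (consensus, SCNA/WGD calling, mutation-clock timing,
clone karyotyping) can be tested against ground truth:

* The tumor lineage starts diploid at the patient's birth and evolves
  to diagnosis at age ``A``. Molecular time runs on [0, 1] and is
  proportional to chronological time (constant mutation accumulation).
* Segmental events (one-allele gains/losses) and 0-2 whole-genome
  doublings occur at chosen molecular times; a WGD doubles every
  chromosome copy.
* Point mutations arise at a constant rate *per chromosome copy*, so a
  region's mutation intensity tracks its current total copy number.
  ``mu`` is calibrated per diploid genome-equivalent: a genome that
  stays diploid accumulates ``Poisson(mu * A)`` mutations in total.
  A mutation lands on one copy extant at its time and is inherited by
  every later duplication of that copy; its true multiplicity is the
  number of final copies descending from the mutated molecule.
  Mutations whose carrier copies are all lost are deleted.
* Reads: per-site depth ~ Poisson(D); alt reads ~ Binomial(depth, phi)
  with phi = m*rho / (rho*CN_total + 2*(1-rho)). No base-call errors.
* Caller replicates: each imperfect caller keeps a true variant with
  its sensitivity and adds Poisson false positives at fresh positions.
* Low-pass bins: per-bin counts with mean proportional to local total
  CN at a polyploid baseline, negative-binomial noise.

Single clonal population throughout (every mutation at cancer-cell
fraction 1); subclonal structure is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .genome import GenomeSpec
from .segments import Segment, SegmentProfile
from .variants import SomaticMutation, VariantRecord

_BASES = np.array(list("ACGT"))

EVENT_GAIN = "segment_gain"
EVENT_LOSS = "segment_loss"
EVENT_ALLELE_LOSS = "allele_loss"
EVENT_WGD = "WGD"


@dataclass(frozen=True)
class SimulationTruth:
    """The stated world of one simulated tumor.

    Parameters
    ----------
    age_at_diagnosis
        Patient age A in years; the molecular clock maps [0, 1] onto
        [0, A].
    mutation_rate
        mu, expected mutations per diploid genome-equivalent per year.
    wgd_times
        Molecular times (fractions of the clock) of 0, 1 or 2
        whole-genome doublings, strictly increasing in (0, 1).
    purity
        Tumor cell fraction rho of the sequenced sample.
    depth
        Mean sequencing depth D (reads per site).
    seed
        Root seed; all randomness in the simulation flows from it.
    """

    age_at_diagnosis: float = 66.0
    mutation_rate: float = 50.0
    wgd_times: tuple[float, ...] = ()
    purity: float = 0.7
    depth: float = 60.0
    seed: int = 0

    def __post_init__(self):
        times = tuple(float(t) for t in self.wgd_times)
        object.__setattr__(self, "wgd_times", times)
        if len(times) > 2:
            raise ValidationError("at most two WGD events are modeled")
        if any(not (0.0 < t < 1.0) for t in times):
            raise ValidationError("WGD times must lie strictly inside (0, 1)")
        if len(times) == 2 and not times[0] < times[1]:
            raise ValidationError("WGD times must be strictly increasing")
        if not (0.0 < self.purity <= 1.0):
            raise ValidationError("purity must be in (0, 1]")
        if self.age_at_diagnosis <= 0 or self.mutation_rate <= 0 or self.depth <= 0:
            raise ValidationError("age, mutation rate and depth must be > 0")


@dataclass(frozen=True)
class Event:
    """One evolutionary event. ``chrom`` is None for genome-wide WGD;
    ``allele`` indexes the parental allele (0/1) for segmental events."""

    kind: str
    time: float
    chrom: Optional[str] = None
    start: int = 0
    end: int = 0
    allele: int = 0


@dataclass
class EventLog:
    """Time-ordered record of every applied (or skipped) event."""

    genome: GenomeSpec
    events: list[Event] = field(default_factory=list)
    skipped: list[Event] = field(default_factory=list)

    def __post_init__(self):
        times = [e.time for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValidationError("event times must be non-decreasing")
        for e in self.events:
            if e.kind != EVENT_WGD and not self.genome.contains_interval(e.chrom, e.start, e.end):
                raise ValidationError(f"event interval outside genome: {e}")


def simulate_cn_profile(
    genome: GenomeSpec,
    truth: SimulationTruth,
    n_cna: int,
    seed: Optional[int] = None,
    sample_id: str = "sim",
    cna_length_range: tuple[float, float] = (0.05, 0.5),
) -> tuple[SegmentProfile, EventLog]:
    """Evolve a diploid genome through ``n_cna`` segmental events plus
    the WGDs in ``truth``, returning the final profile and the log.

    Each segmental event picks a chromosome (length-weighted), a random
    interval covering ``cna_length_range`` of it, one parental allele,
    and gains or loses one copy of it there. Events that would drive a
    copy number below zero are skipped and logged. The emitted profile
    reports (major, minor) per maximal run of constant allele-specific
    state; segments are merged across identical neighbours.
    """
    if n_cna < 0:
        raise ValidationError("n_cna must be >= 0")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    events = [Event(EVENT_WGD, t) for t in truth.wgd_times]
    lengths = np.array([l for _, l in genome.chromosomes], dtype=float)
    probs = lengths / lengths.sum()
    lo, hi = cna_length_range
    for _ in range(n_cna):
        t = float(rng.uniform())
        ci = int(rng.choice(len(probs), p=probs))
        chrom, clen = genome.chromosomes[ci]
        seg_len = max(1, int(rng.uniform(lo, hi) * clen))
        start = int(rng.integers(0, clen - seg_len + 1))
        kind = EVENT_GAIN if rng.uniform() < 0.5 else EVENT_LOSS
        events.append(Event(kind, t, chrom, start, start + seg_len, int(rng.integers(2))))
    events.sort(key=lambda e: e.time)

    state = {c: [(0, l, 1, 1)] for c, l in genome.chromosomes}  # (start, end, cnA, cnB)
    applied, skipped = [], []
    for ev in events:
        if ev.kind == EVENT_WGD:
            for c in state:
                state[c] = [(s, e, 2 * a, 2 * b) for s, e, a, b in state[c]]
            applied.append(ev)
            continue
        delta = 1 if ev.kind == EVENT_GAIN else -1
        segs = _split(state[ev.chrom], ev.start, ev.end)
        if delta < 0:
            affected = [
                (a if ev.allele == 0 else b)
                for s, e, a, b in segs if s < ev.end and e > ev.start
            ]
            if any(cn + delta < 0 for cn in affected):
                skipped.append(ev)
                state[ev.chrom] = segs
                continue
        new = []
        for s, e, a, b in segs:
            if s < ev.end and e > ev.start:
                if ev.allele == 0:
                    a += delta
                else:
                    b += delta
            new.append((s, e, a, b))
        state[ev.chrom] = new
        applied.append(ev)

    segments = []
    for chrom, _ in genome.chromosomes:
        for s, e, a, b in _merge(state[chrom]):
            segments.append(Segment(chrom, s, e, max(a, b), min(a, b)))
    profile = SegmentProfile(sample_id, truth.purity, segments, genome)
    return profile, EventLog(genome, applied, skipped)


def _split(segs, start, end):
    out = []
    for s, e, a, b in segs:
        cuts = sorted({s, e, *(p for p in (start, end) if s < p < e)})
        out.extend((p, q, a, b) for p, q in zip(cuts, cuts[1:]))
    return out


def _merge(segs):
    out = []
    for seg in segs:
        seg = tuple(seg)
        if out and out[-1][1] == seg[0] and out[-1][2:] == seg[2:]:
            out[-1] = (out[-1][0], seg[1], seg[2], seg[3])
        else:
            out.append(seg)
    return out


def replay_events(log: EventLog) -> SegmentProfile:
    """Re-apply the log on a diploid genome (self-consistency oracle).

    Returns the profile the log implies; purity 1 and sample id
    "replay" since neither is part of the event algebra.
    """
    state = {c: [(0, l, 1, 1)] for c, l in log.genome.chromosomes}
    for ev in log.events:
        if ev.kind == EVENT_WGD:
            for c in state:
                state[c] = [(s, e, 2 * a, 2 * b) for s, e, a, b in state[c]]
            continue
        delta = 1 if ev.kind == EVENT_GAIN else -1
        segs = _split(state[ev.chrom], ev.start, ev.end)
        new = []
        for s, e, a, b in segs:
            if s < ev.end and e > ev.start:
                if ev.allele == 0:
                    a += delta
                else:
                    b += delta
            new.append((s, e, a, b))
        state[ev.chrom] = new
    segments = []
    for chrom, _ in log.genome.chromosomes:
        for s, e, a, b in _merge(state[chrom]):
            segments.append(Segment(chrom, s, e, max(a, b), min(a, b)))
    return SegmentProfile("replay", 1.0, segments, log.genome)


def _atomic_regions(log: EventLog):
    """Decompose the genome into atomic intervals sharing one event list.

    Yields (chrom, start, end, events-affecting-interval) with events in
    time order; WGDs affect every interval.
    """
    for chrom, clen in log.genome.chromosomes:
        cuts = {0, clen}
        for ev in log.events:
            if ev.kind != EVENT_WGD and ev.chrom == chrom:
                cuts.update((ev.start, ev.end))
        cuts = sorted(cuts)
        for s, e in zip(cuts, cuts[1:]):
            evs = [
                ev for ev in log.events
                if ev.kind == EVENT_WGD
                or (ev.chrom == chrom and ev.start < e and ev.end > s)
            ]
            yield chrom, s, e, evs


def _allele_history(events, allele):
    """Piecewise-constant copy number of one parental allele through time.

    Returns (times, cns): cn on [times[i], times[i+1]) is cns[i], with
    times[0] = 0 and times[-1] = 1.
    """
    times, cns = [0.0], [1]
    cn = 1
    for ev in events:
        if ev.kind == EVENT_WGD:
            cn *= 2
        elif ev.allele == allele:
            cn += 1 if ev.kind == EVENT_GAIN else -1
        else:
            continue
        times.append(ev.time)
        cns.append(cn)
    times.append(1.0)
    return times, cns


def simulate_mutations(
    profile: SegmentProfile,
    log: EventLog,
    truth: SimulationTruth,
    seed: Optional[int] = None,
) -> list[SomaticMutation]:
    """Drop point mutations onto the simulated lineage and read them out.

    Mutation intensity in an interval tracks its copy number through
    time (constant per-copy rate); each mutation marks one copy and its
    true multiplicity is the count of final copies descended from it.
    Observed counts follow the Poisson-depth / binomial-VAF model with
    the profile's purity. Mutations on fully lost lineages are dropped.
    """
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    genome_len = log.genome.total_length
    total_muts = truth.mutation_rate * truth.age_at_diagnosis

    # rectangles: (chrom, start, end, allele, t0, t1, cn, later-events)
    rects = []
    weights = []
    for chrom, s, e, evs in _atomic_regions(log):
        for allele in (0, 1):
            times, cns = _allele_history(evs, allele)
            for i, cn in enumerate(cns):
                t0, t1 = times[i], times[i + 1]
                if cn == 0 or t1 <= t0:
                    continue
                later = [ev for ev in evs
                         if ev.time >= t1 and (ev.kind == EVENT_WGD or ev.allele == allele)]
                rects.append((chrom, s, e, allele, t0, t1, cn, later))
                weights.append((e - s) * cn * (t1 - t0))
    weights = np.asarray(weights, dtype=float)
    if weights.sum() == 0:
        return []
    # calibrate: a constant-diploid genome has weight 2 * genome_len
    lam = total_muts * weights.sum() / (2.0 * genome_len)
    n = rng.poisson(lam)
    if n == 0:
        return []
    counts = rng.multinomial(n, weights / weights.sum())

    muts: list[SomaticMutation] = []
    for (chrom, s, e, allele, t0, t1, cn0, later), k in zip(rects, counts):
        if k == 0:
            continue
        pos = rng.integers(s, e, size=k) + 1  # 1-based
        marked = np.ones(k, dtype=np.int64)
        cn = np.full(k, cn0, dtype=np.int64)
        for ev in later:
            if ev.kind == EVENT_WGD:
                marked *= 2
                cn *= 2
                continue
            # a fully lost lineage (marked = cn = 0) stays lost
            frac = np.divide(marked, cn, out=np.zeros(k), where=cn > 0)
            if ev.kind == EVENT_GAIN:
                marked += rng.random(k) < frac
                cn += 1
            else:
                marked -= rng.random(k) < frac
                cn = np.maximum(cn - 1, 0)
        alive = marked > 0
        if not alive.any():
            continue
        # final total CN at this interval (both alleles)
        seg = profile.overlapping(chrom, s, e)[0]
        total_cn = seg.total_cn
        phi = marked[alive] * truth.purity / (
            truth.purity * total_cn + 2.0 * (1.0 - truth.purity))
        depth = rng.poisson(truth.depth, size=alive.sum())
        alt = rng.binomial(depth, np.clip(phi, 0.0, 1.0))
        refi = rng.integers(0, 4, size=alive.sum())
        refb = _BASES[refi]
        altb = _BASES[(refi + rng.integers(1, 4, size=refi.size)) % 4]
        for p, m, d, a, rb, ab in zip(pos[alive], marked[alive], depth, alt, refb, altb):
            muts.append(SomaticMutation(
                chrom, int(p), str(rb), str(ab), int(a), int(d),
                caller_id="truth", true_multiplicity=int(m),
            ))
    muts.sort(key=lambda m: (m.chrom, m.pos))
    return muts


def simulate_tumor(
    genome: GenomeSpec,
    truth: SimulationTruth,
    n_cna: int = 10,
    sample_id: str = "sim",
) -> tuple[SegmentProfile, EventLog, list[SomaticMutation]]:
    """Convenience wrapper: profile + event log + mutations from one seed."""
    profile, log = simulate_cn_profile(genome, truth, n_cna, sample_id=sample_id)
    muts = simulate_mutations(profile, log, truth)
    return profile, log, muts


def simulate_caller_replicates(
    true_variants: Sequence[SomaticMutation | VariantRecord],
    n_callers: int,
    sensitivity: float | Sequence[float] = 0.9,
    fp_rate: float | Sequence[float] = 0.0,
    seed: int = 0,
    genome: Optional[GenomeSpec] = None,
) -> list[list[VariantRecord]]:
    """Emulate imperfect, independent variant callers.

    Each caller retains each true variant with its sensitivity and adds
    ``Poisson(fp_rate)`` false positives at fresh random positions
    (``fp_rate`` is the expected number of false calls per callset).
    Callsets are labeled ``caller0 .. caller{n-1}``.
    """
    if n_callers < 1:
        raise ValidationError("n_callers must be >= 1")
    sens = np.broadcast_to(np.asarray(sensitivity, dtype=float), (n_callers,))
    fps = np.broadcast_to(np.asarray(fp_rate, dtype=float), (n_callers,))
    if ((sens < 0) | (sens > 1)).any() or (fps < 0).any():
        raise ValidationError("sensitivities must be in [0,1] and fp rates >= 0")
    rng = np.random.default_rng(seed)
    records = [v.to_record() if isinstance(v, SomaticMutation) else v
               for v in true_variants]
    taken = {r.key[:2] for r in records}
    callsets = []
    for c in range(n_callers):
        cid = f"caller{c}"
        keep = rng.random(len(records)) < sens[c]
        calls = [r.with_caller(cid) for r, k in zip(records, keep) if k]
        n_fp = rng.poisson(fps[c])
        g = genome or GenomeSpec([("chr1", 10_000_000)])
        lengths = np.array([l for _, l in g.chromosomes], dtype=float)
        for _ in range(int(n_fp)):
            while True:
                ci = int(rng.choice(len(lengths), p=lengths / lengths.sum()))
                chrom = g.chromosomes[ci][0]
                pos = int(rng.integers(1, g.chromosomes[ci][1] + 1))
                if (chrom, pos) not in taken:
                    break
            taken.add((chrom, pos))
            ref, alt = (str(b) for b in rng.choice(_BASES, size=2, replace=False))
            depth = int(rng.poisson(60))
            alt_reads = min(depth, int(rng.poisson(3)))
            calls.append(VariantRecord(chrom, pos, ref, alt, alt_reads, depth, cid))
        calls.sort(key=lambda r: (r.chrom, r.pos))
        callsets.append(calls)
    return callsets


def simulate_lowpass_bins(
    clone_cn: SegmentProfile,
    bin_size: int = 50_000,
    noise_dispersion: float = 0.05,
    seed: int = 0,
    mean_bin_count: float = 500.0,
    baseline_ploidy: int = 4,
) -> pd.DataFrame:
    """Binned read-count track for a (near-tetraploid) clone genome.

    Per-bin mean is ``mean_bin_count * total_CN / baseline_ploidy``
    scaled by bin width, so a genome at the baseline ploidy yields a
    flat track of ``mean_bin_count`` per full bin. Noise is negative
    binomial with var = mean + dispersion * mean**2; a zero dispersion
    yields the (rounded) deterministic means, so tests can pin the
    noiseless signal exactly.
    """
    if bin_size <= 0:
        raise ValidationError("bin_size must be > 0")
    if noise_dispersion < 0:
        raise ValidationError("noise_dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    genome = clone_cn.genome
    if genome is None:
        raise ValidationError("clone profile needs an attached GenomeSpec")
    rows = []
    for chrom, clen in genome.chromosomes:
        starts = np.arange(0, clen, bin_size)
        ends = np.minimum(starts + bin_size, clen)
        cn = np.zeros(len(starts), dtype=float)
        for seg in clone_cn.overlapping(chrom, 0, clen):
            ov = (np.minimum(ends, seg.end) - np.maximum(starts, seg.start)).clip(min=0)
            cn += ov / (ends - starts) * seg.total_cn
        mean = mean_bin_count * (cn / baseline_ploidy) * (ends - starts) / bin_size
        if noise_dispersion == 0:
            counts = np.round(mean).astype(int)
        else:
            # NB via gamma-poisson: shape r = 1/d, scale mean*d
            lam = rng.gamma(1.0 / noise_dispersion, mean * noise_dispersion)
            counts = rng.poisson(lam)
        for s, e, c in zip(starts, ends, counts):
            rows.append((chrom, int(s), int(e), int(c)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])
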