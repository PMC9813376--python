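"""Mutation-clock timing of whole-genome doublings.

The model: a clonal tumor accumulates point mutations at a constant
rate per chromosome copy from the patient's birth (molecular time 0) to
diagnosis (time 1). A mutation present before a doubling is duplicated
with its chromosome and ends up on multiple copies (multiplicity
m = 2, or 4 through two doublings), whereas a mutation arising after
the doubling sits on a single copy (m = 1). The ratio of high- to
low-multiplicity mutations therefore dates the doubling.

Estimator (one WGD). In copy-number states (2,2) and (2,0) — the
states whose histories are unambiguous — a mutation with m = 2 must
predate the doubling and one with m = 1 postdate it. With c surviving
pre-WGD copies (2 in a 2+2 region, 1 in a 2+0 region) the expected
counts are E[N2] = c*pi and E[N1] = 2c*(1-pi), so in both states

    pi_hat = 2*N2 / (2*N2 + N1)

and the counts pool across states.

Estimator (two WGDs). In (4,4) regions the per-copy clock gives
E[N4] = 2*pi1, E[N2] = 4*(pi2 - pi1), E[N1] = 8*(1 - pi2) per unit
length, so with D = N4/2 + N2/4 + N1/8,

    pi1_hat = (N4/2) / D        pi2_hat = (N4/2 + N2/4) / D.

Multiplicity is assigned per mutation by binomial maximum likelihood
over the VAF model phi(m) = m*rho / (rho*CN_total + 2*(1-rho)) with
rho the tumor purity. Uncertainty comes from a percentile bootstrap
over informative mutations; real time follows from the constant-rate
assumption as (1 - pi)*A years before diagnosis at age A.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import PloidyclockError, ValidationError
from .segments import Segment, SegmentProfile
from .variants import SomaticMutation, TimingClass

DEFAULT_BOOTSTRAP = 1000
DEFAULT_LEVEL = 0.95

# (major, minor) states with an unambiguous doubling history
_INFORMATIVE_ONE_WGD = {(2, 2), (2, 0)}
_INFORMATIVE_TWO_WGD = {(4, 4)}


class TimingError(PloidyclockError):
    """Raised when timing is requested without usable signal."""


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata needed for real-time conversion."""

    sample_id: str
    age_at_diagnosis: float
    purity: float

    def __post_init__(self):
        if self.age_at_diagnosis <= 0:
            raise ValidationError("age_at_diagnosis must be > 0")
        if not (0.0 < self.purity <= 1.0):
            raise ValidationError("purity must be in (0, 1]")


def expected_vaf(m: int, total_cn: int, purity: float) -> float:
    """Expected VAF of a clonal mutation on ``m`` of ``total_cn`` copies.

    phi = m*rho / (rho*total_cn + 2*(1-rho)); the denominator counts
    tumor plus admixed normal (diploid) alleles per cell.
    """
    if not (0.0 < purity <= 1.0):
        raise ValidationError("purity must be in (0, 1]")
    if m < 1 or m > total_cn:
        raise ValidationError(f"need 1 <= m <= total_cn, got m={m}, total_cn={total_cn}")
    return m * purity / (purity * total_cn + 2.0 * (1.0 - purity))


def assign_multiplicity(mutation: SomaticMutation, segment: Segment,
                        purity: float) -> Optional[int]:
    """Maximum-likelihood integer multiplicity for one mutation.

    Maximizes Binomial(alt_reads | depth, phi(m)) over m in
    {1..major_cn}; ties break toward the smaller m. Returns None (and
    leaves the mutation unassigned) when alt_reads = 0.
    """
    if segment.total_cn == 0:
        raise ValidationError(
            f"mutation {mutation.chrom}:{mutation.pos} falls in a homozygous deletion"
        )
    if mutation.total_depth <= 0:
        raise ValidationError(f"mutation {mutation.chrom}:{mutation.pos} has zero depth")
    if mutation.alt_reads == 0:
        mutation.multiplicity = None
        return None
    ms = np.arange(1, segment.major_cn + 1)
    phis = np.array([expected_vaf(int(m), segment.total_cn, purity) for m in ms])
    ll = stats.binom.logpmf(mutation.alt_reads, mutation.total_depth,
                            np.clip(phis, 1e-12, 1.0))
    best = int(ms[np.argmax(ll)])  # argmax takes the first (smallest m) on ties
    mutation.multiplicity = best
    return best


def classify_timing(mutation: SomaticMutation, segment: Segment,
                    n_wgd: int) -> TimingClass:
    """Place a multiplicity-assigned mutation relative to the doubling(s).

    One WGD: only (2,2) and (2,0) segments are informative; m=2 is
    pre-doubling, m=1 post-doubling. Two WGDs: only (4,4); m=4 predates
    both, m=2 falls between them, m=1 postdates both. Everything else —
    including (2,1), whose history is ambiguous — is uninformative.
    """
    if n_wgd < 1:
        raise ValidationError("timing needs at least one WGD event")
    state = (segment.major_cn, segment.minor_cn)
    m = mutation.multiplicity
    cls = TimingClass.UNINFORMATIVE
    if m is not None:
        if n_wgd == 1 and state in _INFORMATIVE_ONE_WGD:
            cls = {2: TimingClass.PRE_WGD, 1: TimingClass.POST_WGD}.get(m, cls)
        elif n_wgd >= 2 and state in _INFORMATIVE_TWO_WGD:
            cls = {4: TimingClass.PRE_WGD, 2: TimingClass.BETWEEN_WGD,
                   1: TimingClass.POST_WGD}.get(m, cls)
    mutation.timing_class = cls
    return cls


def _pi_from_counts(n_wgd: int, counts: np.ndarray) -> np.ndarray:
    """Point estimate(s) of pi from class counts.

    ``counts`` is (N2, N1) for one WGD or (N4, N2, N1) for two; both
    forms broadcast over a leading bootstrap axis.
    """
    counts = np.asarray(counts, dtype=float)
    if n_wgd == 1:
        n2, n1 = counts[..., 0], counts[..., 1]
        denom = 2.0 * n2 + n1
        with np.errstate(invalid="ignore"):
            pi = np.where(denom > 0, 2.0 * n2 / np.where(denom > 0, denom, 1.0), np.nan)
        return pi[..., None]
    n4, n2, n1 = counts[..., 0], counts[..., 1], counts[..., 2]
    d = n4 / 2.0 + n2 / 4.0 + n1 / 8.0
    safe = np.where(d > 0, d, 1.0)
    pi1 = np.where(d > 0, (n4 / 2.0) / safe, np.nan)
    pi2 = np.where(d > 0, (n4 / 2.0 + n2 / 4.0) / safe, np.nan)
    return np.stack([pi1, pi2], axis=-1)


def _assignment_probs(depth: int, phis: np.ndarray, classes: Sequence[int]
                      ) -> np.ndarray:
    """P(assigned class j | true class i) at one read depth.

    ``phis`` spans every candidate multiplicity (1..major); ``classes``
    are the timing-informative multiplicities. Assignment follows the
    same ML rule as :func:`assign_multiplicity` (ties and a=0 excluded
    toward no call), so rows can sum to < 1 (leakage to uninformative).
    """
    a = np.arange(1, depth + 1)
    ll = stats.binom.logpmf(a[:, None], depth, np.clip(phis, 1e-12, 1.0)[None, :])
    assigned = np.argmax(ll, axis=1) + 1
    out = np.zeros((len(classes), len(classes)))
    for i, m_true in enumerate(classes):
        pmf = stats.binom.pmf(a, depth, phis[m_true - 1])
        for j, m_assigned in enumerate(classes):
            out[i, j] = pmf[assigned == m_assigned].sum()
    return out


def misassignment_matrix(mutations: Sequence[SomaticMutation],
                         profile: SegmentProfile, n_wgd: int) -> np.ndarray:
    """Average ML-assignment confusion matrix over informative-region
    mutations.

    At finite depth the ML multiplicity call confuses neighbouring
    states a few percent of the time, which attenuates the early/late
    count ratio (classes are unbalanced, so the flows do not cancel).
    The confusion probabilities follow from the binomial read model
    itself, so the count vector can be corrected by inverting this
    matrix — a standard misclassification (measurement-error)
    deconvolution. Rows/columns follow the class order of
    :func:`timing_counts` (descending multiplicity).
    """
    informative = _INFORMATIVE_ONE_WGD if n_wgd == 1 else _INFORMATIVE_TWO_WGD
    classes = [2, 1] if n_wgd == 1 else [4, 2, 1]
    index = _SegmentIndex(profile)
    combos: dict[tuple[int, int, int], int] = {}
    for mut in mutations:
        k = index.lookup(mut.chrom, mut.pos)
        if k is None:
            continue
        seg = profile.segments[k]
        if (seg.major_cn, seg.minor_cn) not in informative:
            continue
        key = (mut.total_depth, seg.total_cn, seg.major_cn)
        combos[key] = combos.get(key, 0) + 1
    if not combos:
        raise TimingError("no mutations in timing-informative segments")
    total = sum(combos.values())
    bbar = np.zeros((len(classes), len(classes)))
    for (depth, total_cn, major), n in combos.items():
        if depth < 1:
            continue
        phis = np.array([expected_vaf(m, total_cn, profile.purity)
                         for m in range(1, major + 1)])
        bbar += (n / total) * _assignment_probs(depth, phis, classes)
    return bbar


def correct_counts(counts: np.ndarray, bbar: np.ndarray) -> np.ndarray:
    """Deconvolve raw class counts through the confusion matrix.

    Solves ``bbar.T q = counts`` for the underlying class abundances,
    clamping negatives to zero. Falls back to the raw counts when the
    matrix is ill-conditioned (nearly indistinguishable classes) —
    there is then no information to correct with.
    """
    counts = np.asarray(counts, dtype=float)
    if np.linalg.cond(bbar) > 1e6:
        return counts
    q = np.linalg.solve(bbar.T, counts)
    q = np.clip(q, 0.0, None)
    if q.sum() == 0:
        return counts
    return q


def timing_counts(mutations: Sequence[SomaticMutation], n_wgd: int) -> np.ndarray:
    """Class counts (N2, N1) or (N4, N2, N1) from classified mutations."""
    pre = sum(m.timing_class is TimingClass.PRE_WGD for m in mutations)
    mid = sum(m.timing_class is TimingClass.BETWEEN_WGD for m in mutations)
    post = sum(m.timing_class is TimingClass.POST_WGD for m in mutations)
    if n_wgd == 1:
        return np.array([pre, post])
    return np.array([pre, mid, post])


def estimate_wgd_time(mutations: Sequence[SomaticMutation], profile: SegmentProfile,
                      n_wgd: int) -> np.ndarray:
    """Point estimate(s) pi_hat from annotated mutations.

    Mutations must already carry multiplicity and timing class (see
    :class:`WGDTimingModel` for the full path from raw calls). Returns
    one value per doubling.
    """
    if n_wgd not in (1, 2):
        raise ValidationError("n_wgd must be 1 or 2 for timing")
    counts = timing_counts(mutations, n_wgd)
    if counts.sum() == 0:
        raise TimingError(
            f"no informative mutations (counts {counts.tolist()}); cannot time WGD"
        )
    return _pi_from_counts(n_wgd, counts)


def bootstrap_ci(
    mutations: Sequence[SomaticMutation],
    profile: SegmentProfile,
    n_wgd: int,
    n_bootstrap: int = DEFAULT_BOOTSTRAP,
    level: float = DEFAULT_LEVEL,
    seed: Optional[int] = None,
    confusion: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Percentile bootstrap CI for pi by resampling informative mutations.

    Informative mutations are exchangeable given their timing class, so
    resampling n of them with replacement is realised as a multinomial
    draw over the class counts (identical in distribution, vectorised).
    When a ``confusion`` matrix is supplied each resample is deconvolved
    through it, matching the point estimator of the fitted model.
    Returns an array of (ci_low, ci_high) per doubling.
    """
    if n_bootstrap < 1:
        raise ValidationError("n_bootstrap must be >= 1")
    if not (0.0 < level < 1.0):
        raise ValidationError("level must be in (0, 1)")
    counts = timing_counts(mutations, n_wgd)
    n = int(counts.sum())
    if n == 0:
        raise TimingError("cannot bootstrap with zero informative mutations")
    rng = np.random.default_rng(seed)
    resamples = rng.multinomial(n, counts / n, size=n_bootstrap).astype(float)
    if confusion is not None:
        resamples = np.stack([correct_counts(c, confusion) for c in resamples])
    pis = _pi_from_counts(n_wgd, resamples)  # (B, n_wgd)
    alpha = (1.0 - level) / 2.0
    lo = np.nanquantile(pis, alpha, axis=0)
    hi = np.nanquantile(pis, 1.0 - alpha, axis=0)
    return np.stack([lo, hi], axis=-1)


def to_real_time(pi: float, ci: tuple[float, float],
                 meta: SampleMeta) -> tuple[float, tuple[float, float]]:
    """Map molecular time to years before diagnosis: (1 - pi) * A.

    The CI maps monotonically decreasing (a later doubling is fewer
    years before diagnosis), so the interval endpoints swap.
    """
    lo, hi = ci
    for value in (pi, lo, hi):
        if not (0.0 <= value <= 1.0):
            raise ValidationError(f"molecular time {value} outside [0, 1]")
    A = meta.age_at_diagnosis
    return (1.0 - pi) * A, ((1.0 - hi) * A, (1.0 - lo) * A)


class _SegmentIndex:
    """Sorted per-chromosome arrays for O(log n) position -> segment lookup."""

    def __init__(self, profile: SegmentProfile):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for i, seg in enumerate(profile.segments):
            self._by_chrom.setdefault(seg.chrom, ([], [], []))
            starts, ends, idxs = self._by_chrom[seg.chrom]
            starts.append(seg.start)
            ends.append(seg.end)
            idxs.append(i)
        self._by_chrom = {
            c: (np.array(s), np.array(e), np.array(i))
            for c, (s, e, i) in self._by_chrom.items()
        }

    def lookup(self, chrom: str, pos: int) -> Optional[int]:
        """Global segment index covering 1-based ``pos``, or None."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, idxs = entry
        k = int(np.searchsorted(starts, pos - 1, side="right")) - 1
        if k < 0 or pos - 1 >= ends[k]:
            return None
        return int(idxs[k])


class WGDTimingModel:
    """Mutation-clock model for dating whole-genome doublings.

    Parameters
    ----------
    mutations
        Somatic SNVs with read counts (consensus-filtered upstream).
    profile
        The sample's allele-specific copy-number profile with purity.
    n_wgd
        Number of doublings to time (1 or 2); typically from
        :func:`ploidyclock.cn.call_wgd`.
    meta
        Optional sample metadata; enables real-time conversion.

    ``fit`` assigns multiplicities, classifies each mutation against
    the doubling(s) and estimates pi with a bootstrap CI.
    """

    def __init__(self, mutations: Sequence[SomaticMutation],
                 profile: SegmentProfile, n_wgd: int,
                 meta: Optional[SampleMeta] = None):
        if n_wgd not in (1, 2):
            raise ValidationError("WGDTimingModel requires n_wgd in {1, 2}")
        self.mutations = list(mutations)
        self.profile = profile
        self.n_wgd = n_wgd
        self.meta = meta

    @classmethod
    def from_records(cls, records, profile, n_wgd, meta=None):
        """Build from bare :class:`VariantRecord` calls."""
        return cls([SomaticMutation.from_record(r) for r in records],
                   profile, n_wgd, meta)

    def annotate(self) -> list[SomaticMutation]:
        """Assign multiplicity and timing class in place.

        Vectorised equivalent of calling :func:`assign_multiplicity`
        then :func:`classify_timing` per mutation (asserted equal in
        the tests). Mutations outside any segment, in homozygous
        deletions, or without reads stay unassigned/uninformative.
        """
        by_segment: dict[int, list[SomaticMutation]] = {}
        seg_index = _SegmentIndex(self.profile)
        for mut in self.mutations:
            mut.multiplicity = None
            mut.timing_class = TimingClass.UNINFORMATIVE
            idx = seg_index.lookup(mut.chrom, mut.pos)
            if idx is not None:
                by_segment.setdefault(idx, []).append(mut)

        informative = (_INFORMATIVE_ONE_WGD if self.n_wgd == 1
                       else _INFORMATIVE_TWO_WGD)
        class_map = ({2: TimingClass.PRE_WGD, 1: TimingClass.POST_WGD}
                     if self.n_wgd == 1 else
                     {4: TimingClass.PRE_WGD, 2: TimingClass.BETWEEN_WGD,
                      1: TimingClass.POST_WGD})
        annotated = []
        purity = self.profile.purity
        for idx, muts in by_segment.items():
            seg = self.profile.segments[idx]
            if seg.total_cn == 0:
                continue
            alt = np.array([m.alt_reads for m in muts])
            depth = np.array([m.total_depth for m in muts])
            phis = np.array([expected_vaf(m, seg.total_cn, purity)
                             for m in range(1, seg.major_cn + 1)])
            ll = stats.binom.logpmf(alt[:, None], depth[:, None],
                                    np.clip(phis, 1e-12, 1.0)[None, :])
            best = np.argmax(ll, axis=1) + 1  # first max -> smallest m
            state = (seg.major_cn, seg.minor_cn)
            for mut, m, a, d in zip(muts, best, alt, depth):
                if a == 0 or d == 0:
                    continue
                mut.multiplicity = int(m)
                if state in informative:
                    mut.timing_class = class_map.get(int(m),
                                                     TimingClass.UNINFORMATIVE)
                annotated.append(mut)
        return annotated

    def fit(self, n_bootstrap: int = DEFAULT_BOOTSTRAP,
            level: float = DEFAULT_LEVEL,
            seed: Optional[int] = None,
            correct_misassignment: bool = True) -> "WGDTimingResults":
        """Annotate, estimate pi and bootstrap its CI.

        ``correct_misassignment`` deconvolves the class counts through
        the binomial confusion matrix before applying the count
        estimator; without it the finite-depth ML multiplicity calls
        attenuate the early/late ratio and bias pi toward the balanced
        point (see :func:`misassignment_matrix`).
        """
        self.annotate()
        counts = timing_counts(self.mutations, self.n_wgd)
        if counts.sum() == 0:
            raise TimingError(
                f"no informative mutations (counts {counts.tolist()}); cannot time WGD"
            )
        bbar = (misassignment_matrix(self.mutations, self.profile, self.n_wgd)
                if correct_misassignment else None)
        corrected = correct_counts(counts, bbar) if bbar is not None else counts
        pi = _pi_from_counts(self.n_wgd, corrected)
        ci = bootstrap_ci(self.mutations, self.profile, self.n_wgd,
                          n_bootstrap=n_bootstrap, level=level, seed=seed,
                          confusion=bbar)
        return WGDTimingResults(self, pi, ci, counts, n_bootstrap, level)


class WGDTimingResults:
    """Fitted timing estimates with bootstrap uncertainty."""

    def __init__(self, model: WGDTimingModel, pi: np.ndarray, ci: np.ndarray,
                 counts: np.ndarray, n_bootstrap: int, level: float):
        self.model = model
        self.pi = np.asarray(pi, dtype=float)
        self.ci = np.asarray(ci, dtype=float)
        self.counts = np.asarray(counts, dtype=int)
        self.n_bootstrap = n_bootstrap
        self.level = level

    @property
    def n_wgd(self) -> int:
        return self.model.n_wgd

    @property
    def n_informative(self) -> int:
        return int(self.counts.sum())

    @property
    def n_pre(self) -> int:
        return int(self.counts[0])

    @property
    def n_mid(self) -> Optional[int]:
        return int(self.counts[1]) if self.n_wgd == 2 else None

    @property
    def n_post(self) -> int:
        return int(self.counts[-1])

    def years_before_diagnosis(self, meta: Optional[SampleMeta] = None):
        """Real-time estimates [(years, (lo, hi))] per doubling."""
        meta = meta or self.model.meta
        if meta is None:
            raise ValidationError("real-time conversion needs SampleMeta (age at diagnosis)")
        return [
            to_real_time(float(self.pi[k]), (float(self.ci[k, 0]), float(self.ci[k, 1])), meta)
            for k in range(len(self.pi))
        ]

    def as_dict(self) -> dict:
        events = []
        for k in range(len(self.pi)):
            ev = {
                "pi_hat": float(self.pi[k]),
                "ci_low": float(self.ci[k, 0]),
                "ci_high": float(self.ci[k, 1]),
            }
            meta = self.model.meta
            if meta is not None:
                years, (ylo, yhi) = to_real_time(
                    ev["pi_hat"], (ev["ci_low"], ev["ci_high"]), meta)
                ev.update(years_before_diagnosis=years,
                          years_ci_low=ylo, years_ci_high=yhi)
            events.append(ev)
        out = {
            "n_wgd": self.n_wgd,
            "n_bootstrap": self.n_bootstrap,
            "level": self.level,
            "n_informative": self.n_informative,
            "n_pre": self.n_pre,
            "n_post": self.n_post,
            "events": events,
        }
        if self.n_wgd == 2:
            out["n_mid"] = self.n_mid
        return out

    def summary(self) -> str:
        meta = self.model.meta
        lines = [
            "WGD mutation-clock timing",
            "=" * 41,
            f"sample:               {self.model.profile.sample_id}",
            f"doublings timed:      {self.n_wgd}",
            f"informative mutations: {self.n_informative} "
            f"(pre={self.n_pre}"
            + (f", mid={self.n_mid}" if self.n_wgd == 2 else "")
            + f", post={self.n_post})",
            f"bootstrap:            B={self.n_bootstrap}, level={self.level:.0%}",
            "-" * 41,
        ]
        for k in range(len(self.pi)):
            lines.append(
                f"WGD {k + 1}: pi = {self.pi[k]:.3f} "
                f"[{self.ci[k, 0]:.3f}, {self.ci[k, 1]:.3f}]"
            )
            if meta is not None:
                years, (ylo, yhi) = to_real_time(
                    float(self.pi[k]), (float(self.ci[k, 0]), float(self.ci[k, 1])), meta)
                lines.append(
                    f"        {years:.1f} years before diagnosis "
                    f"[{ylo:.1f}, {yhi:.1f}] (age {meta.age_at_diagnosis:g})"
                )
        return "\n".join(lines)
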