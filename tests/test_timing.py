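"""Multiplicity assignment and WGD molecular-time estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ploidyclock as pc
from helpers import uniform_profile
from ploidyclock.exceptions import ValidationError
from ploidyclock.timing import (
    SampleMeta,
    TimingError,
    _pi_from_counts,
    bootstrap_ci,
)
from ploidyclock.variants import SomaticMutation, TimingClass


def mut(alt, depth, pos=500, chrom="chr1"):
    return SomaticMutation(chrom, pos, "A", "T", alt, depth)


def classified(n_pre, n_post, n_mid=0):
    """Mutation list carrying only timing classes (what the estimator uses)."""
    out = []
    for cls, n in ((TimingClass.PRE_WGD, n_pre), (TimingClass.BETWEEN_WGD, n_mid),
                   (TimingClass.POST_WGD, n_post)):
        for i in range(n):
            m = mut(10, 30, pos=len(out) + 1)
            m.timing_class = cls
            out.append(m)
    return out


class TestExpectedVaf:
    @pytest.mark.parametrize("m,total,rho,phi", [
        (2, 4, 1.0, 0.5),
        (1, 2, 0.5, 0.25),
        (3, 3, 1.0, 1.0),
        (1, 2, 1.0, 0.5),
    ])
    def test_closed_form(self, m, total, rho, phi):
        assert pc.expected_vaf(m, total, rho) == pytest.approx(phi)

    def test_m_above_total_rejected(self):
        with pytest.raises(ValidationError):
            pc.expected_vaf(3, 2, 1.0)


class TestAssignMultiplicity:
    @pytest.mark.parametrize("rho", [0.3, 0.5, 0.7, 1.0])
    @pytest.mark.parametrize("total,major", [(2, 1), (2, 2), (4, 2), (4, 4), (8, 4)])
    def test_noiseless_roundtrip(self, rho, total, major):
        """assign(expected_vaf(m)) == m on exact read counts."""
        seg = pc.Segment("chr1", 0, 1000, major, total - major)
        depth = 1000
        for m in range(1, major + 1):
            phi = pc.expected_vaf(m, total, rho)
            mu = mut(int(round(phi * depth)), depth)
            assert pc.assign_multiplicity(mu, seg, rho) == m

    def test_zero_alt_reads_left_unassigned(self):
        seg = pc.Segment("chr1", 0, 1000, 2, 2)
        mu = mut(0, 60)
        assert pc.assign_multiplicity(mu, seg, 0.7) is None
        assert mu.multiplicity is None

    def test_homozygous_deletion_is_an_error(self):
        seg = pc.Segment("chr1", 0, 1000, 0, 0)
        with pytest.raises(ValidationError):
            pc.assign_multiplicity(mut(5, 30), seg, 1.0)

    def test_monte_carlo_recovery_at_realistic_depth(self, rng):
        """rho=0.7, depth~60, true m=2 in a (2,2) segment: ML recovers
        m=2 in >95% of draws (same binomial model as the oracle)."""
        seg = pc.Segment("chr1", 0, 1000, 2, 2)
        phi = pc.expected_vaf(2, 4, 0.7)
        n = 10_000
        depths = rng.poisson(60, size=n)
        alts = rng.binomial(depths, phi)
        hits = 0
        for a, d in zip(alts, depths):
            if d == 0 or a == 0:
                continue
            hits += pc.assign_multiplicity(mut(int(a), int(d)), seg, 0.7) == 2
        assert hits / n > 0.95

    def test_vectorized_annotate_matches_scalar_path(self, genome, rng):
        """The model's batched annotation equals per-mutation assignment."""
        prof = uniform_profile(genome, 2, 2, purity=0.7)
        muts = []
        for i in range(300):
            d = int(rng.poisson(60)) + 1
            a = int(rng.binomial(d, 0.3))
            muts.append(mut(a, d, pos=int(rng.integers(1, 10**6))))
        model = pc.WGDTimingModel([SomaticMutation(**vars(m)) for m in muts],
                                  prof, n_wgd=1)
        model.annotate()
        seg = prof.segments[0]
        for fast, orig in zip(model.mutations, muts):
            expected = pc.assign_multiplicity(orig, prof.segment_at(orig.chrom, orig.pos), 0.7)
            assert fast.multiplicity == expected


class TestClassifyTiming:
    def seg22(self):
        return pc.Segment("chr1", 0, 1000, 2, 2)

    def test_doubled_segment_m2_is_pre_wgd(self):
        m = mut(30, 60)
        m.multiplicity = 2
        assert pc.classify_timing(m, self.seg22(), 1) is TimingClass.PRE_WGD

    def test_doubled_segment_m1_is_post_wgd(self):
        m = mut(15, 60)
        m.multiplicity = 1
        assert pc.classify_timing(m, self.seg22(), 1) is TimingClass.POST_WGD

    def test_diploid_segment_uninformative(self):
        m = mut(30, 60)
        m.multiplicity = 1
        seg = pc.Segment("chr1", 0, 1000, 1, 1)
        assert pc.classify_timing(m, seg, 1) is TimingClass.UNINFORMATIVE

    def test_2_1_segment_excluded_by_default(self):
        m = mut(30, 60)
        m.multiplicity = 2
        seg = pc.Segment("chr1", 0, 1000, 2, 1)
        assert pc.classify_timing(m, seg, 1) is TimingClass.UNINFORMATIVE

    def test_two_wgd_classes_in_4_4(self):
        seg = pc.Segment("chr1", 0, 1000, 4, 4)
        for m_val, expected in [(4, TimingClass.PRE_WGD),
                                (2, TimingClass.BETWEEN_WGD),
                                (1, TimingClass.POST_WGD),
                                (3, TimingClass.UNINFORMATIVE)]:
            m = mut(10, 60)
            m.multiplicity = m_val
            assert pc.classify_timing(m, seg, 2) is expected

    def test_no_wgd_is_an_error(self):
        m = mut(10, 60)
        m.multiplicity = 1
        with pytest.raises(ValidationError):
            pc.classify_timing(m, self.seg22(), 0)


class TestEstimator:
    def test_all_early_limit(self, tetraploid_profile):
        pi = pc.estimate_wgd_time(classified(50, 0), tetraploid_profile, 1)
        assert pi[0] == pytest.approx(1.0)

    def test_all_late_limit(self, tetraploid_profile):
        pi = pc.estimate_wgd_time(classified(0, 50), tetraploid_profile, 1)
        assert pi[0] == pytest.approx(0.0)

    def test_one_wgd_closed_form(self, tetraploid_profile):
        # N2=5, N1=10 -> 2*5/(2*5+10) = 0.5
        pi = pc.estimate_wgd_time(classified(5, 10), tetraploid_profile, 1)
        assert pi[0] == pytest.approx(0.5)

    def test_two_wgd_closed_form(self, tetraploid_profile):
        # N4=4, N2=4, N1=8: D=4, pi1=0.5, pi2=0.75
        pi = pc.estimate_wgd_time(classified(4, 8, n_mid=4), tetraploid_profile, 2)
        assert pi[0] == pytest.approx(0.5)
        assert pi[1] == pytest.approx(0.75)

    def test_no_informative_mutations_errors_with_counts(self, tetraploid_profile):
        with pytest.raises(TimingError, match=r"\[0, 0\]"):
            pc.estimate_wgd_time(classified(0, 0), tetraploid_profile, 1)

    @given(n2=st.integers(0, 500), n1=st.integers(0, 500))
    @settings(deadline=None, max_examples=80)
    def test_pi_in_unit_interval_and_monotone_in_n2(self, n2, n1):
        if n2 + n1 == 0:
            return
        pi = float(_pi_from_counts(1, np.array([n2, n1]))[0])
        assert 0.0 <= pi <= 1.0
        pi_up = float(_pi_from_counts(1, np.array([n2 + 1, n1]))[0])
        assert pi_up > pi or pi == 1.0

    @given(n4=st.integers(0, 200), n2=st.integers(0, 200), n1=st.integers(0, 200))
    @settings(deadline=None, max_examples=80)
    def test_first_doubling_never_after_second(self, n4, n2, n1):
        if n4 + n2 + n1 == 0:
            return
        pi = _pi_from_counts(2, np.array([n4, n2, n1]))
        assert pi[0] <= pi[1] + 1e-12


class TestBootstrap:
    def test_degenerate_ci_when_all_one_class(self, tetraploid_profile):
        ci = bootstrap_ci(classified(40, 0), tetraploid_profile, 1, seed=1)
        assert ci[0, 0] == ci[0, 1] == 1.0

    def test_single_resample_ci_collapses(self, tetraploid_profile):
        ci = bootstrap_ci(classified(5, 10), tetraploid_profile, 1,
                          n_bootstrap=1, seed=3)
        assert ci[0, 0] == ci[0, 1]

    def test_deterministic_given_seed(self, tetraploid_profile):
        muts = classified(50, 80)
        a = bootstrap_ci(muts, tetraploid_profile, 1, seed=11)
        b = bootstrap_ci(muts, tetraploid_profile, 1, seed=11)
        assert np.array_equal(a, b)

    def test_width_shrinks_with_sample_size(self, tetraploid_profile):
        widths = []
        for n in (100, 1000, 10000):
            muts = classified(n // 3, n - n // 3)
            ci = bootstrap_ci(muts, tetraploid_profile, 1, n_bootstrap=400, seed=5)
            widths.append(float(ci[0, 1] - ci[0, 0]))
        assert widths[0] > widths[1] > widths[2]


class TestRealTime:
    def test_midpoint_at_age_66(self):
        meta = SampleMeta("s", 66.0, 0.7)
        years, (lo, hi) = pc.to_real_time(0.5, (0.4, 0.6), meta)
        assert years == pytest.approx(33.0)
        assert (lo, hi) == (pytest.approx(0.4 * 66), pytest.approx(0.6 * 66))

    def test_boundaries(self):
        meta = SampleMeta("s", 70.0, 1.0)
        assert pc.to_real_time(1.0, (1.0, 1.0), meta)[0] == 0.0
        assert pc.to_real_time(0.0, (0.0, 0.0), meta)[0] == 70.0

    def test_out_of_range_pi_rejected(self):
        meta = SampleMeta("s", 66.0, 1.0)
        with pytest.raises(ValidationError):
            pc.to_real_time(1.2, (1.0, 1.3), meta)


class TestModelFit:
    def test_recovers_simulated_doubling_time(self, simulated_tumor):
        truth, profile, _, muts = simulated_tumor
        call = pc.call_wgd(profile)
        assert call.n_wgd == 1
        res = pc.WGDTimingModel(muts, profile, 1,
                                SampleMeta("sim", 66.0, truth.purity)).fit(seed=0)
        assert res.pi[0] == pytest.approx(truth.wgd_times[0], abs=0.05)
        assert res.ci[0, 0] <= res.pi[0] <= res.ci[0, 1]
        years, (ylo, yhi) = res.years_before_diagnosis()[0]
        assert years == pytest.approx((1 - res.pi[0]) * 66.0)
        assert ylo <= years <= yhi

    def test_two_wgd_fit(self, genome):
        truth = pc.SimulationTruth(mutation_rate=120, wgd_times=(0.4, 0.7),
                                   purity=0.9, depth=80, seed=77)
        profile, log, muts = pc.simulate_tumor(genome, truth, n_cna=4)
        assert pc.call_wgd(profile).n_wgd == 2
        res = pc.WGDTimingModel(muts, profile, 2).fit(seed=0)
        assert res.pi[0] == pytest.approx(0.4, abs=0.07)
        assert res.pi[1] == pytest.approx(0.7, abs=0.07)
        assert res.pi[0] < res.pi[1]

    def test_summary_mentions_key_quantities(self, simulated_tumor):
        truth, profile, _, muts = simulated_tumor
        res = pc.WGDTimingModel(muts, profile, 1,
                                SampleMeta("sim", 66.0, truth.purity)).fit(seed=0)
        text = res.summary()
        assert "pi" in text and "years before diagnosis" in text
        assert f"{res.n_informative}" in text
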