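"""SCNA classification, ploidy, WGD calling and LOH reasoning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ploidyclock as pc
from helpers import uniform_profile
from ploidyclock.cn import LossWGDOrder, SCNAClass, scna_fractions
from ploidyclock.exceptions import EmptyProfileError, UncoveredLocusError


def seg(major, minor, chrom="chr1", start=0, end=1000):
    return pc.Segment(chrom, start, end, major, minor)


def half_half_profile(genome, state_a, state_b, purity=1.0):
    """First half of every chromosome in state_a, second half in state_b."""
    segs = []
    for c, l in genome.chromosomes:
        segs.append(pc.Segment(c, 0, l // 2, *state_a))
        segs.append(pc.Segment(c, l // 2, l, *state_b))
    return pc.SegmentProfile("hh", purity, segs, genome)


class TestClassifyScna:
    @pytest.mark.parametrize("major,minor,expected", [
        (1, 1, SCNAClass.NEUTRAL),
        (2, 0, SCNAClass.NEUTRAL_LOH),
        (1, 0, SCNAClass.HEMIZYGOUS),
        (0, 0, SCNAClass.HOM_DEL),
        (3, 0, SCNAClass.AMP_LOH),
        (2, 1, SCNAClass.GAIN),     # total 3 > 2 with retained minor
        (2, 2, SCNAClass.GAIN),
        (8, 1, SCNAClass.GAIN),
    ])
    def test_named_states(self, major, minor, expected):
        assert pc.classify_scna(seg(major, minor)) is expected

    def test_classes_partition_the_full_grid(self):
        """Every (major, minor) pair in [0..8]^2 gets exactly one class."""
        for major in range(9):
            for minor in range(major + 1):
                cls = pc.classify_scna(seg(major, minor))
                assert isinstance(cls, SCNAClass)

    def test_fractions_sum_to_one(self, genome):
        prof = half_half_profile(genome, (2, 0), (1, 1))
        fr = scna_fractions(prof)
        assert sum(fr.values()) == pytest.approx(1.0)
        assert fr["Neutral-LoH"] == pytest.approx(0.5)
        assert fr["Neutral"] == pytest.approx(0.5)


class TestGenomeFraction:
    def test_uniform_diploid_no_loh(self, diploid_profile):
        assert pc.genome_fraction(diploid_profile, lambda s: s.minor_cn == 0) == 0.0

    def test_length_weighting(self, genome):
        prof = half_half_profile(genome, (2, 0), (1, 1))
        assert pc.genome_fraction(prof, lambda s: s.minor_cn == 0) == pytest.approx(0.5)

    def test_always_true_gives_one(self, diploid_profile):
        assert pc.genome_fraction(diploid_profile, lambda s: True) == 1.0

    def test_complementary_predicates_sum_to_one(self, genome, rng):
        states = [(int(M), int(m)) for M in range(4) for m in range(M + 1)]
        segs = []
        pos = 0
        for i in range(12):
            ln = int(rng.integers(1, 10**6))
            M, m = states[rng.integers(len(states))]
            segs.append(pc.Segment("chr1", pos, pos + ln, M, m))
            pos += ln
        prof = pc.SegmentProfile("r", 1.0, segs)
        pred = lambda s: s.total_cn >= 3
        a = pc.genome_fraction(prof, pred)
        b = pc.genome_fraction(prof, lambda s: not pred(s))
        assert a + b == pytest.approx(1.0)

    def test_empty_profile_errors(self):
        with pytest.raises(EmptyProfileError):
            pc.genome_fraction(pc.SegmentProfile("e", 1.0, []), lambda s: True)


class TestPloidy:
    @pytest.mark.parametrize("state,expected", [((1, 1), 2.0), ((2, 2), 4.0)])
    def test_uniform(self, genome, state, expected):
        assert pc.compute_ploidy(uniform_profile(genome, *state)) == pytest.approx(expected)

    def test_weighted_mean(self, genome):
        prof = half_half_profile(genome, (2, 2), (2, 1))
        assert pc.compute_ploidy(prof) == pytest.approx(3.5)


class TestCallWgd:
    def test_diploid_is_zero(self, diploid_profile):
        call = pc.call_wgd(diploid_profile)
        assert call.n_wgd == 0 and not call.polyploid

    def test_one_and_two_doublings(self, genome):
        assert pc.call_wgd(uniform_profile(genome, 2, 2)).n_wgd == 1
        assert pc.call_wgd(uniform_profile(genome, 4, 4)).n_wgd == 2

    def test_boundary_is_inclusive_at_half_genome(self, genome):
        prof = half_half_profile(genome, (2, 1), (1, 1))
        call = pc.call_wgd(prof)
        assert call.fraction_major_ge2 == pytest.approx(0.5)
        assert call.n_wgd == 1

    def test_just_below_half_is_no_wgd(self, genome):
        segs = []
        for c, l in genome.chromosomes:
            cut = l // 2 - 1000
            segs.append(pc.Segment(c, 0, cut, 2, 1))
            segs.append(pc.Segment(c, cut, l, 1, 1))
        assert pc.call_wgd(pc.SegmentProfile("b", 1.0, segs, genome)).n_wgd == 0

    def test_polyploid_flag_threshold(self, genome):
        # ploidy exactly 2.5: half (2,1), half (1,1)
        prof = half_half_profile(genome, (2, 1), (1, 1))
        call = pc.call_wgd(prof)
        assert call.ploidy == pytest.approx(2.5) and call.polyploid

    def test_fraction_ge4_never_exceeds_ge2(self, genome, rng):
        for _ in range(20):
            M, m = int(rng.integers(0, 6)), 0
            m = int(rng.integers(0, M + 1)) if M else 0
            call = pc.call_wgd(uniform_profile(genome, M, m)) if M + m else None
            if call:
                assert call.fraction_major_ge4 <= call.fraction_major_ge2

    def test_in_silico_doubling_never_decreases_call(self, genome, rng):
        """Doubling every segment's alleles is a WGD: the call must not drop
        and ploidy doubles exactly."""
        for seed in range(10):
            truth = pc.SimulationTruth(wgd_times=(0.5,) if seed % 2 else (), seed=seed)
            prof, _ = pc.simulate_cn_profile(genome, truth, n_cna=6, seed=seed)
            before = pc.call_wgd(prof)
            after = pc.call_wgd(prof.doubled())
            assert after.n_wgd >= before.n_wgd
            assert after.ploidy == pytest.approx(2 * before.ploidy)

    def test_recovers_simulated_wgd_count(self, genome):
        """Parameter recovery: the call matches the simulated number of
        doublings in >=95% of scenarios with limited post-WGD loss."""
        hits = trials = 0
        for seed in range(150):
            rng = np.random.default_rng(seed)
            n_wgd = seed % 3
            times = tuple(sorted(rng.uniform(0.2, 0.8, size=n_wgd)))
            if n_wgd == 2 and times[1] - times[0] < 0.05:
                continue
            truth = pc.SimulationTruth(wgd_times=times, seed=seed)
            prof, log = pc.simulate_cn_profile(genome, truth, n_cna=int(rng.integers(0, 12)))
            # condition: <=30% of genome under losses occurring after the last WGD
            last = max(times) if times else 0.0
            lost = sum(ev.end - ev.start for ev in log.events
                       if ev.kind == "segment_loss" and ev.time > last)
            if lost > 0.3 * genome.total_length:
                continue
            trials += 1
            hits += pc.call_wgd(prof).n_wgd == n_wgd
        assert trials >= 100
        assert hits / trials >= 0.95


class TestLohAndOrdering:
    def test_loh_inside_neutral_loh_segment(self, genome):
        prof = half_half_profile(genome, (2, 0), (2, 1))
        is_loh, hits = pc.loh_at_locus(prof, "chr1", 100, 200)
        assert is_loh and len(hits) == 1

    def test_no_loh_with_retained_minor(self, genome):
        prof = half_half_profile(genome, (2, 0), (2, 1))
        mid = genome.length("chr1") // 2
        assert pc.loh_at_locus(prof, "chr1", mid + 10, mid + 20)[0] is False

    def test_locus_spanning_boundary_needs_all_segments_loh(self, genome):
        prof = half_half_profile(genome, (2, 0), (2, 1))
        mid = genome.length("chr1") // 2
        assert pc.loh_at_locus(prof, "chr1", mid - 10, mid + 10)[0] is False

    def test_uncovered_locus_is_an_error_not_false(self, genome):
        segs = [pc.Segment("chr1", 0, 1000, 2, 0)]
        prof = pc.SegmentProfile("g", 1.0, segs, genome)
        with pytest.raises(UncoveredLocusError):
            pc.loh_at_locus(prof, "chr1", 5000, 6000)

    def test_duplicated_retained_allele_implies_loss_first(self, genome):
        # doubled genome with an LOH locus at major 2: one loss then WGD
        prof = half_half_profile(genome, (2, 0), (2, 2))
        assert (pc.infer_loss_vs_wgd_order(prof, "chr1", 10, 20)
                is LossWGDOrder.LOSS_BEFORE_WGD_LIKELY)

    def test_single_retained_copy_leaves_order_open(self, genome):
        prof = half_half_profile(genome, (1, 0), (2, 2))
        assert (pc.infer_loss_vs_wgd_order(prof, "chr1", 10, 20)
                is LossWGDOrder.LOSS_AFTER_WGD_POSSIBLE)

    def test_diploid_sample_reports_no_wgd(self, genome):
        prof = half_half_profile(genome, (1, 0), (1, 1))
        assert pc.infer_loss_vs_wgd_order(prof, "chr1", 10, 20) is LossWGDOrder.NO_WGD

    def test_heterozygous_locus_in_doubled_genome(self, tetraploid_profile):
        assert (pc.infer_loss_vs_wgd_order(tetraploid_profile, "chr1", 0, 100)
                is LossWGDOrder.NO_LOH)


@given(major=st.integers(0, 8), minor=st.integers(0, 8))
@settings(deadline=None, max_examples=60)
def test_classification_matches_definition_table(major, minor):
    """Property: the class follows the (total, minor) definition table
    for every representable state."""
    if minor > major:
        major, minor = minor, major
    if major == 0 and minor == 0:
        expected = SCNAClass.HOM_DEL
    elif major + minor == 1:
        expected = SCNAClass.HEMIZYGOUS
    elif major + minor == 2:
        expected = SCNAClass.NEUTRAL if minor == 1 else SCNAClass.NEUTRAL_LOH
    elif minor == 0:
        expected = SCNAClass.AMP_LOH
    else:
        expected = SCNAClass.GAIN
    assert pc.classify_scna(seg(major, minor)) is expected
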