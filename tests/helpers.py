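import ploidyclock as pc


def uniform_profile(genome, major, minor, purity=1.0, sample="p"):
    """Whole-genome constant (major, minor) profile."""
    segs = [pc.Segment(c, 0, l, major, minor) for c, l in genome.chromosomes]
    return pc.SegmentProfile(sample, purity, segs, genome)
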