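# Methods

## Scope and model

`ploidyclock` analyses a clonal tumor genome through four connected
stages: (i) multi-caller consensus filtering of somatic SNV and SV
calls, (ii) allele-specific copy-number reasoning (SCNA classes, LOH,
ploidy, whole-genome-doubling detection), (iii) mutation-clock timing
of the doubling(s) with bootstrap confidence intervals and conversion
to years before diagnosis, and (iv) chromosome-level karyotyping of
cell clones from low-pass binned coverage. A simulator with a fully
known evolutionary history backs every stage, because the kind of
patient-level sequencing data this pipeline targets is generally not
publicly sharable.

The central assumptions, taken literally throughout:

* **Single clonal population.** Every somatic mutation is present in
  all tumor cells (cancer cell fraction 1). No subclonal
  deconvolution.
* **Constant mutation clock.** Point mutations accumulate at a
  constant rate *per chromosome copy* from the patient's birth
  (molecular time 0) to diagnosis (time 1), so molecular time maps
  linearly onto chronological age. No pre-malignant/malignant rate
  change is modeled.
* **Integer allele-specific copy numbers.** Segment profiles carry
  integer (major, minor) copy numbers, as produced by consensus
  copy-number callers; real-valued input must be rounded upstream
  (round half-up).

## Copy-number stage

**SCNA classes.** Each segment is classified from (total, minor) copy
number: Neutral (2, minor 1), Neutral-LoH (2, minor 0), Hemizygous
(total 1), Hom-del (total 0), Amp-LoH (total > 2, minor 0). These five
classes do not cover total > 2 with a retained minor allele; we assign
that region a sixth class, **Gain**, reported separately so the five
conventional classes remain bit-comparable.

**Ploidy** is the length-weighted mean total copy number over the
covered genome; a sample is flagged polyploid at ploidy >= 2.5
(inclusive). Uncovered genome is excluded from every denominator.

**WGD calling.** One doubling is called when the major allele is >= 2
over at least 50% of the covered genome (inclusive boundary). The
second doubling generalises the same rule to major >= 4 (= 2^k for the
k-th doubling). The 2^k generalisation is our design choice: it is the
only extension consistent with the printed one-doubling rule, and it
is monotone under in-silico doubling (doubling every segment never
decreases the call — a property test). At most two doublings are
modeled.

**Loss-versus-WGD ordering.** At an LOH locus in a doubled genome,
major >= 2 means the retained allele was itself duplicated: a single
loss before the doubling explains the state, whereas loss after
doubling would require two independent losses of the same parental
allele. The verdict is deliberately phrased as *likely* / *possible* —
it is a parsimony argument, not a proof.

## Consensus stage

SNVs/indels match by exact (chrom, pos, ref, alt) and are kept when
called by >= 2 distinct callers (of typically 3). SVs match when type,
chromosome pair and strand pair agree and both breakpoints lie within
±100 bp (inclusive); matching records are single-linkage clustered and
a cluster is kept when it contains >= 2 distinct callers (of typically
4). Support counts distinct callers, never records. The cluster
representative takes the coordinate-wise median breakpoint, lower
value on even counts, making the output deterministic and invariant
under callset permutation. The 100 bp window is a conventional SV
merging tolerance and is exposed as a parameter; reciprocal-overlap
matching is not implemented.

## Timing stage

**VAF model.** A clonal mutation on `m` of `C` tumor copies at purity
ρ has expected variant allele fraction

    φ(m) = m ρ / (ρ C + 2 (1 − ρ)).

**Multiplicity.** `m` is assigned per mutation by maximising the
binomial likelihood Binom(alt | depth, φ(m)) over m ∈ {1..major};
ties break to the smaller m; zero alt reads leave the mutation
unassigned.

**Informative states.** For one doubling, only segments at (2,2) and
(2,0) have unambiguous histories: a mutation at m = 2 must predate the
doubling, m = 1 must postdate it. (2,1) segments are excluded — their
histories are ambiguous. For two doublings only (4,4) segments are
used, with m = 4 / 2 / 1 mapping to before-both / between / after-both.

**Count estimator.** With a per-copy clock, a (2,2) region accrues
pre-doubling mutations at rate 2 and post-doubling mutations at rate
4, so E[N2] = 2π and E[N1] = 4(1−π); a (2,0) region gives E[N2] = π,
E[N1] = 2(1−π) (the lost allele's early mutations are gone). Both
solve to the same point estimate,

    π̂ = 2 N2 / (2 N2 + N1),

so counts pool across the two states. For two doublings in (4,4),
E[N4] = 2π₁, E[N2] = 4(π₂−π₁), E[N1] = 8(1−π₂); with
D = N4/2 + N2/4 + N1/8 the estimates are π̂₁ = (N4/2)/D and
π̂₂ = (N4/2 + N2/4)/D, which guarantees π̂₁ ≤ π̂₂. These algebras were
validated against the forward simulator before being frozen (true
multiplicities recover π without systematic bias).

**Misassignment correction.** At realistic depth (≈60×) and purity
(≈0.7), ML multiplicity calls confuse m = 1 and m = 2 a few percent of
the time in (2,2) regions. Because the classes are unbalanced, the
flows do not cancel: the raw count ratio is attenuated toward the
balanced point, biasing π̂ by ≈ +0.013 at π = 0.5 — larger than the
CI half-width at a few thousand informative mutations, which destroys
bootstrap coverage. Since the read model is fully specified, the
confusion probabilities P(assigned j | true i, depth) are computable
exactly; `WGDTimingModel.fit` averages them over the observed depth
distribution and deconvolves the count vector through the resulting
matrix (standard misclassification correction) before applying the
count estimator. The correction removes the bias (measured ≈ +0.0005)
and restores nominal CI coverage. It can be disabled
(`correct_misassignment=False`), and the module-level functions
(`estimate_wgd_time`, `bootstrap_ci`) implement the uncorrected,
raw-count contracts. When the confusion matrix is ill-conditioned
(nearly indistinguishable classes, e.g. very low purity), the
correction degrades gracefully to the raw counts.

**Bootstrap.** Percentile bootstrap: informative mutations are
resampled with replacement B = 1000 times (level 0.95 by default) and
π̂ recomputed each time. Because informative mutations are
exchangeable given their class, resampling is realised as a
multinomial draw over the class counts — identical in distribution
and vectorisable. The correction matrix is held fixed across
resamples (it is a smooth functional of the depth distribution).
Deterministic given a seed. BCa intervals were considered and
rejected: the percentile method is the simplest consistent with a
plain "bootstrap B times" prescription.

**Real time.** Under the linear clock, a doubling at molecular time π
in a patient diagnosed at age A occurred (1 − π)·A years before
diagnosis; CI endpoints map monotonically (and therefore swap).

## Clone karyotyping stage

Low-pass coverage is binned (default 50 kb); per-bin sample/reference
count ratios are median-scaled so the typical bin sits at the baseline
ploidy (default 4, the near-tetraploid clone setting), then refined:
the scale is re-estimated as the *mean* ratio over chromosomes whose
provisional modal call equals the baseline. The refinement matters
because the median of a skewed count-ratio distribution
underestimates its mean by a few percent at dispersion ≈ 0.1, enough
to shift borderline chromosomes by a whole copy. Zero-count reference
bins are masked; an error is raised when fewer than half the bins are
usable.

Segmentation is deliberately minimal (chromosome-scale calls do not
need CBS): median-smooth the per-bin estimates (window 5 bins), take
maximal runs of the rounded value, merge runs shorter than 10 bins
into the longer neighbour (shortest first; ties to the left), and
re-estimate each final segment's integer CN as the rounded mean of
the unrounded per-bin values — averaging across a segment is what
makes the call robust to per-bin noise. The chromosome's **modal copy
number** is the integer state with the greatest summed base-pair
length (lower CN on ties; we weight by base pairs, which coincides
with bin counts for uniform bins). A clone's alteration count is the
number of chromosomes whose modal CN differs from a reference clone's.

## Synthetic data: what it emulates and what it does not

The generator realises the stated world the estimators assume: a
diploid genome at birth; `n_cna` segmental one-allele gains/losses at
uniform random molecular times on random intervals (5–50% of a
chromosome); 0–2 genome-wide doublings at chosen times; mutations
arising at rate μ per diploid genome-equivalent per year, landing on
one chromosome copy extant at their time and inheriting every
subsequent duplication of that copy (true multiplicity = surviving
descendant copies; fully lost lineages are deleted); per-site depth
Poisson(D); alt reads Binomial(depth, φ); imperfect callers that keep
each true variant with a sensitivity and add Poisson false positives
at fresh positions; negative-binomial bin counts with variance
mean + dispersion·mean² (dispersion 0 yields exact rounded means so
tests can pin the noiseless signal).

Defaults are the cohort-scale values the pipeline targets: age at
diagnosis 66 years, purity 0.7, depth 60×, and μ = 50 mutations per
diploid genome per year — the last chosen once as a WGS-scale burden
(≈3300 total mutations by diagnosis, enough to give the ≥2000
informative mutations the recovery experiments assume); no reported
value fixes μ, so it is an explicit free parameter.

Deliberately not emulated: subclonal populations, sequencing error in
the base calls, mutational signatures, realistic SV breakpoint
mechanisms, chromothripsis, GC/mappability bias in bins, and caller
error modes that correlate across callers. A green recovery test
therefore establishes internal consistency of model + estimator, not
robustness to real-data artifacts outside the model.

## Numerical conventions and degenerate inputs

* Coordinates: VCF positions 1-based; segment/BED/bin intervals
  0-based half-open; CLI locus syntax `chrom:start-end` 1-based
  inclusive, converted at the boundary.
* Rounding of copy numbers: half-up (`floor(x + 0.5)`).
* Thresholds (50% genome fraction, ploidy 2.5, ±100 bp) are inclusive.
* Segment rows with major < minor are auto-swapped with a warning
  (the major allele is by definition the more amplified one);
  overlapping segments are an error naming the offenders.
* Empty profiles make fractions/ploidy errors, not zeros. An
  uncovered locus is an explicit "uncovered" error, never `False`.
* Timing with zero informative mutations raises with the diagnostic
  counts; a no-WGD sample skips the timing stage with a recorded
  reason rather than failing the run.
* All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give identical
  outputs, and pipeline reports contain no timestamps so reruns are
  byte-identical.

## Known limitations

* The two-doubling rule (major ≥ 2^k over half the genome) is a
  declared generalisation; heavily rearranged genomes can defeat it.
* Timing ignores (2,1) and other ambiguous states; tumors whose
  informative states are scarce get wide or unavailable intervals.
* The real-time conversion inherits the constant-rate assumption
  wholesale; any mutation-rate acceleration during tumor growth
  shifts the estimates toward diagnosis.
* Consensus SV matching uses breakpoint distance only (no reciprocal
  overlap), and genotype/FORMAT reconciliation is out of scope.
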