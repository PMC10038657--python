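# Methods

## Time scales and unit conventions

Sequentially-Markovian-coalescent tools report segment boundaries in
mutation-scaled time: a scaled time t corresponds to t/μ generations and
(t/μ)·g calendar years before the anchor year (default 2017, roughly the
collection date of the field samples this pipeline is modeled on; the
anchor is configurable). Tools differ by factors of two in how rates map to
population sizes, so the conventions are fixed once, in `coalescent`:

* Ne = 1/(2·λ₀₀·μ) diploid individuals, with λ₀₀ the within-population
  coalescence rate in scaled units;
* relative cross-coalescence rCCR = 2λ₀₁/(λ₀₀ + λ₁₁), near 0 for isolated
  populations and near 1 once merged;
* the open last segment is the string `inf` on disk, `numpy.inf` in memory;
* migration density m(t) is piecewise-constant within segments, so cumulative
  migration obeys M(right) = M(left) + m·width segment by segment.

## Clock calibration

The calibration treats the historical record of trans-Atlantic traffic
(counts in 25-year bins, 1500–1875) as the ground truth for the timing of the
out-of-Africa migration pulse, and asks which clock (μ, g) makes the
genomically inferred migration trajectory line up with it. Each trajectory
segment is mapped to a calendar interval, its migration mass (m·width)
spread uniformly in calendar time onto the record bins by overlap fraction,
and the match scored with the Bhattacharyya coefficient on the 25-year grid
(no interpolation onto a finer grid — the record's resolution is the
binding constraint).

Mass falling outside the record window is truncated before normalization by
default: migration mass older than 1500 reflects deeper population structure
rather than the trade itself, and the comparison is one of shapes within the
window. The alternative (dividing by total mass everywhere, so out-of-window
mass directly penalizes the overlap score) is available via
`truncate=False`.

Because calendar age depends on (μ, g) only through g/μ, the BC surface is
constant along rays of fixed μ/g; the surface scan (default grids μ ∈
[1e-9, 1e-8], 60 log-spaced; g ∈ [1/20, 1/10], 30 linear, spanning
plausible insect generation times) reports the ridge ratio, and
`calibrate_mu` fixes g and maximizes BC over μ with a 60-point log-spaced
coarse scan followed by golden-section refinement on log μ (relative
tolerance 1e-3). The procedure contains no randomness.

`rescale_calibrated_date` moves a calibrated calendar date to an alternative
mutation rate: dates scale as μ_old/μ_new at fixed g, which is how the
alternative "earlier pulse" and "later pulse" scenarios are explored.

## Synthetic-data generator

The generator produces every input with exact ground truth. What it emulates
— and deliberately does not — determines what passing tests mean for real
data.

* **Frequency panels.** Per site, an ancestral frequency p ~ U(0.05, 0.95)
  and two panel frequencies drawn independently from the Balding–Nichols
  beta Beta(p(1−F)/F, (1−p)(1−F)/F). F = 0.3 is the default differentiation,
  enough that a realistic fraction of sites passes the 0.3
  frequency-difference filter. Sampled-allele counts default to 20 per
  panel. Panels are drift-only: no linked selection, no ascertainment bias.
* **Admixed diploids.** Ancestry along each haplotype is simulated directly
  as the alternating exponential tract process in genetic distance that the
  single-pulse model predicts — specialist tracts Exp((1−α)T), generalist
  tracts Exp(αT), chromosome start state Bernoulli(α) — then mapped to bp
  through the recombination map. Alleles come from the local ancestry's
  panel frequency and are flipped with error rate 0.01 (matching the HMM's
  default ε). This is exactly the HMM's generative model, which is the
  point: it enables clean parameter-recovery tests. It is *not* a coalescent
  simulation — no drift in the admixed population, no tract-length
  correlations from pedigree structure — so recovery results bound what the
  method can do when its model is true, not its robustness to model
  violation. (An external coalescent simulator such as msprime can be
  substituted for the generator where that robustness matters.)
* **Genome scale.** Three 100-Mb chromosomes at 1 cM/Mb by default — a
  desk-scale stand-in for the species' three ~400-Mb chromosomes, keeping
  default test runs in seconds.
* **Migration trajectories.** A calendar density (a record histogram or a
  Gaussian pulse) is mapped into scaled time with a known clock and
  integrated onto a segment grid: the union of an n_segments (default 32)
  log-spaced grid with the images of the calendar bin edges. Aligning
  segment boundaries with bin edges makes the projection back onto the
  record grid *exact*, so the calibration round trip recovers the
  generating μ up to optimizer tolerance rather than binning error.
  Noise-free cumulative migration ends at exactly 1; multiplicative
  lognormal noise perturbs the shape but the total is renormalized.
* **Historical record.** A Gaussian bump over the fixed 15-bin 1500–1875
  grid, peaking late in the window (default 1775 ± 60 y) to mimic the
  documented 18th-century crescendo of traffic; counts are real-valued and
  sum exactly to the requested total.

All generators are deterministic given a seed.

## The ancestry HMM

States are specialist-allele dosage k ∈ {0, 1, 2}, ascending. The haploid
switch kernel Q(d) = e^(−dT)I + (1 − e^(−dT))Π (Π rows = (α, 1−α)) is
exactly semigroup-closed, and the diploid chain is the product of two
independent haploid chains collapsed to dosage — appropriate for unphased
genotypes and verified against Chapman–Kolmogorov to 1e-12. Emissions use
error-adjusted panel frequencies a = pA(1−ε) + (1−pA)ε (resp. b from pB):
dosage 2 emits Binomial(2, a), dosage 0 Binomial(2, b), dosage 1 the
cross-product; missing genotypes emit 1 in every state. ε defaults to 0.01.

Numerics: the forward/backward and likelihood kernels use per-site scaling
constants (numba-compiled) rather than log-sums at every cell; a pure
log-space reference implementation is kept and the two are asserted
equivalent to 1e-9 in the tests. Viterbi runs in log space with ties broken
toward lower dosage — conservative toward "no admixture". Tract bounds are
placed midway between the outermost inside-site and the first outside-site
(unbiased under uniform site placement; runs touching a chromosome end
extend to the chromosome bounds when lengths are supplied), and runs
shorter than `min_sites = 2` are suppressed. Both Viterbi paths and
posterior decodings are available; hard Viterbi calls are the default for
ancestry-proportion profiles.

**Site selection** keeps sites with |pA − pB| strictly greater than 0.3 and
at least 10 sampled alleles per panel, then thins greedily left-to-right so
consecutive retained sites are ≥ 10 kb apart.

**Pulse-age estimation.** T̂ maximizes the log-likelihood summed over
individuals (chromosomes as independent chains), via a 40-point log-spaced
coarse grid on [1, 10000] generations plus golden-section refinement on
log T; deterministic, with a flat-likelihood guard that warns and returns
the flagged midpoint. Masked regions (user-supplied BED, e.g. known
selection outliers) are excluded from timing estimation only; tract decoding
and visualization always run unmasked.

**Block bootstrap.** Sites are partitioned into contiguous blocks of 1000
within each chromosome; each of 80 replicates redraws that many blocks with
replacement. Resampled blocks are scored as independent chains started from
the stationary distribution, which makes the replicate log-likelihood
additive over blocks; per-block log-likelihoods are therefore precomputed on
a dense (120-point) log grid in T once, and each replicate's age is the
grid argmax of a weighted block sum refined by local parabolic
interpolation in log T. The 95% interval is the 2.5/97.5 percentile of
replicate ages, widened if necessary to contain the full-data point
estimate (with few blocks a raw percentile interval can exclude it). When a
chromosome holds fewer than two default-size blocks, the model-level `fit`
shrinks the block size so ~8 blocks remain; the low-level function instead
raises.

**Admixture proportion.** Where α is not supplied (the field workflow takes
it from an external genome-wide estimate), `estimate_alpha` iterates: refresh
T on a coarse grid, update α to the mean posterior dosage / 2, stop at
|Δα| < 1e-4 (≤ 50 iterations, warning on non-convergence). Per-chromosome α
and T are reported, plus the cross-chromosome mean.

## f3 and the permutation test

The f3 statistic uses the Patterson-style finite-sample correction on the
focal population, (pX−pA)(pX−pB) − pX(1−pX)/(nX−1), averaged over sites that
pass a pooled minor-allele-frequency filter (> 0.05) and have non-zero
samples everywhere. Standard errors come from a delete-one jackknife over
contiguous blocks of 500 SNPs (a SNP-count convention; block size is
configurable and the suite checks sensitivity to it indirectly through the
1/√blocks scaling of the SE).

The circular permutation test correlates two populations' per-site
local-ancestry proportions; each permutation rotates every chromosome of one
profile by an independent uniform offset (offset 0 included), preserving the
value multiset and within-chromosome autocorrelation while destroying
cross-population alignment. The test is one-sided for positive correlation
(the scientific hypothesis is excess similarity); two-sided is available.
p-values use the add-one convention (1 + #{null ≥ obs})/(1 + n_perm), so the
smallest attainable p at 1000 permutations is 1/1001 ≈ 0.001.

## Power simulations

Heterozygous donor tracts of 500 kb, 1 Mb, 2 Mb and 10 Mb are implanted at
uniform non-overlapping positions (5 per chromosome, rejection-sampled with
a 1000-attempt cap) onto an unadmixed background; inside a tract the
simulated genotype is one background allele plus the donor haplotype allele
(the exact phased rule when background haplotypes are available, a seeded
Bernoulli(g/2) draw otherwise). Sensitivity and precision are pooled at
base-pair level over replicates with half-open interval arithmetic, so
sensitivity and the false-negative fraction sum to one exactly. Sites called
specialist in ≥ 95% of replicates are emitted as recurrent regions — the
signature of genuine low-level specialist ancestry segregating in the
background rather than placement-specific artifacts. Per-replicate seeds are
split deterministically from the master seed.

## Problem sizes in the shipped tests

The acceptance suite runs the pulse-dating recovery at 1,500 sites × 3
chromosomes × 15 diploids with 100 seeded replicates of the 80-resample
bootstrap, the permutation experiments at 3 × 500 loci, and the power scan
at 20 replicates per tract length — sizes chosen so the full suite completes
in well under a minute of compute after JIT warm-up while leaving the
statistical assertions comfortably powered.

## Known limitations

* The single-pulse model is both the simulator and the estimator; real
  admixture histories with continuous migration or multiple pulses will
  bias T̂ toward an effective average.
* Viterbi-based ancestry profiles shrink toward the modal state; at sparse
  site spacing the mean profile under-estimates α by a few percent (the
  posterior-mean profile does not, and is available).
* The f3 jackknife uses equal-weight delete-one blocks; with a short
  terminal block the SE is very slightly conservative.
* The calibration assumes the migration pulse and the historical record
  describe the same episode; if peak migration actually preceded or
  postdated the record's peak, μ̂ shifts proportionally (the rescaling
  helper quantifies exactly this).
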