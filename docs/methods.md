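# Methods

This note documents the statistical models, parameter defaults, numerical
choices and known limitations of the methmap pipeline. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinates and input handling

All coordinates are 0-based half-open internally (BED convention).
Bismark coverage files are treated as 1-based inclusive and converted at
the reader boundary; bedGraph-with-counts tables are taken as 0-based.
Chromosome names are compared as exact strings — no "chr" aliasing — so a
mixed-convention input fails loudly rather than silently mismatching
coordinates. CpGs with zero total reads carry no methylation level and
are dropped at read time with a logged count; duplicate positions are an
error (they usually indicate an unmerged strand-resolved file). Whether
CpG dyads should be strand-collapsed before analysis is left to the
upstream caller: the readers take positions as given, and the supported
dialects report one record per CpG.

## HMR segmentation

A two-state first-order HMM runs over each chromosome's ordered CpG
sequence. Emissions are beta-binomial: state *s* has parameters
(a_s, b_s) and emits `m ~ BetaBinomial(n; a_s, b_s)` for a CpG with `n`
total reads. Beta-binomial rather than binomial emissions matter at low
coverage (6–15x): per-CpG levels scatter around each state's mean with
biological overdispersion, and a binomial model misreads that scatter as
state switching.

Fitting is Baum–Welch EM. Start/transition updates are the closed-form
expected counts; the emission M-step maximises the posterior-weighted
beta-binomial log-likelihood in (log a, log b) by L-BFGS-B with analytic
gradients (digamma identities), warm-started from the previous iterate
and bounded to log-parameters in [-7, 12]. Observed (m, n) pairs are
aggregated to unique values first, so the M-step cost is independent of
chromosome length. EM stops when the absolute log-likelihood gain falls
below 1e-4 or after 200 iterations; on failure to improve, one restart
from a seeded, perturbed initialisation is attempted. Initial state
means are (0.1, 0.8) with beta strength 10; the label *hypomethylated*
is assigned after fitting to the state with the smaller emission mean,
which makes the decoded segmentation invariant to swapping the
initial means (verified by test).

Decoding is posterior (P(state) > 0.5) by default — it gives more stable
boundaries for short regions than Viterbi, which is available as an
option. Maximal hypomethylated runs are split where consecutive CpGs lie
more than 5 kb apart (so calls never bridge unsequenced deserts), runs
with fewer than 10 CpGs are discarded, and the HMR interval spans the
first CpG to the last CpG + 2, covering the closing dinucleotide. If the
two fitted states collapse onto one emission mean (difference < 1e-3)
the sample is effectively single-state and is decoded by thresholding
that mean at 0.5: an all-unmethylated input yields one whole-chromosome
HMR per chromosome, an all-methylated input yields none.

The forward–backward recursion is written with explicit loops and scaled
probabilities; numba JIT-compiles it when importable, and a pure-numpy
reference implementation with identical arithmetic is kept and
cross-checked in the tests.

PMD-like blocks (large, intermediately methylated domains typical of
cancer methylomes) are separated from focal HMRs by a simple predicate:
length > 1500 bp and mean level within [0.3, 0.7].

## Smoothing and confidence bands

For each CpG a symmetric window grows from a 1 kb half-width until it
contains at least 20 CpGs (both configurable). The smoothed level is the
tricube-weighted binomial proportion p̂ = Σw·m / Σw·n. The 95% band is a
Wilson score interval evaluated at the Kish effective read count
n_eff = (Σwn)² / Σ(w²n) rather than the raw weighted total Σwn: for
unequal weights, Σwn misstates the sampling variance of p̂
(Var p̂ = Σw²n·p(1−p)/(Σwn)², i.e. exactly p(1−p)/n_eff), and using it
would make the band cover a smooth truth at ~98% instead of the nominal
95%. Wilson rather than Wald keeps the band honest near 0 and 1, where
HMR interiors live. Monte-Carlo calibration (200 replicates of a
sinusoidal truth at 15x, in the acceptance suite) measures ~95.0%
pointwise coverage at interior CpGs. Chromosomes with fewer CpGs than the
window minimum are returned unsmoothed with raw per-site Wilson bands and
a warning.

## DMR calling

Two smoothed profiles are first intersected on their shared CpG
positions (dropped positions are logged, not imputed). A CpG is
*separated* when the two 95% bands are disjoint — strictly, not touching
— with the direction given by which band lies above. Maximal
constant-direction runs of at least 6 separated CpGs ("more than five")
become DMRs; the interval convention matches HMRs (last CpG + 2).
Calling is antisymmetric by construction: swapping the samples flips
every direction and changes nothing else.

Two calibration facts, both measured by the acceptance suite at 2000
CpGs / 100 bp spacing / 20x coverage:

- *Power*: a planted 12-CpG region with a 0.6 methylation difference is
  detected in ≥95/100 replicates (100/100 in our runs). Called
  boundaries systematically overshoot the planted edges by ~4 CpGs per
  side, because the ~21-CpG kernel spreads a 12-CpG step across the
  window; boundary positions from this caller should be read as
  window-blurred, not base-precise.
- *Null behaviour*: the same-truth false-call rate is ~3×10⁻⁴ per CpG
  (roughly half of 2000-CpG replicate pairs show at least one false
  DMR). This is a structural property of the predicate: band
  disjointness at one CpG requires the difference of the two estimates
  to exceed ~2.8 of its own standard deviations, and since the smoother
  correlates ~20 consecutive CpGs, any such fluctuation automatically
  spans a ≥6-CpG run, so the run-length filter adds almost no additional
  protection. The rate is also scale-free in the window size (threshold
  and dispersion shrink together). Users needing stringent genome-wide
  null control should treat DMR calls as candidates and apply their own
  replication or FDR layer; widening the bands would break their
  pointwise calibration.

`global_stats` computes per-CpG cross-sample standard deviations on the
CpGs covered at ≥5 reads in every sample (and the fraction exceeding
0.1, the conventional variability cut), `neighbor_correlation` the
Pearson r of adjacent CpG levels within a distance cut, and
`interval_methylation_compare` per-region two-sample Student t-tests on
per-sample region means.

## Catalogs

c-HMRs intersect first, then merge across ≤100 bp gaps — the order is a
documented choice (merging first could bridge a gap in one tissue with
another tissue's coverage and manufacture common bases that no tissue
fully covers). ">50% of tissues" for frequent HMRs is strict
(> 0.5·T, i.e. ≥5 of 8), t-HMR specificity is any-shared-base
(half-open), and both partition invariants (t-HMRs share zero bases with
other tissues' HMRs; frequent and common share zero bases) are asserted
on every build. Interval enrichment tiles the universe at 100 bp (a tile
counts as hit when it shares ≥1 base) before the Fisher exact test, so
adjacent bases are not pseudo-replicated. Promoters default to TSS ± 1 kb
in the synthetic designs; co-activation calls a promoter active when its
state is hypomethylated (for mean-level inputs, the ≤30% rule, the one
stated hypomethylation threshold in the cohort stage, is reused).

## Cohort stage

Thresholds are literal: confirmation needs >5 probes (≥6) and mean beta
≤0.30 in *all* normal samples; events need mean beta strictly >0.33 in
≥25% of cancer samples; candidates need ≥2 probes, a promoter flag, and
beta >0.50 in strictly >1% of (optionally solid-only) cancer samples.
Missing betas are excluded pairwise; an HMR-sample mean requires ≥1
non-missing probe. Event frequency denominators are pooled across all
cancer samples by default with a per-type mode (pass the type's samples
as `cancer_samples`); per-type is what a planted per-type design
exercises, since pooling divides each type's frequency by the number of
types. Clustering dichotomises at 0.33, computes Jaccard distances on
the binary sample vectors (two all-zero vectors have distance 0) and
applies Ward agglomeration; samples are sorted by id first so tie
handling is deterministic, and the dendrogram exports to Newick.
Validation sweeps a hypomethylation threshold over t-HMR mean betas,
scoring tissue-matched calls as true positives and unmatched as false
positives, with AUC by trapezoid over the swept (FPR, sensitivity)
points closed at (0,0) and (1,1).

## Mutual exclusivity

Coverage (samples hit in ≥1 set gene) is compared to a null that
preserves each gene's alteration count and respects the per-sample total
alteration burden: each gene's k altered samples are redrawn by weighted
sampling without replacement with weights proportional to burden over
*all* genes (not just the tested set, so the tested genes do not
dominate their own null). Zero-burden samples remain reachable through a
pseudo-burden ε = 0.01 — with ε = 0 the null concentrates entirely on
already-altered samples, which overstates exclusivity when the matrix
contains few genes. Sampling uses the Gumbel-top-k construction
(equivalent to sequential weighted draws without replacement), which
vectorises across the 10⁵ default simulations and is verified against
exhaustive enumeration on small matrices. The empirical p uses +1
smoothing, p = (1 + #{sim ≥ obs})/(n_sims + 1), so it is never zero, and
z is computed on raw coverage. Measured calibration (acceptance suite):
type-I error 0.0575 at nominal 0.05 over 400 burden-heterogeneous null
datasets. The per-stratum scan runs the test within each cancer type
(strata under 5 samples are skipped) and pooled.

## Synthetic data

The generator plants the ground truth every stage is tested against.
Defaults model a desk-scale study: 2 chromosomes × 2 Mb with background
CpGs at ~100 bp mean spacing and CpG islands of 50–200 CpGs at ~10 bp
spacing at planted regulatory sites (~56k CpGs total); per-CpG true
levels Beta(7.5, 2.5) in the background (mean 0.75, matching the 70–80%
global methylation of normal somatic tissue) and Beta(1, 19) inside
planted HMRs (mean 0.05); read depths zero-truncated Poisson at a
configurable mean (default 15x, within the 6–25x range of real WGBS
studies) with binomial methylated-read sampling. Site roles (shared /
frequent / tissue-specific / inert) are assigned so the planted truth
satisfies the catalog algebra exactly, and sites are spaced far beyond
the 100 bp merge gap so merging cannot fuse distinct planted regions.
Cancer series add partially methylated blocks (100–250 kb at level ~0.5
with heterogeneity noise), focal hypermethylation of chosen c-HMR sites
and a global background shift; the metastasis inherits and extends the
primary's alterations so planted global means decrease strictly.

Beta cohorts draw per-HMR hypomethylated baselines from U(0.05, 0.15),
plant per-type disjoint event HMR sets — a few near-universal
"signature" events (frequency 0.9, the cancer-type fingerprint that
makes type blocks clusterable) plus rarer events at the configured
frequency (default 0.30) — and add truncated Gaussian probe noise
(default sd 0.05). Event carriers are drawn as *exact* sample counts
(round(f·n)), not Bernoulli, so recorded truth frequencies are exact and
"recovered exactly at the default thresholds" is a well-posed check.
Alteration matrices are independent Bernoulli(rate_g × multiplier_s) in
null mode and draw within-set carriers disjointly in exclusive mode.

What the generator does **not** model — and hence what passing tests do
not certify about real data: sequence context and bisulfite conversion
error, copy-number effects on coverage, cell-type mixture within a
sample, spatially varying CpG density beyond the two-scale
island/background process, array probe cross-reactivity, and batch
effects. Planted event intensities are noise-jittered constants, whereas
real tumors show continuous intensity spectra.

## Reproducibility and problem sizes

All randomness flows from one root seed through named `SeedSequence`
substreams; every generator is bit-reproducible given its seed, and the
pipeline manifest records parameters, seeds and SHA-256 checksums of all
outputs (verified byte-identical across reruns in the tests). The test
and acceptance runs use desk-scale problems chosen to exercise every
code path at full statistical fidelity: ~56k-CpG methylomes for
segmentation, 2000-CpG × 100-replicate Monte-Carlo for DMR calibration,
200 replicates for band coverage, a 12-type × 25-sample beta cohort, and
10⁵-simulation mutual-exclusivity tests.
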