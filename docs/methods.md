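# Methods

## The estimation problem

A sewage sample collected near its sources is, to first approximation, an
equal-weight mixture of the gut microbiomes of the n people who contributed
to it: if host i has relative-abundance profile
X_i = (X_{i,1}, …, X_{i,p}), the ideal mixture is
X̄_n = (X_1 + … + X_n)/n.  The hosts are unobserved; only the mixture is.
Because averaging n i.i.d. profiles shrinks every taxon's variance by 1/n,
the typical distance of the mixture from the population mean carries
information about n, and `microcensus` turns that into a point estimate and
a one-sided confidence interval for the number of contributors.

## The census statistic

For a reference cohort of n₀ single-host profiles, the package estimates a
per-taxon mean μ̂_j (cohort average) and standard deviation
σ̂_j = sqrt(Σ_i (X_{i,j} − X̄_j)² / n₀) (population divisor n₀, not
n₀ − 1, so that σ̂² is the plug-in second moment).  For a query profile w
restricted to the p selected taxa,

    T(w) = Σ_j ((w_j − μ̂_j) / σ̂_j)².

This is a diagonal-covariance Hotelling-type quantity: with a diagonal
cohort covariance the classical Hotelling T² equals n·T.  The full
covariance is deliberately not estimated — with p in the hundreds and
cohorts of ~10³ hosts the sample covariance is singular or
ill-conditioned, while its diagonal is estimable coordinate by coordinate.
The statistic therefore ignores inter-taxon correlation; the validation
suite exercises it on compositional cohorts whose closure to the simplex
induces mild negative correlation, precisely to confirm the procedure
tolerates it.

Two asymptotic facts anchor the method, and are checked empirically rather
than proved here: (i) with true parameters and independent standardized
coordinates with finite moments, n·T_n converges to a chi-square law with p
degrees of freedom (so E[n·T_n] = p); (ii) the distribution of n·T_n is
asymptotically free of n, which is what makes a single pooled quantile
usable for interval estimation.

## Null distributions and maximum likelihood

For each candidate size n = 1..N the sampling law of T_n is simulated from
the reference cohort (B replicates per n), in one of two modes:

- **plain_bootstrap** (default): draw n hosts i.i.d. with replacement,
  average them, and evaluate T against μ̂, σ̂.  This is the estimation
  procedure proper.
- **subsample_corrected**: draw a without-replacement subset A of size n,
  center at the cohort mean, and store
  ‖σ̂⁻¹(X̄_A − X̄_{n₀})‖² / (1 − n/n₀).  The finite-population correction
  makes the empirical law of these values a consistent estimate of the
  law of T_n; the mode exists to cross-validate the bootstrap null and
  requires N < n₀.

The replicates are generated incrementally: each of the B chains keeps a
running sum extended by one freshly drawn host per candidate size (a random
permutation prefix in the subsample mode).  Every stored sample has exactly
the marginal law described above; samples are dependent across n within a
chain, which neither the per-n density estimate nor the pooled quantile
requires independence for.  The full grid then costs O(N·B·p) rather than
O(N²·B·p/2), which is what makes N = 300, B = 10,000 practical on a laptop.

Each per-n sample gets a Gaussian kernel density estimate with Silverman's
rule-of-thumb bandwidth (0.9·min(sd, IQR/1.34)·B^{−1/5}, floored at 1e−12;
an all-equal degenerate sample falls back to the floor and is logged).  The
bandwidth is recorded in the model archive for reproducibility.

Estimation evaluates the query statistic T₀ under each of the N densities
and reports n̂ = argmax (the discrete grid is searched exactly; no
interpolation), taking the smallest n on exact ties — conservative, in the
sense that the sample is at least that mixed.  Convention for the
degenerate query T₀ = 0 (profile exactly at the cohort mean): the KDE
argmax at 0 reflects bandwidths rather than likelihood, so the estimate is
reported as the most-mixed candidate N with a vacuous interval and a
warning.

## Confidence interval

Since n·T_n is asymptotically n-free, the package pools the n·T samples
across all candidate sizes, takes the empirical (1 − α) quantile q̂, and
reports the one-sided interval [1, q̂/T₀].  An alternative (quantile from
the null at n̂ only) is available behind a flag.  The pooled construction
is slightly conservative at large n and slightly anti-conservative at
small n, because small-n laws of n·T are heavier-tailed than the pooled
mixture before the limit kicks in: at nominal 95% the measured coverage on
the synthetic study conditions is ≈ 96% at n = 150 and ≈ 88% at n = 10,
≈ 92–93% across trials spanning n ∈ {10, 50, 150}.

## Features, tuning, and evaluation

Features are the top-k taxa by mean relative abundance over the reference
cohort (median available as an option), skipping taxa with zero
cross-sample variance, which would make the statistic undefined; ties break
lexicographically by taxon id so selection is deterministic.  k is tuned by
repeated 50–50 holdout validation inside the training half of a
subject-level split: fit on one half, estimate simulated mixtures from the
other half, keep the k with the lowest mean validation MAPE (smallest k on
ties).  Errors are δ = |n̂ − n|/n × 100% per prediction and MAPE, their
mean.  The benchmark refuses test subjects that were used to build the
null; training error (same-subject evaluation) is a separate, explicit
entry point.

## Sewage preprocessing

Raw sewage mixes gut organisms with water-matrix organisms.  The gut
filter keeps the smallest set of families that covers 99% of reference
cohort reads (ranked by read share), then removes Enterobacteriaceae and
Burkholderiaceae, which plausibly grow in tap water.  Samples are
renormalized over the retained taxa and the per-sample retained fraction is
reported as a diagnostic.  A Welch unequal-variance t-test then screens
individual OTUs, retaining those whose mean does not differ from the
reference cohort at raw p > α = 0.05.  No multiple-testing correction is
applied on purpose: the screen's role is to drop suspect features, and
correcting would retain more, not fewer.  Welch's test is exactly
calibrated under normal within-group errors and measurably conservative
under strong skew at small group sizes (rejection ≈ 0.036 instead of 0.05
at n = 25/side under a log-normal null in our measurements) — acceptable
for a screen that errs toward dropping.

## Species-abundance-distribution comparison

Multi-person communities for the SAD analysis are built by summing read
counts of the same taxa across hosts — distinct from the census mixture,
which averages relative abundances.  Five models are fit by maximum
likelihood to each community's abundance vector: continuous lognormal
(closed form), zero-truncated Poisson-lognormal (Gauss–Hermite quadrature,
order 50; Nelder–Mead over (meanlog, log sdlog)), Fisher's log-series
(solving S = α·ln(1 + N/α) for α, which is the ML condition given S and N),
MacArthur's broken stick (parameter-free), and a Zipf power law on ranks
with a multinomial likelihood (exponent bounded in (0.01, 20) for optimizer
stability).  Each fit predicts a rank-abundance distribution — closed form
for broken stick (E[rank i] = (N/S)·Σ_{k=i..S} 1/k) and Zipf, quantiles at
rank plotting positions for the others; the log-series quantile is computed
from the pmf cumulative sum directly because generic numeric inversion
stalls as the parameter approaches 1 in large summed communities; the
Poisson-lognormal quantile switches to its underlying lognormal when the
fitted scale is large enough that Poisson noise is negligible.

Goodness of fit is the R² of an OLS regression (with intercept) of observed
on predicted abundances, rank by rank, computed on log10 abundances — the
convention of rank-by-rank SAD evaluation in microbial macroecology.  The
log scale matters: community abundances span orders of magnitude, and a
linear-scale regression is dominated by the single first-rank point, which
in a large (nearly deterministic) community makes the measured R² mostly a
draw-specific accident.  On log scale the lognormal fit improves with
population size on every synthetic cohort tried (≈0.92 at single hosts
versus ≈0.99 at 100-person communities), for a mechanistically transparent
reason: at 4,000 reads per host the tail counts are small and discrete,
and summation smooths them.

## Sub-species (SNV) diversity

Per-sample allele counts over marker-gene sites feed two metrics: the
per-site heterozygosity h = D/(D−1)·(1 − Σ_a f_a²) with D the site depth
and f_a the allele fractions (the D/(D−1) factor makes h the exact
probability that two reads drawn without replacement differ), averaged over
covered sites (depth ≥ 2 by default) and then over genes to give nucleotide
diversity π; and the count of covered sites carrying at least one non-major
read (thresholds configurable).  Aggregating hosts sums allele counts
coordinate-wise; the growth of both metrics with the number of aggregated
hosts is simulated by without-replacement subsets.

The synthetic SNV generator gives each gene a pool of population haplotypes
derived from one reference sequence by substituting ~2% of sites per
haplotype, and each host carries one pool haplotype per gene.  The percent
divergence is essential realism: conspecific marker-gene strains differ at
percent scale, and independent random sequences (75% pairwise difference)
would saturate polymorphism with the second host, erasing the growth
phenomenon the module exists to study.  With near host-specific strains the
polymorphic-site count grows almost linearly over a wide size range
(Pearson r ≈ 0.95 between mean count and size on the study conditions)
while π, dominated by the frequency balance of the top haplotypes,
saturates quickly — so the count tracks population size more usefully than
π, and the normalized polymorphic-site curve sits below the normalized π
curve at every intermediate size.  By default hosts are clonal (no
within-host minor alleles), so single-host π is exactly 0 and every
observed polymorphism in an aggregate comes from between-host variation; a
noise rate is available to relax this.

## Synthetic cohorts

The cohort generator draws, per host and taxon, a zero-inflated log-normal
abundance and closes each host to the simplex.  Defaults emulate a
population-scale 16S gut survey: per-taxon log-means spread with standard
deviation 2 on the natural-log scale (heavy-tailed rank-abundance curve),
per-taxon log-standard-deviations uniform on [0.5, 2] (so different taxa's
mixture variances shrink at visibly different rates), zero-inflation 0.05.
Closure induces mild negative inter-taxon correlation, kept deliberately:
the census statistic ignores covariance and should be shown to tolerate it.
The generator returns its ground-truth parameters (with analytic
pre-closure moments) so tests can do parameter recovery against truth.
What the generator does not emulate: taxon-specific ecological correlation
structure, within-host temporal variation, geography- or diet-driven
subpopulations, and real cohorts' taxon-specific zero patterns — so
passing tests demonstrate the machinery and its asymptotics, not field
accuracy on any particular population.

## Validation protocols and problem sizes

`microcensus.protocols` packages the validation battery used by both the
test suite and `scripts/acceptance.py`; every run generates its inputs from
a single integer seed.  The chosen problem sizes keep the full battery to a
few minutes on one CPU: chi-square limit at p = 20, n = 200, 5,000
replicates; null-construction agreement at n = 20 on a 2,000-host cohort
(B = 4,000 per mode); monotonicity of the median statistic over
n ∈ {1, 5, 25, 100, 300} on both fixture presets (200×50 and 1,100×300);
parameter recovery on a 1,000-host, 120-taxon cohort with B = 2,000,
N = 300 and 200 queries at each of n ∈ {5, 25, 100} (measured overall MAPE
≈ 19–24% across seeds, medians within a few percent of truth); interval
coverage over 1,000 trials spanning n ∈ {10, 50, 150}; Welch calibration
over 5,000 null OTUs; SAD recovery at S = 500 plus the size trend at 50
repeats; and SNV growth on 60 hosts with a 30-haplotype pool.  Production
defaults remain B = 10,000, N = 300, k = 120, α = 0.05.

## Known limitations

- The model assumes an even, fresh mixture: unequal fecal loading, in-sewer
  growth/decay, and travel-time dispersion are not modeled.
- Accuracy hinges on μ̂, σ̂ estimated from a cohort exchangeable with the
  catchment population; a mismatched reference biases T₀ upward and the
  estimate downward, visibly so for large true n.
- The candidate grid tops out at N; truly larger populations are censored
  at N, and the subsampling theory wants N ≪ n₀ (a warning fires at
  N > n₀/3).
- The pooled-quantile interval undercovers somewhat at small true n (see
  above); callers who care most about small n can switch to the
  at-n̂ quantile flag.
- The polymorphic-site definitions (minor-allele count ≥ 1 at depth ≥ 2)
  are thresholds, not estimates; at high depth with sequencing error a
  stricter minor-allele threshold is advisable.
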