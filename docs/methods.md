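# Methods

## Scope and interfaces

`deltabind` consumes per-site binding scores that some footprint caller
has already computed for each (condition, replicate) pair, plus — for
ground-truth construction — per-site statistics tables from a
multi-condition ChIP-seq peak caller and a count-based differential test.
It does not process reads, call footprints, or run those upstream tools;
their outputs arrive as TSV. Everything downstream of the score table is
invariant to strictly increasing transforms of the scores, which is the
point of the rank standardisation: the method applies unchanged to any
scorer.

The bound condition must provide exactly two replicates (the
reproducibility fit is a bivariate model); the unbound condition one or
two. Rows with missing score cells are excluded from every model fit (the
count is logged) but are carried through to outputs with null
probabilities, so site bookkeeping never changes.

## Rank transform

Each replicate column is ranked within itself, rank N = strongest signal,
ties averaged (this preserves the column-sum invariant N(N+1)/2 that the
tests use). Ranking is genome-wide over the candidate set, not
per-chromosome. The probit map uses the plotting position r/(N+1) rather
than (r-1/2)/N: it is symmetric and finite at both extremes, and the
median rank maps to exactly zero. Rank direction is chosen so that the
"weaker in the unbound condition" event corresponds to a positive mean-rank
difference D = R_bound − R_unbound.

## Reproducibility model, P(A | R)

Probit-transformed replicate ranks (z1, z2) of the bound condition follow
a two-component bivariate normal mixture: background fixed at the standard
bivariate normal with correlation 0, signal N((mu, mu), sigma2*[[1, rho],
[rho, 1]]) with weight pi1, constrained to mu ≥ 0, 0 ≤ rho ≤ 0.999.
Estimation is plain EM (init pi1=0.5, mu=1, sigma2=1, rho=0.5; max 500
iterations; relative log-likelihood tolerance 1e-6); the observed-data
log-likelihood is recorded every iteration and is nondecreasing. A fit
whose mixing weight ends outside (1e-4, 1-1e-4) raises a degeneracy error
that carries the boundary estimates — the perfect-correlation limit
(duplicated replicate columns) lands here by design, with rho at its cap.

Because the probit of pooled ranks is a copula transform, the fitted
(pi1, mu, sigma2, rho) describe the rank-space shape of the data, not the
latent generative parameters of any particular simulation; parameter
recovery is therefore asserted on data simulated from the mixture itself,
while end-to-end runs assert ranking performance instead.

P(A | R) is obtained by isotonic regression of the per-site reproducible
posterior on the mean bound-condition rank. Isotonic regression was chosen
over binning because it is deterministic, monotone by construction,
interpolates monotone inputs exactly, and has no bandwidth parameter. The
pooled-adjacent-violators knots are stored with the model and evaluated by
linear interpolation with clipping at the ends.

A subtlety worth knowing: the posterior of the reproducible component is
monotone in z1+z2 only to the right of the vertex of the (quadratic)
diagonal log-odds, at z = −mu / (sigma2·(1+rho) − 1) when the bracket is
positive; in the far-left tail the wide correlated cluster is closer in
Mahalanobis distance than the standard normal and the posterior ticks up
again. The isotonic regression absorbs this harmlessly.

## Rank-difference mixture, P(B | A, R)

Within windows of bound-condition mean rank, the difference D is modelled
as a three-component Gaussian mixture with constrained means (0, +delta,
−delta): "no significant difference", "significantly weaker unbound"
(the event of interest) and its mirror. The null spread sigma0 and the
tied shifted spread sigma1 are free; all of (weights, delta, sigma0,
sigma1) are per-window. Gaussians with constrained means are the simplest
family that realises the three categories; the mirror category is fitted
for symmetry and reported, but only the +delta posterior feeds the final
score (the task is one-directional: bound in the bound condition, unbound
in the other).

Conditioning on the bound event is soft: each site enters the weighted EM
with its reproducibility posterior as case weight. This uses all sites,
avoids an arbitrary bound/unbound cutoff, and demonstrably prevents
zero-weight contamination from pulling the shifted component (tested).

Defaults: 20 windows over the rank-sorted sites, each holding 10% of
sites, starts spaced so consecutive windows overlap by about half;
EM init weights (0.8, 0.1, 0.1), delta initialised at the weighted SD of
D, spreads at half of it; max 500 iterations, tolerance 1e-6. Spread and
shift are floored at 1 rank unit — the spread floor guards degenerate
components, and flooring delta at the same value keeps the shifted
components distinguishable from the null in the all-ties limit (a shift
smaller than the minimum spread is not a significant difference; without
the floor the no-difference limit stalls at the EM init instead of
collapsing onto the null category). Windows whose summed case weight falls
below 50 borrow parameters from the nearest fitted window, with a warning;
on small cohorts (a few thousand sites) the low-rank windows routinely
borrow, which is harmless because P(A) is near zero there.

Posterior evaluation blends the two windows whose centers bracket the
site's mean bound rank linearly; outside the center range the nearest
window is used. Per-site category posteriors sum to one, and P(B) is
nondecreasing in D within a window.

## Final score and baselines

The differential score is exactly P(A|R) · P(B|A,R) per site. Output
ranking is by descending score with ties broken lexicographically by
site id, making runs reproducible across platforms. The two baselines are
the mean raw-score difference between conditions (replicates averaged on
the raw scale; the original could equally have used ranks, which the score
tables also expose) and the difference of precomputed window read counts.

## Ground-truth construction

High-confidence differential events are distilled from two independent
upstream analyses in a fixed, stage-wise order where each stage only
removes sites:

1. **Agreement stopping rule.** Walking down the multi-condition caller's
   differential ranking, the trailing-window proportion of sites agreeing
   with the count test (window 200 by default) is compared with (global
   maximum so far)/1.6; the walk stops at the first rank below threshold.
   The rule is evaluated only once a full window is available — with a
   partial window a single early disagreement after one agreement would
   trigger a spurious stop. The agreement column may be boolean or a
   precomputed local proportion. If the proportion never drops, all sites
   are kept and the event is logged.
2. **Threshold filter.** Keep sites with count-test p < 0.05, −log10 Q <
   2.5 in the unbound condition, −log10 Q > 2.5 in the bound condition,
   and a q-value contrast above 0.5 — all strict inequalities, applied
   exactly as stated.
3. **Motif proximity.** An event survives if some candidate motif site's
   center lies within 20 bp (center-to-center; the anchor choice is
   configurable) on the same chromosome; the nearest motif receives the
   label, equal distances break to the lexicographically smaller site id.

## Evaluation under extreme imbalance

AUPR is average precision without interpolation (tied score blocks
processed jointly) — standard, pessimistic, and well defined when
positives are 0.1–1% of sites; a random ranking's expected AUPR is the
prevalence, which anchors all null comparisons. Precision at recall r
reports the precision at the strictest threshold whose recall reaches r
(first crossing, not the maximum beyond r). AUROC is the Mann-Whitney
statistic with tie correction. Significance uses label permutation with
the add-one estimator p = (1 + #{permuted ≥ observed})/(1 + n_resamples),
which never returns zero; "bootstrap" significance in this setting is
under-specified, and permutation is the exchangeable null that matches the
question asked. The two-group factor-class comparison is a one-sided
permutation test on the difference of group means, exact whenever the
number of regroupings is enumerable. Curve and area computations delegate
to scikit-learn; the tests verify them against brute-force all-pairs and
threshold-sweep oracles.

The packaged CTCF/SNP contingency table (six integers) summarises a
published survey of allelic-SNP CTCF sites; `contingency_stats` reports
PPV/NPV of accessibility imbalance for differential binding and the two
marginal prevalences.

## Synthetic generator

The generator emulates the study conditions the method targets: 100,000
candidate sites, 0.4% planted differential, 10% bound in the bound
condition, and a reproducible cluster with mu = 2, sigma2 = 1, rho = 0.8
in probit units. A per-site latent strength s_i ~ N(mu, rho·sigma2) is
shared by all replicates and, for sites bound in both conditions, by both
conditions; replicate noise has variance (1−rho)·sigma2. This
decomposition reproduces the assumed reproducible cluster exactly
(marginal N(mu, sigma2), replicate correlation rho) and makes "no
significant rank difference" the typical bound-both behaviour, which is
the structure the rank-difference mixture assumes. Planted differential
sites keep their strength in the bound condition and are shifted down by
delta = 2 probit units in the unbound condition — i.e. they fall back to
the background mean. The shift is specified on the latent score scale
(scores are generated before ranks exist); the rank-scale shift that the
mixture estimates emerges from ranking the cohort.

Window read counts for the count-difference baseline are Poisson draws
whose log-rate is dominated by a per-site accessibility term (N(3,1),
shared by both conditions) plus condition-level accessibility noise
(sd 0.4) unrelated to binding, with the binding strength entering at
coefficient 0.15 — the footprint occupies a small fraction of the counting
window. This reproduces the qualitative field observation the package's
contingency fixture quantifies: accessibility imbalance is common and
mostly not differential binding.

Statistics tables for truth-pipeline testing draw null p-values uniform,
null −log10 q-values exponential (scale 0.5), and give planted positives
Beta(0.05, 20) p-values, a bound-condition −log10 q offset of 3.2 and a
differential score of N(6, 1) against a N(0, 1) null, so that positives
pass every stage with high probability while null leakage stays well
under the thresholds; event coordinates jitter up to 10 bp around their
motif centers. At these settings the full truth pipeline recovers ≥ 99% of
planted positives and passes ~0.03% of nulls through the threshold filter
(matching the closed-form product of tail probabilities, tested).

**What passing tests show — and what they do not.** The generator
simulates the model's own assumptions, so parameter recovery and the
baseline ordering demonstrate that the implementation is correct and that
the method dominates the baselines *when its assumptions hold*. They say
nothing about biological adequacy on real footprint data, where replicate
scores are not Gaussian copulas, bound fractions drift with factor class,
and truth labels are themselves model outputs.

## Problem sizes and determinism

Default test and acceptance runs use the full 100,000-site cohort for
single-pass checks (truth pipeline, baseline ordering across 10 seeds) and
reduced cohorts of 4,000–20,000 sites for invariance and smoke tests;
mixture parameter recovery uses 10,000 draws from the respective model.
These sizes put every Monte-Carlo tolerance comfortably beyond its
sampling error. All randomness flows through numpy Generators seeded
explicitly; seeded CLI runs are byte-reproducible (no timestamps in any
output, fixed float formatting, lexicographic tie-breaks).

## Known limitations

- The three-component mixture can absorb the tails of a single heavy
  Gaussian into its shifted components; the windowed fit tolerates this
  because the final score multiplies by P(A), but interpreting per-window
  weights as event fractions requires care.
- The IDR-style fit assumes the background is standard bivariate normal
  after the probit map, which holds exactly only if background scores are
  an i.i.d. majority; heavy bound fractions bias (mu, sigma2) as rank
  compression sets in.
- With a single unbound replicate the unbound mean rank is that
  replicate's rank; no reproducibility information exists on that side and
  none is claimed.
- The agreement stopping rule uses a trailing window and a global running
  maximum; a centered window or a windowed maximum are defensible variants
  and would move the cutoff by at most a window width.
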