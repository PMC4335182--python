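# Methods

This note records the model, the conventions chosen where several were
defensible, and what the synthetic-data studies do and do not establish.

## Model and assumptions

Each region pair is modeled independently. For one pair, the data are N
subjects' joint-activation counts Z_n (4-category multinomial with total
T) and tractography success counts S_n (binomial with M trials). The
structural connection probability π has a Beta(α₀, β₀) prior; the
activation table θ has a Dirichlet prior whose first weight is
α(π) + α₁, coupling structure to function a priori. Conditional on
(θ, π), Z and S are independent; their marginal dependence flows entirely
through the (θ, π) prior. Observations are treated as independent across
subjects and across scans — the latter presumes the fMRI profiles were
pre-whitened upstream; the package does not remove temporal
autocorrelation itself.

Dichotomization declares scan t elevated when the mean-adjusted signal
exceeds c·σ, with σ the sample standard deviation (denominator T*−1; at
T* ≈ 500 scans the choice is immaterial) and c = 0.01 by default.
Constant (zero-variance) profiles yield an all-zero indicator and a
`degenerate` flag rather than an error, so pair bookkeeping over a full
parcellation stays rectangular.

## Data-preparation conventions

* Regional summaries: the dominant temporal profile of a scans × voxels
  matrix is its first left singular vector (unit norm), sign-aligned with
  the voxel-mean signal or a caller-supplied reference.
* Rescaling counts to T: largest-remainder allocation, ties broken toward
  the lowest cell index, so the rescaled vector is integer and sums to T
  exactly (the multinomial likelihood requires integers).
* Tractography: voxel-level counts are aggregated by the 0.90 quantile
  (linear interpolation between order statistics), symmetrized by the
  maximum of the two directions, averaged over scans, and rescaled to M
  trials with rounding to the nearest integer, clamped to [0, M].
* A distance adjustment for tractography counts (path length confounds
  stream success) is not performed; callers may supply pre-adjusted
  matrices.

## The link function

The default link is α(π) = C·(10^π − 1) with
C = 10/((9/ln 10) − 1) = 3.4380206765828176 (kept at full precision in
code). It is zero at π = 0, averages exactly 10 over the unit interval,
and at π = 1 puts the prior mean of θ₁ at 0.545 — strong structural
evidence nudges expected joint activation toward one half without
overwhelming T·N functional observations (total prior mass ≈ 35–66
against N·T = 1500+).

Alternative families, all normalized to the same unit-interval average:
exponential g(b): C_b·(b^π − 1) with C_b = mean/((b−1)/ln b − 1)
(increasing for b > 1 and, through a negative C_b, for 0 < b < 1), and
power f(p): mean·(p+1)·π^p. A degenerate `constant` family
(α(π) ≡ mean) is also provided: it decouples the posterior into conjugate
Beta × Dirichlet pieces, which makes it both the FC-only comparator of
the bias study and the closed-form oracle used to validate the sampler.

## Sampling

One sweep draws θ from its Dirichlet full conditional given π, then
updates π by random-walk Metropolis with a Normal proposal. All densities
are evaluated in log space via log-gamma; proposals outside (0, 1) have
zero density and are rejected outright (no reflection or transformation).
The proposal scale follows a Robbins–Monro recursion on its logarithm
toward 25% acceptance during burn-in only, and is frozen afterwards so
the post-burn-in chain is time-homogeneous with the correct stationary
law. Initialization: π at its flat-link posterior mean
(ΣS + α₀)/(NM + α₀ + β₀), θ drawn from its full conditional at that π.
Defaults: 10,000 iterations after 2,000 burn-in for data analysis, 7,000
after 2,000 in the simulation studies, thinning by 10.

Every pair gets its own seed stream derived from (base seed, pair index),
so multi-pair results are independent of processing order. The studies
drive a vectorized engine that advances hundreds of chains in lock-step
as numpy arrays; the single-pair fit is the same code path with batch
size one, so the conjugate and calibration tests cover both. Sampler
validation: with the constant link, chain moments of π and θ match the
Beta/Dirichlet closed forms within Monte-Carlo error, and under the
default link the ranks of true (θ₁, π) within their posterior samples are
uniform over 200 prior-predictive replicates (simulation-based
calibration, χ² at α = 0.01).

## Edge inference

κ and τ are functionals of θ and are computed on every retained draw,
then summarized — never from the posterior-mean θ. Exceedance
probabilities use strict inequality (immaterial for continuous samples,
fixed for determinism). The ascendancy effect size e_τ, when not given,
is the median oriented posterior-mean τ pooled over the κ-connected pairs
only, since ascendancy is defined only for functionally connected pairs.
Because E[1/τ] ≠ 1/E[τ], the "oriented" summary is the larger of the two
orientations' posterior means, computed from the same draws — this makes
e_τ and the direction call invariant to which region of a pair happens to
be stored first.

## Network metrics

Clustering: C_i = 2E_i/(k_i(k_i−1)) for undirected graphs; for directed
graphs k_i counts distinct neighbors (union of in- and out-neighbors) and
E_i counts each directed link among them once, C_i = E_i/(k_i(k_i−1)) —
this keeps C ≤ 1 and gives the directed 3-cycle C = 1/2. Nodes with fewer
than two neighbors contribute C_i = 0. Path length averages shortest
paths over ordered reachable pairs, excluding unreachable ones. The null
model rewires by double edge swaps (10·|E| successful swaps per
realization, self-loops and duplicate edges rejected; directed swaps
preserve in- and out-degrees separately), so every realization has
exactly the original degree sequence. Hub thresholds use the population
standard deviation over all network nodes and a strict inequality, so a
regular graph has no hubs.

## Simulation studies

The generator draws from the model hierarchy itself and its defaults are
the study conditions: T = 100, M = 1000, structural-prior grid
(α₀, β₀) ∈ {(1,100), (2,18), (2,5), (2,2), (5,2), (18,2)} spanning prior
connection probabilities 0.01–0.9, and sample sizes N ∈ {15, 30, 100}.
Full replication is 10 π × 10 θ × 100 datasets per cell; a scaled-down
preset (10 π × 5 θ × 20 datasets, chains 2,000 + 500 burn-in) keeps the
default test run inside a few minutes. Sample sizes share common random
numbers: smaller N uses a prefix of the same simulated subjects, so the
bias-versus-N ordering is compared on identical randomness.

Two different bias conventions are used deliberately. The bias **grid**
reports the mean absolute error of the posterior mean (per dataset, then
averaged), with a companion standard deviation; all entries are positive
and shrink as N grows. The **sensitivity** study instead reports the sum
over components of the absolute *replicate-averaged signed* bias of the
posterior-mean θ. When the fitting link matches the generating link the
posterior mean is Bayes-unbiased under the replication distribution, so
the matched-link entry is a Monte-Carlo residual whose magnitude is set
by the replication (≈ 0.002 at the 100-replicate design used here,
N = 30); mismatched links add the systematic pull of a miscentered prior
on top. The study's conclusion — equal-area links give comparable θ
bias — is therefore a statement that the systematic component stays
within the noise scale, and it is checked as a max/min ratio across
fitting links rather than cellwise equality. The FC-only comparator is
the same multinomial likelihood with the constant link (α(π) replaced by
its average), so both estimators carry equal total prior mass; its θ
posterior mean is computed in closed form.

The correlation study maps each activation table to a bivariate-normal
model: thresholds solve the marginal equations P(R > c) = marginal
activation probability, and ρ solves the Gaussian orthant equation
P(R_a > c_a, R_b > c_b) = θ₁ by monotone root finding (brentq, tolerance
1e-8, orthant probabilities from the bivariate normal CDF). For interior
θ a solution in (−1, 1) always exists (the open Fréchet bounds are
strict); boundary tables are rejected. Targets are (π, θ) pairs drawn
from the model prior with π ~ Beta(2, 2) so coherence spans weak to
strong; series use σ² = 0.2 (matching task-fMRI signal variance
estimates) and T* = 483 scans, and κ is estimated by the full pipeline —
dichotomize at the implied thresholds, tabulate, rescale, fit.

## What the synthetic data do not show

The generator matches the model exactly: no temporal autocorrelation
(real profiles are pre-whitened, imperfectly), no spatial dependence
between pairs (pairs sharing a region are correlated in real brains, and
the model fits pairs independently either way), no distance-dependent
tractography bias, and no misalignment between functional and structural
parcellations. Passing simulation checks therefore establishes internal
consistency — the sampler targets the stated posterior, estimators
behave as the theory predicts — not robustness to these real-data
violations.

## Known limitations and numerical notes

* The posterior mean of τ is a heavy-tailed functional (a ratio of odds);
  its mean-absolute-error summaries are sensitive to tail draws and run
  higher than robust alternatives (e.g. posterior medians) would give.
  κ, being bounded, has no such issue.
* Whether proposal-scale adaptation should continue after burn-in is an
  open choice; freezing it is conservative and costs little efficiency at
  these chain lengths.
* The small-world index is undefined for triangle-free networks
  (C_random = 0); the CLI reports and skips such networks rather than
  fabricating a value.
* Quadrature (link integrals) is checked to 1e-8; acceptance tolerances
  for stochastic quantities are stated as multiples of cluster-level
  Monte-Carlo standard errors, treating each simulated θ as a cluster.
* The acceptance script runs the bias cells at the full 10 × 10 × 100
  replication with shortened (2,000 + 500) chains — posterior means are
  insensitive to the chain-length reduction, while the full replication
  pins the reported values to well under 5% Monte-Carlo spread.
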