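# jointfc

Bayesian joint modeling of functional and structural brain connectivity.

`jointfc` infers functional brain networks from task fMRI while borrowing
strength from diffusion-imaging tractography. It is aimed at neuroimaging
researchers who have (a) regional activity profiles (scans × regions per
subject) and (b) probabilistic-tractography stream counts between the same
regions, and who want whole-brain, region-pair-level inference about
functional coherence, directionality, and network topology.

## The model

For each pair of regions, each subject's activity profiles are
dichotomized into elevated / non-elevated states (threshold `c` standard
deviations above the mean) and cross-tabulated over scans into a
4-category joint-activation count vector **Z** = (Z₁, Z₂, Z₃, Z₄)
(both active, only the first, only the second, neither), rescaled to a
common total T = 100. Tractography gives a success count S out of
M = 1000 rescaled trials. The hierarchy is

    Z_n | θ ~ Multinomial(T, θ)          n = 1..N subjects
    S_n | π ~ Binomial(M, π)
    θ | π  ~ Dirichlet(α(π) + α₁, α₂, α₃, α₄)
    π      ~ Beta(α₀, β₀)

where π is the probability of a structural connection and
α(π) = C·(10^π − 1), with C chosen so that the average of α(π) over
[0, 1] equals 10, is an increasing *link* that raises the prior weight on
joint activation (θ₁) when structural evidence is strong — without
letting structure dictate function. Defaults: α₀ = β₀ = 1, α₁ = 5,
α₂ = α₃ = α₄ = 10, c = 0.01.

The posterior p(θ, π | Z, S) is sampled by a Gibbs sweep for θ with an
embedded random-walk Metropolis step for π (proposal scale adapted during
burn-in toward ~25% acceptance). From each retained θ draw two statistics
are computed:

* **κ (functional coherence)** — chance-corrected agreement of the two
  regions' activation states, κ = (θ₁ + θ₄ − E)/(1 − E) when the odds
  ratio θ₁θ₄/θ₂θ₃ exceeds 1 and 0 otherwise, with
  E = (θ₁+θ₂)(θ₁+θ₃) + (θ₃+θ₄)(θ₂+θ₄); κ ∈ [0, 1].
* **τ (ascendancy)** — the ratio of the two regions' marginal activation
  odds, τ_ab = ((θ₁+θ₂)/(θ₃+θ₄)) / ((θ₁+θ₃)/(θ₂+θ₄)); τ > 1 means the
  first region is ascendant and orients the edge.

A pair is *connected* iff P(κ > e_κ | Z, S) > p_κ (defaults e_κ = 0.4,
p_κ = 0.5) and *directed* iff additionally P(τ > e_τ | Z, S) > p_τ on the
ascendant orientation, with e_τ the median oriented posterior-mean τ over
connected pairs. The resulting undirected and directed graphs are
characterized by the mean clustering coefficient C, characteristic path
length L, the small-world index σ = (C/C_random)/(L/L_random) against
1000 degree-matched rewired null networks, and hub sets (degree more than
one standard deviation above the network mean; out-/in-degree variants
give driving/driven hubs).

The package also ships the model's simulation studies: a bias grid
comparing the joint model against an FC-only comparator across structural
priors and sample sizes, a correspondence study mapping θ to an
equivalent bivariate-normal correlation ρ, and a sensitivity study over
link-function families with equal area under the curve.

## Worked example

Simulate an 8-region, 15-subject dataset from a structurally dense prior,
fit every pair, and analyze the resulting network:

```sh
$ cat sim.json
{"seed": 3, "hyperparameters": {"alpha0": 18, "beta0": 2}}
$ jointfc simulate --config sim.json --n-regions 8 --n-subjects 15 --output-dir data
wrote data/counts.tsv and data/structural_counts.tsv
$ cat fit.json
{"seed": 3, "hyperparameters": {"alpha0": 18, "beta0": 2},
 "counts": "data/counts.tsv", "structural_counts": "data/structural_counts.tsv",
 "chain": {"n_iterations": 10000, "n_burnin": 2000},
 "thresholds": {"e_kappa": 0.25}}
$ jointfc fit --config fit.json --output-dir run
wrote run/edges.tsv (28 pairs)
```

`run/edges.tsv` holds one row per region pair (first rows shown):

```
region_a region_b  kappa_mean  p_kappa  tau_mean  p_tau  pi_mean  connected direction
      R1       R2       0.461    0.995     0.867  0.700    0.922       True      b->a
      R1       R3       0.287    0.000     0.970  0.106    0.986      False      none
      R1       R4       0.383    0.223     1.066  0.174    0.962      False      none
      R1       R5       0.439    0.937     1.121  0.484    0.936       True      none
```

`kappa_mean` is the posterior-mean coherence and `p_kappa` the exceedance
probability P(κ > e_κ | Z, S); R1–R2 is called connected and, because the
oriented ascendancy exceedance passes, directed R2 → R1 (R2's marginal
activation odds are higher). `pi_mean` is the posterior structural
connection probability. The network step then computes topology against
a degree-matched null:

```sh
$ jointfc network run/edges.tsv --seed 3 --output-dir net
undirected: 8 nodes, 12 edges, sigma=0.88
$ python -m json.tool net/metrics_undirected.json
{"clustering": 0.3792, "path_length": 1.7143, "c_random": 0.4284,
 "l_random": 1.7006, "small_world": 0.878, "hubs": ["R1", "R4"], ...}
```

σ ≈ 0.88 says this small synthetic network clusters no more than its
degree-matched random counterparts — unsurprising at 8 nodes; the
small-world signature (σ ≫ 1) emerges in whole-brain networks with
hundreds of regions.

The simulation studies are available as `jointfc bias-study`,
`jointfc sensitivity-study`, and `jointfc kappa-rho-study` (each with
`--scaled-down/--paper-scale` presets where applicable), or directly
through `jointfc.simulate`.

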