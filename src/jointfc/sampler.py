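"""Metropolis-within-Gibbs sampling of the joint posterior p(theta, pi | Z, S).

Each region pair is fit independently.  One sweep updates theta from its
Dirichlet full conditional given pi, then updates pi by a Metropolis step
with a Normal jumping kernel whose scale is adapted during burn-in toward a
~25% acceptance rate (the classic efficiency target for one-dimensional
random-walk Metropolis) and frozen afterwards so the post-burn-in chain is
a genuine Markov chain with the posterior as its stationary law.

The workhorse is a batch engine that advances B chains in lock-step as
numpy arrays; ``run_pair_chain`` is its B=1 wrapper and the simulation
studies drive it with B in the hundreds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammaln

from .model import ModelHyperparameters, alpha_link

__all__ = [
    "ChainSettings",
    "PairPosterior",
    "metropolis_step_pi",
    "gibbs_step_theta",
    "run_pair_chain",
    "run_chains_batch",
    "fit_all_pairs",
    "pair_seed_sequence",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChainSettings:
    """MCMC run lengths and tuning constants.

    ``n_iterations`` counts post-burn-in sweeps; every ``thin``-th of these
    is retained.  ``jump_sd`` is the initial Metropolis proposal scale for
    pi (adapted during burn-in only).
    """

    n_iterations: int = 10000
    n_burnin: int = 2000
    thin: int = 10
    jump_sd: float = 0.05
    target_acceptance: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1 or self.n_burnin < 0:
            raise ValueError("chain lengths must be positive")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.jump_sd <= 0:
            raise ValueError("jump_sd must be positive")
        if not 0.0 < self.target_acceptance < 1.0:
            raise ValueError("target_acceptance must lie in (0, 1)")

    @property
    def n_kept(self) -> int:
        return self.n_iterations // self.thin


@dataclass
class PairPosterior:
    """Retained posterior samples for one region pair."""

    pair: tuple[str, str]
    theta_samples: np.ndarray  # [n_kept, 4], rows on the simplex
    pi_samples: np.ndarray  # [n_kept], in (0, 1)
    acceptance_rate: float
    settings: ChainSettings
    structural_fallback: bool = False

    @property
    def theta_mean(self) -> np.ndarray:
        return self.theta_samples.mean(axis=0)

    @property
    def pi_mean(self) -> float:
        return float(self.pi_samples.mean())


def _batch_log_conditional_pi(pi, theta1, Ssum, n_subjects, hyper):
    """Vectorized log p(pi | theta, S) up to a constant; -inf outside (0,1)."""
    out = np.full(np.shape(pi), -np.inf)
    ok = (pi > 0.0) & (pi < 1.0)
    if np.any(ok):
        p = pi[ok]
        a = alpha_link(p, hyper.link)
        t1 = theta1[ok] if np.ndim(theta1) else theta1
        s = Ssum[ok] if np.ndim(Ssum) else Ssum
        out[ok] = (
            gammaln(a + hyper.alpha_sum)
            - gammaln(a + hyper.alpha1)
            + (s + hyper.alpha0 - 1.0) * np.log(p)
            + (n_subjects * hyper.M - s + hyper.beta0 - 1.0) * np.log1p(-p)
            + a * np.log(t1)
        )
    return out


def metropolis_step_pi(
    pi: float,
    jump_sd: float,
    theta: np.ndarray,
    S_all,
    hyper: ModelHyperparameters,
    rng: np.random.Generator,
) -> tuple[float, bool]:
    """One random-walk Metropolis update of pi given theta.

    Proposes pi* ~ Normal(pi, jump_sd^2) and accepts with probability
    min(r, 1) where r is the full-conditional density ratio; proposals
    outside (0, 1) have zero density and are always rejected.
    """
    S = np.atleast_1d(np.asarray(S_all, dtype=float))
    ssum = np.array(S.sum())
    n = S.shape[0]
    theta1 = float(np.asarray(theta).reshape(-1)[0])
    proposal = pi + jump_sd * rng.standard_normal()
    cur = _batch_log_conditional_pi(np.array(pi), theta1, ssum, n, hyper)
    new = _batch_log_conditional_pi(np.array(proposal), theta1, ssum, n, hyper)
    if np.log(rng.uniform()) < new - cur:
        return float(proposal), True
    return float(pi), False


def gibbs_step_theta(
    Z_all, pi: float, hyper: ModelHyperparameters, rng: np.random.Generator
) -> np.ndarray:
    """One draw of theta from its Dirichlet full conditional given pi."""
    from .model import conditional_theta_params

    return rng.dirichlet(conditional_theta_params(Z_all, pi, hyper))


def run_chains_batch(
    Zsum: np.ndarray,
    Ssum: np.ndarray,
    n_subjects: int,
    hyper: ModelHyperparameters,
    settings: ChainSettings,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Advance B independent chains in lock-step.

    Parameters
    ----------
    Zsum : array [B, 4]
        Per-chain subject-summed multinomial counts (the sufficient
        statistic for theta).
    Ssum : array [B]
        Per-chain subject-summed binomial counts.
    n_subjects : int
        Number of subjects behind each chain (common across the batch).

    Returns
    -------
    theta_samples : array [B, n_kept, 4]
    pi_samples : array [B, n_kept]
    acceptance_rate : array [B]
        Post-burn-in Metropolis acceptance fraction per chain.
    """
    Zsum = np.atleast_2d(np.asarray(Zsum, dtype=float))
    Ssum = np.atleast_1d(np.asarray(Ssum, dtype=float))
    B = Zsum.shape[0]
    if Zsum.shape != (B, 4) or Ssum.shape != (B,):
        raise ValueError("Zsum must be [B, 4] and Ssum [B]")
    if n_subjects < 1:
        raise ValueError("at least one subject is required")
    if rng is None:
        rng = np.random.default_rng(settings.seed)

    alpha_rest = hyper.alpha_rest
    total_trials = n_subjects * hyper.M

    # Initialization: pi at its (flat-link) posterior mean, theta from its
    # full conditional given that pi.
    pi = (Ssum + hyper.alpha0) / (total_trials + hyper.alpha0 + hyper.beta0)
    params = Zsum + alpha_rest
    params[:, 0] += alpha_link(pi, hyper.link)
    g = rng.standard_gamma(params)
    theta = g / g.sum(axis=1, keepdims=True)

    log_sd = np.full(B, np.log(settings.jump_sd))

    n_kept = settings.n_kept
    theta_out = np.empty((B, n_kept, 4))
    pi_out = np.empty((B, n_kept))
    accepted_post = np.zeros(B)
    kept = 0

    total = settings.n_burnin + settings.n_iterations
    for it in range(total):
        in_burnin = it < settings.n_burnin

        # --- Gibbs: theta | pi ---
        params = Zsum + alpha_rest
        params[:, 0] += alpha_link(pi, hyper.link)
        g = rng.standard_gamma(params)
        theta = g / g.sum(axis=1, keepdims=True)
        # theta changed, so the cached conditional of pi must be refreshed
        log_cond = _batch_log_conditional_pi(pi, theta[:, 0], Ssum, n_subjects, hyper)

        # --- Metropolis: pi | theta ---
        proposal = pi + np.exp(log_sd) * rng.standard_normal(B)
        log_cond_new = _batch_log_conditional_pi(
            proposal, theta[:, 0], Ssum, n_subjects, hyper
        )
        accept = np.log(rng.uniform(size=B)) < log_cond_new - log_cond
        pi = np.where(accept, proposal, pi)

        if in_burnin:
            # Robbins-Monro on the log proposal scale, frozen after burn-in
            step = (it + 1.0) ** -0.6
            log_sd += step * (accept.astype(float) - settings.target_acceptance)
        else:
            accepted_post += accept
            post_it = it - settings.n_burnin + 1
            if post_it % settings.thin == 0:
                theta_out[:, kept] = theta
                pi_out[:, kept] = pi
                kept += 1

    return theta_out, pi_out, accepted_post / settings.n_iterations


def run_pair_chain(
    Z_all,
    S_all,
    hyper: ModelHyperparameters,
    settings: ChainSettings,
    pair: tuple[str, str] = ("a", "b"),
    rng: np.random.Generator | None = None,
) -> PairPosterior:
    """Fit the joint model for one region pair.

    Deterministic given ``settings.seed`` (or an explicit ``rng``).
    """
    Z = np.atleast_2d(np.asarray(Z_all, dtype=float))
    S = np.atleast_1d(np.asarray(S_all, dtype=float))
    if Z.shape[0] < 1:
        raise ValueError("at least one subject is required")
    if Z.shape[0] != S.shape[0]:
        raise ValueError("Z_all and S_all must cover the same subjects")
    if (S < 0).any() or (S > hyper.M).any():
        raise ValueError("structural counts must lie in [0, M]")
    theta_s, pi_s, acc = run_chains_batch(
        Z.sum(axis=0)[None, :], np.array([S.sum()]), Z.shape[0], hyper, settings, rng
    )
    return PairPosterior(
        pair=pair,
        theta_samples=theta_s[0],
        pi_samples=pi_s[0],
        acceptance_rate=float(acc[0]),
        settings=settings,
    )


def _flat_prior_posterior(
    Z_all, hyper: ModelHyperparameters, settings: ChainSettings,
    pair: tuple[str, str], rng: np.random.Generator
) -> PairPosterior:
    """Posterior without structural data: constant link at its mean value.

    theta is conjugate (Dirichlet) and pi reverts to its Beta prior; both
    are sampled i.i.d. to the same retained-sample count as an MCMC fit.
    """
    Z = np.atleast_2d(np.asarray(Z_all, dtype=float))
    params = Z.sum(axis=0) + hyper.alpha_rest
    params[0] += hyper.link.target_mean
    n_kept = settings.n_kept
    theta_s = rng.dirichlet(params, size=n_kept)
    pi_s = rng.beta(hyper.alpha0, hyper.beta0, size=n_kept)
    return PairPosterior(
        pair=pair,
        theta_samples=theta_s,
        pi_samples=pi_s,
        acceptance_rate=float("nan"),
        settings=settings,
        structural_fallback=True,
    )


def pair_seed_sequence(base_seed: int, pair_index: int) -> np.random.SeedSequence:
    """Deterministic per-pair seed stream, independent of execution order."""
    return np.random.SeedSequence(entropy=(int(base_seed), int(pair_index)))


def fit_all_pairs(
    dataset: dict,
    hyper: ModelHyperparameters,
    settings: ChainSettings,
    on_missing_structural: str = "error",
) -> dict:
    """Fit every region pair independently.

    Parameters
    ----------
    dataset : dict
        Maps ``(region_a, region_b)`` to ``(Z_all, S_all)`` where ``S_all``
        may be None if tractography is unavailable for the pair.
    on_missing_structural : {"error", "flat"}
        With "flat", pairs lacking structural counts are fit with a
        pi-independent prior (constant link at its average value) and the
        fallback is logged.

    Pairs are processed in canonical (sorted-label) order with per-pair
    seeds derived from ``(settings.seed, pair_index)``, so results do not
    depend on iteration order or any parallel scheduling.
    """
    if on_missing_structural not in ("error", "flat"):
        raise ValueError("on_missing_structural must be 'error' or 'flat'")
    results: dict = {}
    for idx, pair in enumerate(sorted(dataset)):
        Z_all, S_all = dataset[pair]
        rng = np.random.default_rng(pair_seed_sequence(settings.seed, idx))
        if S_all is None:
            if on_missing_structural == "error":
                raise ValueError(f"missing structural counts for pair {pair}")
            logger.warning(
                "pair %s: no structural counts; falling back to flat prior", pair
            )
            results[pair] = _flat_prior_posterior(Z_all, hyper, settings, pair, rng)
        else:
            results[pair] = run_pair_chain(
                Z_all, S_all, hyper, settings, pair=pair, rng=rng
            )
    return results
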