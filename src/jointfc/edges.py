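"""Functional coherence, ascendancy, and edge calling.

Two statistics summarize a pair's joint activation probabilities theta:

* kappa — chance-corrected agreement between the two regions' activation
  states (a Cohen's-kappa analogue on the 2x2 activation table), truncated
  to zero when the odds ratio theta1*theta4 / (theta2*theta3) is <= 1, so
  it ranges over [0, 1];
* tau — the ratio of the two regions' marginal activation odds; tau > 1
  means the first region is ascendant, which orients the edge.

Both are computed per retained posterior draw of theta (never from the
posterior mean), and edges are called from exceedance probabilities:
connected iff P(kappa > e_kappa) > p_kappa, directed iff additionally
P(tau > e_tau) > p_tau on the orientation whose posterior-mean tau is
>= 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sampler import PairPosterior

__all__ = [
    "InferenceThresholds",
    "EdgeInference",
    "kappa",
    "tau",
    "exceedance",
    "determine_e_tau",
    "call_edges",
    "edges_to_frame",
]


@dataclass(frozen=True)
class InferenceThresholds:
    """Effect sizes and exceedance-probability cutoffs for edge calls.

    ``e_kappa = 0.4`` marks moderate agreement or above; ``e_tau`` may be a
    number or ``"auto-median"``, in which case it is the median
    orientation-normalized posterior-mean tau over connected pairs.
    """

    e_kappa: float = 0.4
    p_kappa: float = 0.5
    e_tau: float | str = "auto-median"
    p_tau: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.e_kappa < 1.0:
            raise ValueError("e_kappa must lie in [0, 1)")
        for name in ("p_kappa", "p_tau"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not isinstance(self.e_tau, str) and self.e_tau <= 0:
            raise ValueError("e_tau must be positive or 'auto-median'")


@dataclass
class EdgeInference:
    """Posterior edge summary for one region pair (oriented a -> b)."""

    pair: tuple[str, str]
    kappa_mean: float
    p_kappa_exceed: float
    tau_mean: float
    p_tau_exceed: float
    connected: bool
    direction: str  # "a->b", "b->a", or "none"
    pi_mean: float


def kappa(theta) -> np.ndarray | float:
    """Chance-corrected coherence of a 2x2 activation table.

    With E = (t1+t2)(t1+t3) + (t3+t4)(t2+t4) the expected agreement under
    independent margins, returns (t1 + t4 - E) / (1 - E) when the odds
    ratio exceeds 1 and 0 otherwise.  Vectorized over rows of ``theta``.
    """
    th = np.asarray(theta, dtype=float)
    scalar = th.ndim == 1
    th = np.atleast_2d(th)
    if th.shape[-1] != 4:
        raise ValueError("theta must have 4 components")
    t1, t2, t3, t4 = th.T
    E = (t1 + t2) * (t1 + t3) + (t3 + t4) * (t2 + t4)
    with np.errstate(divide="ignore", invalid="ignore"):
        value = (t1 + t4 - E) / (1.0 - E)
    value = np.where(E >= 1.0, 1.0, value)  # simplex vertex t1 or t4 = 1
    out = np.where(t1 * t4 > t2 * t3, value, 0.0)
    return float(out[0]) if scalar else out


def tau(theta) -> np.ndarray | float:
    """Ascendancy: ratio of the two regions' marginal activation odds.

    ((t1+t2)/(t3+t4)) / ((t1+t3)/(t2+t4)).  Undefined (NaN) when either
    marginal probability is 0 or 1.  Vectorized over rows.
    """
    th = np.asarray(theta, dtype=float)
    scalar = th.ndim == 1
    th = np.atleast_2d(th)
    if th.shape[-1] != 4:
        raise ValueError("theta must have 4 components")
    t1, t2, t3, t4 = th.T
    pa, pb = t1 + t2, t1 + t3
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (pa / (1.0 - pa)) / (pb / (1.0 - pb))
    bad = (pa <= 0) | (pa >= 1) | (pb <= 0) | (pb >= 1)
    out = np.where(bad, np.nan, out)
    return float(out[0]) if scalar else out


def exceedance(samples, threshold: float) -> float:
    """Fraction of posterior samples strictly exceeding ``threshold``."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("samples must be non-empty")
    return float(np.mean(x > threshold))


def _oriented_tau_mean(posterior: PairPosterior) -> float:
    """Posterior-mean tau in the ascendant orientation (>= 1 by choice).

    The reciprocal of the a->b posterior mean is not the b->a posterior
    mean (Jensen), so both orientations' means are computed from the same
    draws and the larger is taken; this makes the summary invariant to
    which region happens to be stored first.
    """
    t = tau(posterior.theta_samples)
    return max(float(np.nanmean(t)), float(np.nanmean(1.0 / t)))


def determine_e_tau(
    posteriors, e_kappa: float = 0.4, p_kappa: float = 0.5
) -> float:
    """Data-driven ascendancy effect size: the median oriented tau.

    Ascendancy is only defined for functionally connected pairs, so the
    pool is the kappa-connected pairs; each contributes its posterior-mean
    tau folded to >= 1 (max of tau-bar and its reciprocal), making the
    result invariant to how each pair happens to be oriented.
    """
    oriented = [
        _oriented_tau_mean(p)
        for p in posteriors
        if exceedance(kappa(p.theta_samples), e_kappa) > p_kappa
    ]
    if not oriented:
        raise ValueError("no connected pairs; cannot set e_tau")
    return float(np.median(oriented))


def call_edges(
    posteriors, thresholds: InferenceThresholds | None = None
) -> list[EdgeInference]:
    """Call connected and directed edges from per-pair posteriors.

    kappa and tau are evaluated on every retained theta draw.  A pair is
    connected iff P(kappa > e_kappa) > p_kappa.  Direction is assessed on
    the orientation whose posterior-mean tau is >= 1: that region is
    declared ascendant iff P(tau_oriented > e_tau) > p_tau.
    """
    thresholds = thresholds or InferenceThresholds()
    posteriors = list(posteriors)

    e_tau = thresholds.e_tau
    if isinstance(e_tau, str):
        if e_tau != "auto-median":
            raise ValueError(f"unknown e_tau policy: {e_tau!r}")
        try:
            e_tau = determine_e_tau(
                posteriors, thresholds.e_kappa, thresholds.p_kappa
            )
        except ValueError:
            # no connected pairs: ascendancy is undefined, direction calls
            # are all "none" and the table still records kappa evidence
            e_tau = np.inf

    out = []
    for post in posteriors:
        k = kappa(post.theta_samples)
        t = tau(post.theta_samples)
        k_mean = float(np.mean(k))
        p_k = exceedance(k, thresholds.e_kappa)
        t_mean = float(np.nanmean(t))
        connected = p_k > thresholds.p_kappa

        # orient toward the candidate ascendant region: the orientation
        # with the larger posterior-mean tau (label-invariant)
        forward = t_mean >= float(np.nanmean(1.0 / t))
        t_oriented = t if forward else 1.0 / t
        p_t = exceedance(t_oriented[~np.isnan(t_oriented)], e_tau)

        direction = "none"
        if connected and p_t > thresholds.p_tau:
            direction = "a->b" if forward else "b->a"
        out.append(
            EdgeInference(
                pair=post.pair,
                kappa_mean=k_mean,
                p_kappa_exceed=p_k,
                tau_mean=t_mean,
                p_tau_exceed=p_t,
                connected=connected,
                direction=direction,
                pi_mean=post.pi_mean,
            )
        )
    return out


def edges_to_frame(edges) -> pd.DataFrame:
    """Tabulate edge calls (one row per pair) for TSV output."""
    return pd.DataFrame(
        {
            "region_a": [e.pair[0] for e in edges],
            "region_b": [e.pair[1] for e in edges],
            "kappa_mean": [e.kappa_mean for e in edges],
            "p_kappa": [e.p_kappa_exceed for e in edges],
            "tau_mean": [e.tau_mean for e in edges],
            "p_tau": [e.p_tau_exceed for e in edges],
            "pi_mean": [e.pi_mean for e in edges],
            "connected": [e.connected for e in edges],
            "direction": [e.direction for e in edges],
        }
    )
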