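"""The joint probability model for functional and structural connectivity.

For one region pair, the data are N subjects' joint-activation count
vectors Z_n ~ Multinomial(T, theta) and tractography success counts
S_n ~ Binomial(M, pi).  The structural-connection probability pi carries a
Beta(alpha0, beta0) prior, and theta carries a Dirichlet prior whose first
concentration parameter is linked to pi:

    theta | pi ~ Dirichlet(alpha(pi) + alpha1, alpha2, alpha3, alpha4)

with alpha(pi) an increasing link function normalized so its average over
pi in [0, 1] equals a fixed target (10 by default).  Stronger structural
evidence therefore raises the prior expectation of joint activation
(theta_1) without overriding the functional data.

This module houses the link-function families, the hyperparameter
container, and all log densities the sampler needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "LinkFunction",
    "ModelHyperparameters",
    "alpha_link",
    "prior_mean_theta1",
    "log_likelihood",
    "log_conditional_pi",
    "conditional_theta_params",
]


@dataclass(frozen=True)
class LinkFunction:
    """Increasing map from structural probability pi to Dirichlet weight.

    Families
    --------
    ``exp10`` (default)
        ``C * (10**pi - 1)`` with ``C = target_mean / ((9/ln 10) - 1)``.
        This is the unique exponential-in-base-10 form that is 0 at pi=0
        and integrates to ``target_mean`` over [0, 1]; at pi=1 it puts the
        prior mean of theta_1 near 0.5 under the default hyperparameters.
    ``exp``
        ``g(b)``: ``C_b * (b**pi - 1)``, ``C_b = target_mean / ((b-1)/ln b - 1)``.
        Increasing for b > 1 directly and for 0 < b < 1 via negative
        ``C_b``; ``b = 10`` reproduces the default family.
    ``power``
        ``f(p)``: ``target_mean * (p + 1) * pi**p`` for p > 0.
    ``constant``
        ``alpha(pi) = target_mean`` everywhere.  Degenerate: it decouples
        the structural and functional parameters (the posterior factorizes
        into conjugate Beta and Dirichlet pieces), which makes it the
        FC-only comparator and the closed-form oracle for sampler
        validation.

    All families share the same area under the curve, so swapping families
    changes the prior's shape but not its average strength.
    """

    family: str = "exp10"
    parameter: float = 10.0
    target_mean: float = 10.0

    def __post_init__(self) -> None:
        if self.family not in ("exp10", "exp", "power", "constant"):
            raise ValueError(f"unknown link family: {self.family!r}")
        if self.target_mean <= 0:
            raise ValueError("target_mean must be positive")
        if self.family == "exp":
            b = self.parameter
            if b <= 0 or b == 1.0:
                raise ValueError("exp-family base must be positive and != 1")
        if self.family == "power" and self.parameter <= 0:
            raise ValueError("power-family exponent must be positive")

    @property
    def scale(self) -> float:
        """Normalizing constant making the [0,1] average equal target_mean."""
        if self.family == "exp10":
            return self.target_mean / (9.0 / np.log(10.0) - 1.0)
        if self.family == "exp":
            b = self.parameter
            return self.target_mean / ((b - 1.0) / np.log(b) - 1.0)
        if self.family == "constant":
            return self.target_mean
        return self.target_mean * (self.parameter + 1.0)

    def __call__(self, pi):
        return alpha_link(pi, self)


def alpha_link(pi, link: LinkFunction):
    """Evaluate the structure-function link alpha(pi) on [0, 1].

    Accepts scalars or arrays; raises if any value falls outside [0, 1].
    """
    p = np.asarray(pi, dtype=float)
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("pi must lie in [0, 1]")
    if link.family == "exp10":
        out = link.scale * (10.0 ** p - 1.0)
    elif link.family == "exp":
        out = link.scale * (link.parameter ** p - 1.0)
    elif link.family == "constant":
        out = np.full_like(p, link.scale)
    else:
        out = link.scale * p ** link.parameter
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ModelHyperparameters:
    """All fixed quantities of the joint model.

    alpha0, beta0
        Beta prior for the structural probability pi; (1, 1) is flat.
    alpha1..alpha4
        Baseline Dirichlet weights; the first cell additionally receives
        alpha(pi).  Defaults (5, 10, 10, 10) give theta_2..theta_4 equal
        prior means with moderate variances.
    T, M
        Scaled multinomial total (scans) and binomial trials (streams).
    c
        Activation threshold in standard-deviation units.
    """

    alpha0: float = 1.0
    beta0: float = 1.0
    alpha1: float = 5.0
    alpha2: float = 10.0
    alpha3: float = 10.0
    alpha4: float = 10.0
    link: LinkFunction = field(default_factory=LinkFunction)
    T: int = 100
    M: int = 1000
    c: float = 0.01

    def __post_init__(self) -> None:
        for name in ("alpha0", "beta0", "alpha1", "alpha2", "alpha3", "alpha4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.T < 1 or self.M < 1:
            raise ValueError("T and M must be >= 1")

    @property
    def alpha_rest(self) -> np.ndarray:
        return np.array([self.alpha1, self.alpha2, self.alpha3, self.alpha4])

    @property
    def alpha_sum(self) -> float:
        return self.alpha1 + self.alpha2 + self.alpha3 + self.alpha4


def prior_mean_theta1(pi, hyper: ModelHyperparameters):
    """Prior expectation of theta_1 given pi.

    (alpha(pi) + alpha1) / (alpha(pi) + alpha1 + alpha2 + alpha3 + alpha4);
    increasing in pi whenever the link is increasing, which encodes the
    empirical observation that structurally connected pairs tend to show
    more joint activation.
    """
    a = alpha_link(pi, hyper.link)
    return (a + hyper.alpha1) / (a + hyper.alpha_sum)


def _sums(Z_all, S_all):
    Z = np.atleast_2d(np.asarray(Z_all, dtype=float))
    S = np.atleast_1d(np.asarray(S_all, dtype=float))
    if Z.shape[1] != 4:
        raise ValueError("Z_all must have 4 columns")
    if Z.shape[0] != S.shape[0]:
        raise ValueError("Z_all and S_all must cover the same subjects")
    return Z.sum(axis=0), float(S.sum()), Z.shape[0]


def log_likelihood(Z_all, S_all, theta, pi, hyper: ModelHyperparameters) -> float:
    """Joint log likelihood of all subjects' (Z, S), up to an additive constant.

    sum_i (sum_n Z_in) log theta_i + (sum_n S_n) log pi
        + (N*M - sum_n S_n) log(1 - pi).

    A zero theta_i with positive count (or pi on a boundary with mass on
    the other side) yields -inf rather than an exception.
    """
    Zsum, Ssum, n_subj = _sums(Z_all, S_all)
    theta = np.asarray(theta, dtype=float)
    total_trials = n_subj * hyper.M

    mask = Zsum > 0
    if np.any(theta[mask] <= 0.0):
        return -np.inf
    out = float(np.sum(Zsum[mask] * np.log(theta[mask])))

    for count, prob in ((Ssum, pi), (total_trials - Ssum, 1.0 - pi)):
        if count > 0:
            if prob <= 0.0:
                return -np.inf
            out += count * np.log(prob)
    return out


def log_conditional_pi(
    pi, theta, S_all, hyper: ModelHyperparameters, n_subjects: int | None = None
):
    """Log full-conditional density of pi given theta, up to a constant.

    log Gamma(alpha(pi) + sum alphas) - log Gamma(alpha(pi) + alpha1)
      + (sum S + alpha0 - 1) log pi
      + (N*M - sum S + beta0 - 1) log(1 - pi)
      + alpha(pi) * log theta_1

    Vectorized over ``pi``; returns -inf outside the open interval (0, 1)
    and -inf everywhere if theta_1 = 0 (the link term degenerates).
    """
    S = np.atleast_1d(np.asarray(S_all, dtype=float))
    n = S.shape[0] if n_subjects is None else n_subjects
    Ssum = float(S.sum())
    theta1 = float(np.asarray(theta, dtype=float).reshape(-1)[0])

    p = np.asarray(pi, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    out = np.full(p.shape, -np.inf)
    ok = (p > 0.0) & (p < 1.0)
    if theta1 > 0.0 and ok.any():
        pv = p[ok]
        a = alpha_link(pv, hyper.link)
        out[ok] = (
            gammaln(a + hyper.alpha_sum)
            - gammaln(a + hyper.alpha1)
            + (Ssum + hyper.alpha0 - 1.0) * np.log(pv)
            + (n * hyper.M - Ssum + hyper.beta0 - 1.0) * np.log1p(-pv)
            + a * np.log(theta1)
        )
    return float(out[0]) if scalar else out


def conditional_theta_params(Z_all, pi, hyper: ModelHyperparameters) -> np.ndarray:
    """Dirichlet parameters of the full conditional of theta given pi.

    (sum_n Z_1n + alpha(pi) + alpha1, sum_n Z_2n + alpha2,
     sum_n Z_3n + alpha3, sum_n Z_4n + alpha4)
    """
    Z = np.atleast_2d(np.asarray(Z_all, dtype=float))
    if Z.shape[1] != 4:
        raise ValueError("Z_all must have 4 columns")
    Zsum = Z.sum(axis=0)
    params = Zsum + hyper.alpha_rest
    params[0] += alpha_link(pi, hyper.link)
    return params
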