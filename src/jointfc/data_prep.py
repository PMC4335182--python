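"""Convert regional fMRI profiles and tractography counts into model inputs.

The model's sufficient statistics are, per region pair and subject:

* ``Z`` — a 4-category joint-activation count vector (both regions elevated,
  only the first, only the second, neither), obtained by dichotomizing each
  region's activity profile and cross-tabulating over scans, then rescaling
  to a common total ``T``;
* ``S`` — a structural-connection success count out of ``M`` tractography
  trials, obtained from voxel-level stream counts by quantile aggregation,
  symmetrization, averaging over scans, and rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RegionalProfile",
    "ActivationIndicator",
    "JointActivationTable",
    "StructuralCount",
    "extract_dominant_profile",
    "dichotomize",
    "joint_activation_counts",
    "rescale_joint_counts",
    "aggregate_directional_counts",
    "symmetrize_pair_counts",
    "combine_scans_and_rescale",
]


@dataclass
class RegionalProfile:
    """A single region's activity time course for one subject."""

    region_id: str
    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("profile must be a 1-D vector of length >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")


@dataclass
class ActivationIndicator:
    """Binary elevated-activity indicator derived from a profile.

    ``bits[t] = 1`` iff the mean-adjusted signal at scan ``t`` exceeds
    ``c`` standard deviations.  ``degenerate`` flags a constant series
    (zero variance), which yields an all-zero indicator.
    """

    region_id: str
    subject_id: str
    bits: np.ndarray
    threshold_c: float
    mean_used: float
    sd_used: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.int8)
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be binary")
        if self.sd_used < 0:
            raise ValueError("sd_used must be >= 0")


@dataclass
class JointActivationTable:
    """Joint activation counts for one region pair and subject.

    ``raw_counts`` tallies the four activation states over the ``raw_total``
    observed scans; ``scaled_counts`` is the same tally rescaled to sum to
    ``scaled_total`` (the model's ``T``) for comparability across analyses.
    """

    pair: tuple[str, str]
    subject_id: str
    raw_counts: np.ndarray
    raw_total: int
    scaled_counts: np.ndarray
    scaled_total: int

    def __post_init__(self) -> None:
        self.raw_counts = np.asarray(self.raw_counts, dtype=np.int64)
        self.scaled_counts = np.asarray(self.scaled_counts, dtype=np.int64)
        if self.raw_counts.shape != (4,) or self.scaled_counts.shape != (4,):
            raise ValueError("count vectors must have length 4")
        if (self.raw_counts < 0).any() or (self.scaled_counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.raw_counts.sum() != self.raw_total:
            raise ValueError("raw counts must sum to raw_total")
        if self.scaled_counts.sum() != self.scaled_total:
            raise ValueError("scaled counts must sum to scaled_total")


@dataclass
class StructuralCount:
    """Tractography success count for one region pair and subject."""

    pair: tuple[str, str]
    subject_id: str
    raw_count: float
    raw_trials: int
    scaled_count: int
    scaled_trials: int

    def __post_init__(self) -> None:
        if not 0 <= self.raw_count <= self.raw_trials:
            raise ValueError("raw count must lie in [0, raw_trials]")
        if not 0 <= self.scaled_count <= self.scaled_trials:
            raise ValueError("scaled count must lie in [0, scaled_trials]")


def extract_dominant_profile(
    voxel_matrix: np.ndarray,
    region_id: str = "",
    subject_id: str = "",
    reference_mean: np.ndarray | None = None,
) -> RegionalProfile:
    """Summarize a scans-by-voxels matrix by its dominant temporal trend.

    Performs an SVD in the time domain and returns the singular vector of
    length ``T*`` associated with the largest singular value — a weighted
    combination of voxel time courses capturing the dominant shared signal.
    Singular vectors are unique only up to sign, so the sign is fixed by
    requiring non-negative correlation with the voxel-mean signal (or with
    ``reference_mean`` if supplied).
    """
    X = np.asarray(voxel_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("voxel matrix must be 2-D with at least one voxel")
    if not np.all(np.isfinite(X)):
        raise ValueError("voxel matrix must be finite")
    if not X.any():
        raise ValueError("degenerate input: all-zero voxel matrix")

    # Temporal singular vector = left singular vector of the T* x V matrix.
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    profile = U[:, 0]

    ref = X.mean(axis=1) if reference_mean is None else np.asarray(reference_mean, float)
    if ref.shape != profile.shape:
        raise ValueError("reference_mean length must equal the number of scans")
    if float(profile @ ref) < 0.0:
        profile = -profile
    return RegionalProfile(region_id=region_id, subject_id=subject_id, values=profile)


def dichotomize(profile: RegionalProfile, c: float = 0.01) -> ActivationIndicator:
    """Threshold a profile into elevated / non-elevated activity states.

    A scan is elevated when the mean-adjusted signal exceeds ``c`` sample
    standard deviations.  A constant series has no variability to threshold:
    it yields an all-zero indicator flagged ``degenerate`` rather than an
    error, so pair bookkeeping over all regions stays rectangular.
    """
    values = profile.values
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        bits = np.zeros(values.size, dtype=np.int8)
        return ActivationIndicator(
            profile.region_id, profile.subject_id, bits, c, mean, sd, degenerate=True
        )
    bits = ((values - mean) > c * sd).astype(np.int8)
    return ActivationIndicator(profile.region_id, profile.subject_id, bits, c, mean, sd)


def joint_activation_counts(
    ind_a: ActivationIndicator, ind_b: ActivationIndicator
) -> np.ndarray:
    """Cross-tabulate two activation indicators into the raw 4-vector Z*.

    Cells are ordered (both active, only a, only b, neither); they sum to
    the number of scans.
    """
    a, b = ind_a.bits, ind_b.bits
    if a.size != b.size:
        raise ValueError("indicators must have equal length")
    if ind_a.subject_id != ind_b.subject_id:
        raise ValueError("indicators must come from the same subject")
    both = int(np.sum((a == 1) & (b == 1)))
    only_a = int(np.sum((a == 1) & (b == 0)))
    only_b = int(np.sum((a == 0) & (b == 1)))
    neither = int(np.sum((a == 0) & (b == 0)))
    return np.array([both, only_a, only_b, neither], dtype=np.int64)


def rescale_joint_counts(raw: np.ndarray, t_star: int, t: int) -> np.ndarray:
    """Rescale integer counts to sum exactly to ``t`` (largest remainder).

    The multinomial likelihood needs integer counts, so the proportional
    targets ``raw * t / t_star`` are floored and the leftover units assigned
    to the cells with the largest fractional remainders, ties broken toward
    the lowest cell index.
    """
    raw = np.asarray(raw, dtype=np.int64)
    if t_star <= 0:
        raise ValueError("t_star must be positive")
    if t < 1:
        raise ValueError("t must be >= 1")
    if raw.sum() != t_star:
        raise ValueError("raw counts must sum to t_star")
    exact = raw * (t / t_star)
    base = np.floor(exact).astype(np.int64)
    shortfall = int(t - base.sum())
    if shortfall:
        remainders = exact - base
        # stable argsort ascending; take the last `shortfall` = largest
        # remainders, with ties resolved toward the lowest index
        order = np.argsort(-remainders, kind="stable")
        base[order[:shortfall]] += 1
    return base


def aggregate_directional_counts(voxel_counts: np.ndarray, q: float = 0.90) -> float:
    """Summarize voxel-level stream counts by an upper quantile.

    The default 90th percentile reflects the strongest anatomical
    connectivity between the regions while resisting single-voxel outliers.
    Linear interpolation between order statistics.
    """
    x = np.asarray(voxel_counts, dtype=float)
    if x.size == 0:
        raise ValueError("voxel_counts must be non-empty")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    return float(np.quantile(x, q))


def symmetrize_pair_counts(count_ab: float, count_ba: float) -> float:
    """Impose symmetry on directional tractography counts via the maximum."""
    if count_ab < 0 or count_ba < 0:
        raise ValueError("counts must be non-negative")
    return max(count_ab, count_ba)


def combine_scans_and_rescale(
    counts_per_scan: np.ndarray,
    m_star: int,
    m: int,
    pair: tuple[str, str] = ("", ""),
    subject_id: str = "",
) -> StructuralCount:
    """Average per-scan counts and rescale trials from ``m_star`` to ``m``.

    The average of quantile-aggregated counts may be non-integer; the final
    scaled count is rounded to the nearest integer (binomial likelihood
    requires an integer) and clamped to ``[0, m]``.
    """
    x = np.asarray(counts_per_scan, dtype=float)
    if m_star <= 0:
        raise ValueError("m_star must be positive")
    if m < 1:
        raise ValueError("m must be >= 1")
    if x.size == 0:
        raise ValueError("counts_per_scan must be non-empty")
    s_star = float(x.mean())
    s = int(np.clip(round(s_star * m / m_star), 0, m))
    return StructuralCount(
        pair=pair,
        subject_id=subject_id,
        raw_count=s_star,
        raw_trials=m_star,
        scaled_count=s,
        scaled_trials=m,
    )
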