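"""Mean- and median-type residual-based irregularity analysis.

Both variants treat the nucleus as nominally circular: the radial profile
of a perfect circle is constant, so its residuals about any central value
vanish.  The mean-type analysis takes residuals about the mean radial
distance, the median-type about the median (robust to up to half the
profile being corrupted).  Each reports the mean (mu) and the N-1
denominator standard deviation (sigma) of the absolute residuals; both
grow with membrane irregularity and are exactly zero for a circle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

__all__ = ["ResidualResult", "mean_residual_analysis", "median_residual_analysis"]


@dataclass(frozen=True)
class ResidualResult:
    """Residual summary for one radial profile.

    ``center`` is the mean or median radial distance (pixels); ``resi`` the
    absolute residuals about it; ``mu``/``sigma`` their mean and sample
    (N-1) standard deviation.
    """

    kind: str  # "mean" or "median"
    center: float
    resi: np.ndarray
    mu: float
    sigma: float


def _residual_summary(profile: np.ndarray, center: float, kind: str) -> ResidualResult:
    resi = np.abs(profile - center)
    mu = float(resi.mean())
    sigma = float(resi.std(ddof=1))
    return ResidualResult(kind=kind, center=float(center), resi=resi, mu=mu, sigma=sigma)


def _check_profile(profile: np.ndarray) -> np.ndarray:
    d = np.asarray(profile, dtype=np.float64)
    if d.ndim != 1:
        raise ParameterError("profile must be 1-D")
    if len(d) < 2:
        raise ParameterError("need at least 2 points (sigma undefined)")
    return d


def mean_residual_analysis(profile: np.ndarray) -> ResidualResult:
    """Residuals about the mean radial distance: resi_i = |d_i - d_mean|."""
    d = _check_profile(profile)
    return _residual_summary(d, d.mean(), "mean")


def median_residual_analysis(profile: np.ndarray) -> ResidualResult:
    """Residuals about the median radial distance.

    For odd N the median is the ((N+1)/2)-th sorted value; for even N the
    average of the two middle sorted values (standard convention).
    """
    d = _check_profile(profile)
    return _residual_summary(d, float(np.median(d)), "median")
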