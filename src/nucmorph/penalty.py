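"""Penalty-driven smoothing analysis (PD score).

The radial profile of the nuclear membrane contour is smoothed with a
moving-average filter of odd span (3, 5, 7 or 9).  A smooth contour barely
moves under smoothing, so the per-point absolute difference between the
original and smoothed profiles measures local irregularity.  Differences
are normalized by their own mean, binned at ratio cut points 0.1 / 0.2 /
0.3, and the bin occupancy fractions are combined with penalty weights
c1 < c2 < c3 < c4 drawn from a linear, quadratic or cubic function:

    PD = c1*p1 + c2*p2 + c3*p3 + c4*p4

so PD ranges from c1 (every point close to the smoothed curve) to c4
(every point deviating strongly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .geometry import Contour, compute_centroid, radial_distances

__all__ = [
    "PENALTY_TABLE",
    "PenaltyConfig",
    "PDResult",
    "smooth_profile",
    "absolute_difference",
    "normalized_ratios",
    "partition_fractions",
    "pd_score",
    "penalty_driven_score",
]

#: Penalty constants (c1, c2, c3, c4) per named function.
PENALTY_TABLE: dict[str, tuple[float, float, float, float]] = {
    "linear": (1.0, 2.0, 3.0, 4.0),
    "quadratic": (1.0, 4.0, 9.0, 16.0),
    "cubic": (1.0, 8.0, 27.0, 64.0),
}

SPANS = (3, 5, 7, 9)


@dataclass(frozen=True)
class PenaltyConfig:
    """Span, penalty constants and ratio bin edges for the PD score."""

    span: int = 3
    function: str = "linear"
    penalties: tuple[float, float, float, float] | None = None
    bin_edges: tuple[float, float, float] = (0.1, 0.2, 0.3)
    boundary: str = "wrap"  # "wrap" (closed contour) or "shrink" (MATLAB-style)

    def __post_init__(self) -> None:
        if self.span < 3 or self.span % 2 == 0:
            raise ParameterError("span must be an odd integer >= 3")
        if self.penalties is None:
            if self.function not in PENALTY_TABLE:
                raise ParameterError(
                    "unknown penalty function %r (choose from %s)"
                    % (self.function, sorted(PENALTY_TABLE))
                )
            object.__setattr__(self, "penalties", PENALTY_TABLE[self.function])
        c1, c2, c3, c4 = self.penalties
        if not (c1 < c2 < c3 < c4):
            raise ParameterError("penalties must satisfy c1 < c2 < c3 < c4")
        if self.boundary not in ("wrap", "shrink"):
            raise ParameterError("boundary must be 'wrap' or 'shrink'")
        if not (0 < self.bin_edges[0] < self.bin_edges[1] < self.bin_edges[2]):
            raise ParameterError("bin edges must be strictly increasing and > 0")


@dataclass(frozen=True)
class PDResult:
    """PD score with all intermediates of the computation."""

    d: np.ndarray
    d_s: np.ndarray
    diff: np.ndarray
    mu_pd: float
    rat: np.ndarray
    fractions: tuple[float, float, float, float]
    pd: float
    config: PenaltyConfig = field(repr=False, default=PenaltyConfig())


def smooth_profile(
    profile: np.ndarray, span: int, boundary: str = "wrap"
) -> np.ndarray:
    """Moving-average smoothing of a radial profile.

    Filter coefficients are ``1/span`` over a centered window.  The profile
    belongs to a closed curve, so the default boundary handling wraps the
    window circularly, which makes the result independent of where the
    contour trace started.  ``boundary="shrink"`` instead shrinks the window
    symmetrically near the sequence ends (the convention of MATLAB's
    ``smooth``), kept as an explicit deviation knob.
    """
    d = np.asarray(profile, dtype=np.float64)
    if d.ndim != 1:
        raise ParameterError("profile must be 1-D")
    if span % 2 == 0 or span < 3:
        raise ParameterError("span must be an odd integer >= 3")
    if span > len(d):
        raise ParameterError("span exceeds profile length")
    if boundary == "wrap":
        return ndimage.uniform_filter1d(d, size=span, mode="wrap")
    if boundary == "shrink":
        out = ndimage.uniform_filter1d(d, size=span, mode="nearest")
        half = span // 2
        n = len(d)
        for i in range(half):
            k = i  # largest centered half-window that fits
            out[i] = d[: 2 * k + 1].mean() if k else d[0]
            out[n - 1 - i] = d[n - 2 * k - 1 :].mean() if k else d[-1]
        return out
    raise ParameterError("boundary must be 'wrap' or 'shrink'")


def absolute_difference(profile: np.ndarray, smoothed: np.ndarray) -> np.ndarray:
    """Per-point absolute difference |d - d_s|."""
    d = np.asarray(profile, dtype=np.float64)
    ds = np.asarray(smoothed, dtype=np.float64)
    if d.shape != ds.shape:
        raise ParameterError("profile and smoothed profile differ in length")
    return np.abs(d - ds)


def normalized_ratios(diff: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute difference mu_PD and the normalized ratios diff/mu_PD.

    A perfectly smooth contour has mu_PD = 0; its ratios are defined as 0
    so the PD score collapses to the minimum penalty c1.
    """
    dif = np.asarray(diff, dtype=np.float64)
    if dif.size == 0:
        raise ParameterError("empty difference sequence")
    mu = float(dif.mean())
    if mu == 0.0:
        return 0.0, np.zeros_like(dif)
    return mu, dif / mu


def partition_fractions(
    rat: np.ndarray, bin_edges: tuple[float, float, float] = (0.1, 0.2, 0.3)
) -> tuple[float, float, float, float]:
    """Occupancy fractions of the ratio bins.

    Bins are half-open, [0, e1), [e1, e2), [e2, e3), [e3, inf), so each
    point falls in exactly one bin and the fractions sum to 1.
    """
    r = np.asarray(rat, dtype=np.float64)
    if r.size == 0:
        raise ParameterError("empty ratio sequence")
    edges = [0.0, *bin_edges, np.inf]
    counts, _ = np.histogram(r, bins=edges)
    return tuple(counts / r.size)


def pd_score(
    fractions: tuple[float, float, float, float], config: PenaltyConfig
) -> float:
    """PD = c1*p1 + c2*p2 + c3*p3 + c4*p4."""
    p = np.asarray(fractions, dtype=np.float64)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ParameterError("partition fractions must sum to 1")
    return float(np.dot(config.penalties, p))


def penalty_driven_score(contour: Contour, config: PenaltyConfig) -> PDResult:
    """Full PD computation for one contour: centroid, radial profile,
    smoothing, normalized differences, bin fractions, penalty score."""
    d = radial_distances(contour, compute_centroid(contour))
    d_s = smooth_profile(d, config.span, boundary=config.boundary)
    diff = absolute_difference(d, d_s)
    mu_pd, rat = normalized_ratios(diff)
    fractions = partition_fractions(rat, config.bin_edges)
    pd = pd_score(fractions, config)
    return PDResult(
        d=d, d_s=d_s, diff=diff, mu_pd=mu_pd, rat=rat,
        fractions=fractions, pd=pd, config=config,
    )
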