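"""Time-domain precision measures for fixation gaze segments.

All measures operate on a :class:`GazeSegment`, a fixed-rate window of 2-D
gaze positions in degrees.  Six quantities characterize such a window:

* **RMS-S2S** — root mean square of the displacement between successive
  samples; at a fixed sampling rate it is proportional to the average
  intra-fixation velocity.
* **STD** — Euclidean combination of the per-axis standard deviations
  about the centroid; a spatial-spread measure.
* **BCEA** — bivariate contour ellipse area, the area of the ellipse that
  contains a fraction ``P = 1 - exp(-k)`` of the samples, derived from the
  2-D covariance.  Its square root is directly comparable to STD.
* **signal magnitude** — ``sqrt(RMS-S2S^2 + STD^2)``, a composite noise
  level weighing step size and spread equally.
* **signal type** — ``RMS-S2S / STD``, a dimensionless index of signal
  color: sqrt(2) for white signals, below for smooth/persistent signals,
  above for spiky/anti-persistent ones.
* **alpha** — the PSD scaling exponent, computed in :mod:`gazenoise.spectral`.

Conventions fixed here: per-axis dispersion uses the population (1/n)
denominator; RMS-S2S averages the n-1 squared steps with a 1/(n-1)
denominator; the correlation in BCEA uses the same population moments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import (
    DegenerateSegmentError,
    InvalidSegmentError,
    UndefinedSignalTypeError,
)

__all__ = [
    "GazeSegment",
    "PrecisionSummary",
    "EllipseParams",
    "rms_s2s",
    "std_2d",
    "bcea",
    "sqrt_bcea",
    "bcea_ellipse",
    "points_inside_bcea_ellipse",
    "signal_magnitude",
    "signal_type",
    "signal_type_bound",
    "summarize",
]


@dataclass(frozen=True)
class GazeSegment:
    """A fixed-rate window of 2-D gaze positions.

    Parameters
    ----------
    x, y
        Horizontal and vertical gaze positions in degrees.  Equal length,
        at least 2 samples, all finite (missing data must be handled
        upstream; no interpolation is performed here).
    fs
        Sampling frequency in Hz, > 0.
    """

    x: np.ndarray
    y: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
            raise InvalidSegmentError(
                "x and y must be 1-D sequences of equal length"
            )
        if x.size < 2:
            raise InvalidSegmentError("segment needs at least 2 samples")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise InvalidSegmentError("segment contains non-finite values")
        if not (self.fs > 0 and math.isfinite(self.fs)):
            raise InvalidSegmentError("sampling frequency must be positive")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "fs", float(self.fs))

    def __len__(self) -> int:
        return self.x.size

    @property
    def xy(self) -> np.ndarray:
        """Positions as an (n, 2) array."""
        return np.column_stack((self.x, self.y))


@dataclass(frozen=True)
class PrecisionSummary:
    """The precision measures computed for one segment (degrees, except
    the dimensionless ``signal_type`` and ``alpha``)."""

    rms_s2s: float
    std: float
    sqrt_bcea: float
    signal_magnitude: float
    signal_type: float
    alpha: Optional[float] = None


@dataclass(frozen=True)
class EllipseParams:
    """Eigenstructure of a segment's 2-D covariance.

    ``lambda1 >= lambda2`` are the eigenvalues (squared degrees; squared
    semi-axis lengths of the k=1 BCEA ellipse up to a factor 2k),
    ``aspect_ratio = sqrt(lambda1/lambda2)`` and ``orientation`` is the
    major-axis angle from the positive x-axis, counter-clockwise, mapped
    into (-pi/2, pi/2] (ellipse orientation is axial).
    """

    lambda1: float
    lambda2: float
    aspect_ratio: float
    orientation: float


def _steps_sq(seg: GazeSegment) -> np.ndarray:
    return np.diff(seg.x) ** 2 + np.diff(seg.y) ** 2


def rms_s2s(seg: GazeSegment) -> float:
    """Root mean square of sample-to-sample displacement (degrees).

    Averages the n-1 squared Euclidean steps with a 1/(n-1) denominator.
    Returns 0 for a constant segment.
    """
    return float(np.sqrt(np.mean(_steps_sq(seg))))


def std_2d(seg: GazeSegment) -> float:
    """Euclidean combination of per-axis standard deviations (degrees).

    Per-axis dispersion about the centroid uses the population (1/n)
    denominator; no ddof knob is exposed.
    """
    return float(np.sqrt(np.var(seg.x) + np.var(seg.y)))


def _population_cov(seg: GazeSegment) -> np.ndarray:
    xy = seg.xy - seg.xy.mean(axis=0)
    return (xy.T @ xy) / len(seg)


def bcea(seg: GazeSegment, k: float = 1.0) -> float:
    """Bivariate contour ellipse area, ``2*k*pi*sx*sy*sqrt(1-rho^2)``.

    ``k = -log(1-P)`` sets the containment fraction; the default k=1
    corresponds to P = 1 - 1/e = 0.632.  Standard deviations and the
    correlation rho use population (1/n) moments.  Units: squared degrees.
    """
    if len(seg) < 3:
        raise InvalidSegmentError("BCEA needs at least 3 samples")
    if k <= 0:
        raise InvalidSegmentError("k must be positive")
    vx, vy = np.var(seg.x), np.var(seg.y)
    if vx == 0.0 or vy == 0.0:
        raise DegenerateSegmentError(
            "zero variance on an axis: correlation undefined"
        )
    cov = _population_cov(seg)
    rho2 = cov[0, 1] ** 2 / (vx * vy)
    rho2 = min(rho2, 1.0)  # guard rounding above 1
    return float(2.0 * k * np.pi * np.sqrt(vx * vy) * np.sqrt(1.0 - rho2))


def sqrt_bcea(seg: GazeSegment, k: float = 1.0) -> float:
    """Square root of BCEA (degrees), directly comparable to STD."""
    return math.sqrt(bcea(seg, k=k))


def bcea_ellipse(seg: GazeSegment) -> EllipseParams:
    """Eigendecomposition of the segment covariance underlying BCEA.

    Raises :class:`DegenerateSegmentError` for a rank-deficient
    covariance (collinear or constant data), where the aspect ratio and
    orientation are undefined.
    """
    if len(seg) < 3:
        raise InvalidSegmentError("ellipse recovery needs at least 3 samples")
    cov = _population_cov(seg)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam1, lam2 = float(evals[1]), float(evals[0])
    if lam2 <= 0.0 or lam2 <= lam1 * 1e-12:
        raise DegenerateSegmentError("rank-deficient segment covariance")
    q = evecs[:, 1]  # major-axis eigenvector
    theta = math.atan2(q[1], q[0])
    # axial angle: map into (-pi/2, pi/2]
    if theta <= -math.pi / 2:
        theta += math.pi
    elif theta > math.pi / 2:
        theta -= math.pi
    return EllipseParams(
        lambda1=lam1,
        lambda2=lam2,
        aspect_ratio=math.sqrt(lam1 / lam2),
        orientation=theta,
    )


def points_inside_bcea_ellipse(
    seg: GazeSegment, points: Optional[np.ndarray] = None, k: float = 1.0
) -> np.ndarray:
    """Boolean mask of points inside the segment's BCEA ellipse.

    A point is inside when its squared Mahalanobis distance from the
    segment centroid (under the population covariance) is at most ``2k``,
    which contains the fraction ``P = 1 - exp(-k)`` of an ideal Gaussian
    sample.  ``points`` defaults to the segment's own samples.
    """
    if k <= 0:
        raise InvalidSegmentError("k must be positive")
    cov = _population_cov(seg)
    if np.linalg.det(cov) <= 0:
        raise DegenerateSegmentError("rank-deficient segment covariance")
    pts = seg.xy if points is None else np.asarray(points, dtype=float)
    centered = pts - seg.xy.mean(axis=0)
    d2 = np.einsum("ij,jk,ik->i", centered, np.linalg.inv(cov), centered)
    return d2 <= 2.0 * k


def signal_magnitude(rms: float, std: float) -> float:
    """Composite noise level ``sqrt(rms^2 + std^2)`` in degrees."""
    if rms < 0 or std < 0:
        raise InvalidSegmentError("magnitudes must be non-negative")
    return math.hypot(rms, std)


def signal_type(rms: float, std: float) -> float:
    """Signal-color index ``rms / std`` (dimensionless).

    sqrt(2) for white signals; smaller for smooth/persistent signals,
    larger (up to about 2) for spiky anti-persistent signals.  Undefined
    for a constant segment (std == 0).
    """
    if rms < 0 or std < 0:
        raise InvalidSegmentError("magnitudes must be non-negative")
    if std == 0.0:
        raise UndefinedSignalTypeError("signal type undefined for zero STD")
    return rms / std


def signal_type_bound(n: int) -> float:
    """Exact supremum of the signal-type value for an n-sample segment.

    The ratio of summed squared steps to summed squared deviations is
    maximized by the top eigenvalue of the path-graph Laplacian,
    ``4*cos^2(pi/(2n))``; combined with the 1/(n-1) vs 1/n denominators
    this gives ``2*cos(pi/(2n)) * sqrt(n/(n-1))``, which approaches the
    nominal upper bound of 2 from above as n grows.
    """
    if n < 2:
        raise InvalidSegmentError("bound defined for n >= 2")
    return 2.0 * math.cos(math.pi / (2 * n)) * math.sqrt(n / (n - 1))


def summarize(
    seg: GazeSegment, k: float = 1.0, with_alpha: bool = False
) -> PrecisionSummary:
    """Compute all time-domain measures (optionally the PSD exponent) for
    one segment."""
    r = rms_s2s(seg)
    s = std_2d(seg)
    alpha = None
    if with_alpha:
        from .spectral import alpha_2d

        alpha = alpha_2d(seg)
    return PrecisionSummary(
        rms_s2s=r,
        std=s,
        sqrt_bcea=sqrt_bcea(seg, k=k),
        signal_magnitude=signal_magnitude(r, s),
        signal_type=signal_type(r, s),
        alpha=alpha,
    )
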