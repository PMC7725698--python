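"""Power-spectral-density slope estimation.

A gaze signal's spectral color is summarized by the scaling exponent
``alpha`` of a power law ``S(f) ∝ 1/f^alpha``: alpha = 0 is white (flat
spectrum, no temporal dependence), alpha = 1 pink (persistent, smooth),
alpha < 0 anti-persistent (spiky, e.g. high-frequency oscillation
artifacts).  alpha is estimated by an ordinary least-squares line on the
log10 periodogram versus log10 frequency; alpha is the negated slope.

The periodogram is raw — no taper, no Welch averaging, no frequency-band
restriction — computed on the mean-removed signal with the DC bin dropped.
Single-realization estimates are therefore noisy; analyses here always
average over realizations.  Callers needing a band restriction can slice
the :class:`PSDResult` before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InvalidSegmentError
from .measures import GazeSegment

__all__ = ["PSDResult", "AlphaFit", "periodogram_psd", "fit_alpha", "alpha_2d"]

#: minimum positive-frequency bins with power required for a slope fit
_MIN_FIT_BINS = 4


@dataclass(frozen=True)
class PSDResult:
    """One-sided power spectral density: positive frequencies (Hz,
    ascending, DC excluded) and density (squared degrees per Hz)."""

    freqs: np.ndarray
    power: np.ndarray


@dataclass(frozen=True)
class AlphaFit:
    """Result of the log-log line fit: ``alpha`` (negated slope),
    ``intercept`` (log10 power at log10 f = 0) and the bin count used."""

    alpha: float
    intercept: float
    n_bins_used: int


def periodogram_psd(x, fs: float) -> PSDResult:
    """Raw (boxcar, unsmoothed) periodogram of a mean-removed 1-D signal.

    The DC bin is dropped; the Nyquist bin is retained for even lengths.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise InvalidSegmentError("periodogram needs a 1-D signal, n >= 8")
    if not np.all(np.isfinite(x)):
        raise InvalidSegmentError("signal contains non-finite values")
    if fs <= 0:
        raise InvalidSegmentError("sampling frequency must be positive")
    freqs, power = sps.periodogram(
        x, fs=fs, window="boxcar", detrend="constant", scaling="density"
    )
    return PSDResult(freqs=freqs[1:], power=power[1:])


def fit_alpha(psd: PSDResult) -> AlphaFit:
    """OLS line on (log10 f, log10 S); ``alpha`` is the negated slope.

    Zero-power bins are excluded (their log is undefined); at least 4
    usable bins are required.
    """
    mask = psd.power > 0.0
    n_used = int(mask.sum())
    if n_used < _MIN_FIT_BINS:
        raise InvalidSegmentError(
            f"need at least {_MIN_FIT_BINS} nonzero-power bins, got {n_used}"
        )
    logf = np.log10(psd.freqs[mask])
    logp = np.log10(psd.power[mask])
    slope, intercept = np.polyfit(logf, logp, 1)
    return AlphaFit(alpha=float(-slope), intercept=float(intercept), n_bins_used=n_used)


def alpha_2d(seg: GazeSegment) -> float:
    """Scaling exponent of a 2-D segment: fitted per axis, then averaged.

    Use :func:`fit_alpha` on each axis's periodogram directly when the
    per-axis values are of interest."""
    ax = fit_alpha(periodogram_psd(seg.x, seg.fs)).alpha
    ay = fit_alpha(periodogram_psd(seg.y, seg.fs)).alpha
    return 0.5 * (ax + ay)
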