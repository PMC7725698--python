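"""Spectral-shaping synthesizer for artificial eye-tracker noise.

Generates 2-D fixation noise with four independently controlled
properties:

1. **type** — the spectral color, set either directly as the scaling
   exponent ``alpha`` of a 1/f^alpha power spectrum, or as a signal-type
   value resolved to alpha through a Monte-Carlo
   :class:`~gazenoise.mapping.MappingTable`;
2. **magnitude** — the output is uniformly rescaled so that a chosen
   measure (RMS-S2S, STD, or signal magnitude) equals the requested value
   exactly;
3. **distribution** — the white seed noise is Gaussian, uniform
   (on [-sqrt(3), sqrt(3)], unit variance), or drawn from an empirical
   CDF by inverse transform sampling;
4. **anisotropy** — an aspect ratio applied to the horizontal component
   followed by a rotation of the major axis.

Procedure per channel: draw white noise, Fourier transform, multiply the
coefficient at bin k by k^(-alpha/2) (the amplitude spectrum of 1/f^alpha
noise; the DC coefficient is zeroed), inverse transform, subtract the
centroid.  Then apply anisotropy and the exact magnitude scaling.
Because the shaping runs through the FFT the output is cyclical: the last
sample connects smoothly to the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .errors import ConfigError, DegenerateSegmentError
from .measures import GazeSegment, rms_s2s, signal_magnitude, std_2d

__all__ = [
    "EmpiricalCDF",
    "NoiseSpec",
    "generate_white",
    "shape_spectrum",
    "synthesize_noise",
]

MAGNITUDE_KINDS = ("rms_s2s", "std", "signal_magnitude")


@dataclass(frozen=True)
class EmpiricalCDF:
    """An empirical cumulative distribution for inverse transform sampling.

    ``values`` are ascending sample values (degrees), ``probs`` the
    ascending cumulative probabilities, ending at exactly 1.  Sampling
    interpolates linearly between the knots, so small empirical samples
    yield a continuous distribution rather than atoms.
    """

    values: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        probs = np.asarray(self.probs, dtype=float)
        if values.ndim != 1 or values.shape != probs.shape or values.size < 1:
            raise ConfigError("values and probs must be equal-length 1-D")
        if np.any(np.diff(values) < 0) or np.any(np.diff(probs) < 0):
            raise ConfigError("values and probs must be ascending")
        if not np.isclose(probs[-1], 1.0):
            raise ConfigError("probs must end at 1")
        if probs[0] < 0:
            raise ConfigError("probs must be within [0, 1]")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "probs", probs)

    @classmethod
    def from_samples(cls, samples) -> "EmpiricalCDF":
        """Build the CDF of an observed sample, knot i at p=(i+1)/n."""
        s = np.sort(np.asarray(samples, dtype=float))
        n = s.size
        return cls(values=s, probs=np.arange(1, n + 1) / n)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Inverse-transform draws (Devroye): uniforms through the
        linearly interpolated quantile function."""
        u = rng.uniform(size=n)
        return np.interp(u, self.probs, self.values)

    def to_csv(self, path) -> None:
        arr = np.column_stack((self.values, self.probs))
        np.savetxt(path, arr, delimiter=",", header="value,prob", comments="")

    @classmethod
    def from_csv(cls, path) -> "EmpiricalCDF":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(values=arr[:, 0], probs=arr[:, 1])


@dataclass(frozen=True)
class NoiseSpec:
    """Full specification of a noise signal to synthesize.

    Exactly one of ``alpha`` (spectral exponent) or ``signal_type``
    (resolved via a mapping table for length ``n``) must be given.
    ``magnitude_kind`` names the measure pinned to ``magnitude_value``
    exactly.  ``seed`` deterministically derives independent substreams
    for the horizontal and vertical channels.
    """

    n: int
    magnitude_value: float
    magnitude_kind: str = "signal_magnitude"
    alpha: Optional[float] = None
    signal_type: Optional[float] = None
    distribution: Union[str, EmpiricalCDF] = "gaussian"
    aspect_ratio: float = 1.0
    orientation: float = 0.0
    fs: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 8:
            raise ConfigError("n must be at least 8")
        if (self.alpha is None) == (self.signal_type is None):
            raise ConfigError("give exactly one of alpha or signal_type")
        if self.signal_type is not None and not (0.0 < self.signal_type < 2.0):
            raise ConfigError("signal_type target must lie in (0, 2)")
        if self.magnitude_kind not in MAGNITUDE_KINDS:
            raise ConfigError(f"magnitude_kind must be one of {MAGNITUDE_KINDS}")
        if self.magnitude_value <= 0:
            raise ConfigError("magnitude_value must be positive")
        if self.aspect_ratio < 1.0:
            raise ConfigError("aspect_ratio must be >= 1")
        if isinstance(self.distribution, str) and self.distribution not in (
            "gaussian",
            "uniform",
        ):
            raise ConfigError(
                "distribution must be 'gaussian', 'uniform' or an EmpiricalCDF"
            )


def generate_white(
    n: int,
    distribution: Union[str, EmpiricalCDF] = "gaussian",
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Draw n i.i.d. white-noise samples.

    ``gaussian`` draws standard normals; ``uniform`` draws from
    [-sqrt(3), sqrt(3)] (unit variance, so all distributions start at a
    comparable scale); an :class:`EmpiricalCDF` is sampled by inverse
    transform.
    """
    if n < 1:
        raise ConfigError("n must be positive")
    rng = np.random.default_rng(rng)
    if isinstance(distribution, EmpiricalCDF):
        return distribution.sample(n, rng)
    if distribution == "gaussian":
        return rng.standard_normal(n)
    if distribution == "uniform":
        s3 = np.sqrt(3.0)
        return rng.uniform(-s3, s3, size=n)
    raise ConfigError(f"unknown distribution {distribution!r}")


def shape_spectrum(white, alpha: float) -> np.ndarray:
    """Impose a 1/f^alpha power spectrum on a sequence by FFT filtering.

    The positive-frequency Fourier coefficient at bin k is multiplied by
    ``k**(-alpha/2)`` — the amplitude spectrum of 1/f^alpha noise on the
    bin-index frequency axis (physical frequency units cancel after the
    magnitude rescaling downstream, so the result is sampling-rate
    agnostic).  The DC coefficient is zeroed, which both centers the
    output and avoids the f -> 0 divergence for alpha > 0.  Negative
    alpha amplifies high frequencies (anti-persistent output).  For
    alpha = 0 the output is exactly the mean-removed input.  Operates on
    the last axis, so stacked realizations shape in one call.
    """
    x = np.asarray(white, dtype=float)
    if x.shape[-1] < 2:
        raise ConfigError("need at least 2 samples to shape")
    if not np.all(np.isfinite(x)):
        raise ConfigError("input contains non-finite values")
    n = x.shape[-1]
    coef = np.fft.rfft(x, axis=-1)
    k = np.arange(coef.shape[-1], dtype=float)
    gain = np.zeros_like(k)
    gain[1:] = k[1:] ** (-alpha / 2.0)
    coef = coef * gain
    return np.fft.irfft(coef, n=n, axis=-1)


def _measure(kind: str, seg: GazeSegment) -> float:
    if kind == "rms_s2s":
        return rms_s2s(seg)
    if kind == "std":
        return std_2d(seg)
    return signal_magnitude(rms_s2s(seg), std_2d(seg))


def synthesize_noise(spec: NoiseSpec, mapping=None) -> GazeSegment:
    """Synthesize one 2-D noise segment according to ``spec``.

    When the spec targets a signal-type value, ``mapping`` must be a
    :class:`~gazenoise.mapping.MappingTable` built for ``spec.n`` samples;
    the target is inverted to an alpha through it.  The two channels use
    independent random substreams derived from ``spec.seed``.  The
    requested magnitude measure matches ``spec.magnitude_value`` exactly
    (uniform rescaling about the origin; the output is centered first, so
    the centroid stays at (0, 0)).
    """
    if spec.alpha is not None:
        alpha = spec.alpha
    else:
        if mapping is None:
            raise ConfigError("signal-type target requires a mapping table")
        if mapping.n_samples != spec.n:
            raise ConfigError(
                f"mapping built for n={mapping.n_samples}, spec has n={spec.n}"
            )
        from .mapping import lookup_alpha

        alpha = lookup_alpha(spec.signal_type, mapping)

    rng_x, rng_y = (
        np.random.default_rng(s)
        for s in np.random.SeedSequence(spec.seed).spawn(2)
    )
    sx = shape_spectrum(generate_white(spec.n, spec.distribution, rng_x), alpha)
    sy = shape_spectrum(generate_white(spec.n, spec.distribution, rng_y), alpha)
    # center on the centroid (DC removal already centers up to rounding)
    sx = sx - sx.mean()
    sy = sy - sy.mean()
    if spec.aspect_ratio != 1.0:
        sx = sx * spec.aspect_ratio
    if spec.orientation != 0.0:
        c, s = np.cos(spec.orientation), np.sin(spec.orientation)
        sx, sy = c * sx - s * sy, s * sx + c * sy
    seg = GazeSegment(x=sx, y=sy, fs=spec.fs)
    current = _measure(spec.magnitude_kind, seg)
    if current == 0.0:
        raise DegenerateSegmentError("synthesized segment has zero magnitude")
    scale = spec.magnitude_value / current
    return GazeSegment(x=sx * scale, y=sy * scale, fs=spec.fs)
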