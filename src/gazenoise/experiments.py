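"""Simulation and descriptive analyses built on the measures and synthesizer.

Three studies live here:

* :func:`window_length_experiment` — how each precision measure depends
  on the number of samples it is computed over.  Long isotropic noise
  sequences are generated at fixed signal magnitude for several
  asymptotic signal-type levels; a window of each requested length is
  positioned at random within each sequence and all measures computed.
  This exposes that RMS-S2S (and alpha) stabilize beyond roughly 30
  samples while STD and its relatives grow toward their asymptote for
  persistent (type < sqrt(2)) signals.
* :func:`rms_std_space` — a 2-D kernel-density summary of segments in
  the (STD, RMS-S2S) plane, where distance from the origin is signal
  magnitude and the tangent of the direction is signal type, plus the
  circular histogram of the signal-type direction.
* :func:`probit_distribution_fit` — Gaussianity assessment of pooled,
  per-window-centered gaze positions: the empirical CDF on a z-scaled
  (probit) ordinate is a straight line of slope 1/sigma for Gaussian
  data; a line is fitted to the central 80% of points, so heavy tails
  show up as departures outside the fitted band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegenerateSegmentError, GazeNoiseError
from .mapping import MappingTable, build_mapping, lookup_alpha
from .measures import (
    GazeSegment,
    PrecisionSummary,
    rms_s2s,
    signal_magnitude,
    signal_type,
    sqrt_bcea,
    std_2d,
)
from .spectral import alpha_2d
from .synth import NoiseSpec, synthesize_noise

__all__ = [
    "WindowStabilityResult",
    "SpaceDensity",
    "ProbitFit",
    "DEFAULT_TYPE_LEVELS",
    "window_length_experiment",
    "rms_std_space",
    "probit_distribution_fit",
]

MEASURE_NAMES = (
    "rms_s2s",
    "std",
    "sqrt_bcea",
    "signal_magnitude",
    "signal_type",
    "alpha",
)

#: asymptotic signal-type levels: strongly colored through white to spiky
DEFAULT_TYPE_LEVELS = (0.25, 0.75, 1.0, math.sqrt(2.0), 1.8)

#: window lengths spanning short to nearly the full sequence
DEFAULT_WINDOW_LENGTHS = (12, 18, 27, 40, 60, 90, 135, 200, 300, 450, 499)

#: smallest window for which the PSD slope fit is defined (>= 4 bins)
_MIN_ALPHA_WINDOW = 9


@dataclass(frozen=True)
class WindowStabilityResult:
    """Monte-Carlo means of each measure per (signal-type level, window
    length), in tidy form, plus the count of regenerated degenerate
    windows."""

    signal_type_levels: tuple
    window_lengths: tuple
    table: pd.DataFrame  # columns: level, window_length, measure, mean, sd
    reps: int
    n_regenerated: int

    def pivot(self, measure: str, value: str = "mean") -> pd.DataFrame:
        """One measure's mean (or per-rep "sd") as a
        (level x window_length) frame."""
        sub = self.table[self.table["measure"] == measure]
        return sub.pivot(index="level", columns="window_length", values=value)

    def sem(self, measure: str) -> pd.DataFrame:
        """Monte-Carlo standard error of the mean per cell."""
        return self.pivot(measure, value="sd") / math.sqrt(self.reps)


@dataclass(frozen=True)
class SpaceDensity:
    """KDE summary of the (STD, RMS-S2S) plane.

    ``density[i, j]`` is the density at (std_grid[j], rms_grid[i]);
    ``contour_levels`` are the retained (lowest dropped) equally spaced
    levels; the angular histogram covers directions in [0, pi/2].
    """

    std_grid: np.ndarray
    rms_grid: np.ndarray
    density: np.ndarray
    contour_levels: np.ndarray
    angle_bin_edges: np.ndarray
    angle_counts: np.ndarray


@dataclass(frozen=True)
class ProbitFit:
    """Straight-line fit to an empirical CDF on a probit ordinate over
    the most central points; ``1/slope`` estimates the Gaussian sigma."""

    slope: float
    intercept: float
    central_fraction: float
    n_points: int


def _window_measures(seg: GazeSegment, with_alpha: bool) -> Dict[str, float]:
    r, s = rms_s2s(seg), std_2d(seg)
    out = {
        "rms_s2s": r,
        "std": s,
        "sqrt_bcea": sqrt_bcea(seg),
        "signal_magnitude": signal_magnitude(r, s),
        "signal_type": signal_type(r, s),
        "alpha": alpha_2d(seg) if with_alpha else math.nan,
    }
    return out


def window_length_experiment(
    levels: Sequence[float] = DEFAULT_TYPE_LEVELS,
    magnitude: float = 0.5,
    seq_len: int = 500,
    window_lengths: Sequence[int] = DEFAULT_WINDOW_LENGTHS,
    reps: int = 200,
    seed: int = 0,
    mapping: Optional[MappingTable] = None,
    fs: float = 1000.0,
) -> WindowStabilityResult:
    """Monte-Carlo study of measure stability across window lengths.

    For each signal-type level and window length, ``reps`` fresh
    ``seq_len``-sample isotropic Gaussian sequences are synthesized at a
    fixed signal magnitude (degrees); one window of the given length is
    placed uniformly at random in each sequence; all measures are
    computed on the window and averaged.  Windows with degenerate
    covariance are regenerated (from a fresh sequence) and counted.
    The PSD exponent needs at least 9 samples; shorter windows record
    NaN for alpha.
    """
    window_lengths = tuple(sorted(int(w) for w in window_lengths))
    if window_lengths[0] < 6 or window_lengths[-1] >= seq_len:
        raise ConfigError("window lengths must lie in [6, seq_len)")
    if mapping is None:
        mapping = build_mapping(seq_len, seed=seed)
    alphas = {lv: lookup_alpha(lv, mapping) for lv in levels}

    master = np.random.default_rng(seed)
    rows = []
    n_regen = 0
    for lv in levels:
        for wl in window_lengths:
            acc = {m: [] for m in MEASURE_NAMES}
            for _ in range(reps):
                for attempt in range(50):
                    seg = synthesize_noise(
                        NoiseSpec(
                            n=seq_len,
                            alpha=alphas[lv],
                            magnitude_kind="signal_magnitude",
                            magnitude_value=magnitude,
                            fs=fs,
                            seed=int(master.integers(2**31)),
                        )
                    )
                    start = int(master.integers(0, seq_len - wl + 1))
                    win = GazeSegment(
                        x=seg.x[start : start + wl],
                        y=seg.y[start : start + wl],
                        fs=fs,
                    )
                    try:
                        vals = _window_measures(win, wl >= _MIN_ALPHA_WINDOW)
                        break
                    except DegenerateSegmentError:
                        n_regen += 1
                else:  # pragma: no cover - continuous noise never gets here
                    raise GazeNoiseError("could not draw a non-degenerate window")
                for m in MEASURE_NAMES:
                    acc[m].append(vals[m])
            for m in MEASURE_NAMES:
                rows.append(
                    {
                        "level": lv,
                        "window_length": wl,
                        "measure": m,
                        "mean": float(np.mean(acc[m])),
                        "sd": float(np.std(acc[m])),
                    }
                )
    return WindowStabilityResult(
        signal_type_levels=tuple(levels),
        window_lengths=window_lengths,
        table=pd.DataFrame(rows),
        reps=reps,
        n_regenerated=n_regen,
    )


def rms_std_space(
    summaries: Iterable[PrecisionSummary],
    grid_size: int = 128,
    n_levels: int = 16,
    angle_bins: int = 36,
    padding: float = 0.25,
    bandwidth=None,
) -> SpaceDensity:
    """Kernel-density summary of segments in the (STD, RMS-S2S) plane.

    A Gaussian-kernel KDE (Scott's rule bandwidth unless ``bandwidth``
    overrides) is evaluated on a rectangular grid padded beyond the data
    range; ``n_levels`` equally spaced contour levels are computed and
    the lowest dropped (it only outlines the KDE's support).  The
    circular histogram of direction angles arctan(RMS-S2S/STD) — whose
    tangent is the signal-type value — is returned alongside.
    """
    summaries = list(summaries)
    if len(summaries) < 30:
        raise ConfigError("need at least 30 summaries for a density summary")
    std = np.array([s.std for s in summaries])
    rms = np.array([s.rms_s2s for s in summaries])
    kde = stats.gaussian_kde(np.vstack((std, rms)), bw_method=bandwidth)

    def _axis(v: np.ndarray) -> np.ndarray:
        span = v.max() - v.min()
        pad = padding * span if span > 0 else 0.5 * abs(v.mean()) + 1e-6
        return np.linspace(v.min() - pad, v.max() + pad, grid_size)

    std_grid, rms_grid = _axis(std), _axis(rms)
    gs, gr = np.meshgrid(std_grid, rms_grid)
    density = kde(np.vstack((gs.ravel(), gr.ravel()))).reshape(gs.shape)
    levels = np.linspace(0.0, density.max(), n_levels + 1)[1:]
    angles = np.arctan2(rms, std)
    edges = np.linspace(0.0, np.pi / 2, angle_bins + 1)
    counts, _ = np.histogram(angles, bins=edges)
    return SpaceDensity(
        std_grid=std_grid,
        rms_grid=rms_grid,
        density=density,
        contour_levels=levels[1:],  # lowest level removed
        angle_bin_edges=edges,
        angle_counts=counts,
    )


def plot_space(sd: SpaceDensity, path) -> None:
    """Render a SpaceDensity to an image file (headless-safe)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, (ax, axp) = plt.subplots(
        1, 2, figsize=(9, 4), subplot_kw=None, constrained_layout=True
    )
    ax.contour(sd.std_grid, sd.rms_grid, sd.density, levels=sd.contour_levels)
    lim = max(sd.std_grid[-1], sd.rms_grid[-1])
    ax.plot([0, lim], [0, lim * math.sqrt(2)], "g--", lw=1, label="white (√2)")
    ax.set_xlabel("STD (deg)")
    ax.set_ylabel("RMS-S2S (deg)")
    ax.legend(loc="upper right", fontsize=8)
    centers = 0.5 * (sd.angle_bin_edges[:-1] + sd.angle_bin_edges[1:])
    axp.bar(centers, sd.angle_counts, width=np.diff(sd.angle_bin_edges))
    axp.set_xlabel("direction angle (rad)")
    axp.set_ylabel("count")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def probit_distribution_fit(
    segments: Iterable[GazeSegment], central_fraction: float = 0.8
) -> Dict[str, ProbitFit]:
    """Per-axis probit line fit to pooled, per-segment-centered positions.

    Each segment is centered on its own centroid; positions are pooled
    per axis; the empirical CDF (plotting positions (i-1/2)/n) is mapped
    through the standard-normal quantile function; an OLS line is fitted
    to the points whose abscissa lies within the central
    ``central_fraction`` band (10th-90th percentile by default).  For
    Gaussian data the line has slope 1/sigma; heavy tails flatten the
    curve outside the band.
    """
    if not (0.0 < central_fraction <= 1.0):
        raise ConfigError("central_fraction must be in (0, 1]")
    pooled = {"x": [], "y": []}
    for seg in segments:
        pooled["x"].append(seg.x - seg.x.mean())
        pooled["y"].append(seg.y - seg.y.mean())
    out: Dict[str, ProbitFit] = {}
    for axis, chunks in pooled.items():
        if not chunks:
            raise ConfigError("no segments supplied")
        v = np.sort(np.concatenate(chunks))
        if v.size < 100:
            raise ConfigError("pooled sample must have at least 100 points")
        if v[0] == v[-1]:
            raise DegenerateSegmentError("pooled positions have zero variance")
        p = (np.arange(1, v.size + 1) - 0.5) / v.size
        z = stats.norm.ppf(p)
        tail = 0.5 * (1.0 - central_fraction) * 100.0
        lo, hi = np.percentile(v, [tail, 100.0 - tail])
        mask = (v >= lo) & (v <= hi)
        slope, intercept = np.polyfit(v[mask], z[mask], 1)
        if slope <= 0:
            raise DegenerateSegmentError("non-positive probit slope")
        out[axis] = ProbitFit(
            slope=float(slope),
            intercept=float(intercept),
            central_fraction=central_fraction,
            n_points=int(mask.sum()),
        )
    return out
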