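"""Monte-Carlo mapping between the PSD scaling exponent and signal type.

The signal-type value (RMS-S2S/STD) of a 1/f^alpha signal depends on
alpha *and* on the number of samples in the window: for alpha > 0 the
STD of a short window underestimates the asymptotic spread, raising the
ratio.  No closed form is known, so the mapping is tabulated by
simulation: for each alpha on a grid, many isotropic Gaussian
realizations are spectrally shaped, their signal-type values measured,
and the mean stored.  Inverting the (monotone non-increasing) table then
turns a requested signal-type value into the alpha the synthesizer needs.

Raw Monte-Carlo means can show small local inversions, which would break
the inverse lookup; an isotonic (non-increasing) regression is applied
before the table is used.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .errors import ConfigError, DegenerateSegmentError, MappingRangeError
from .synth import shape_spectrum

__all__ = ["MappingTable", "build_mapping", "lookup_alpha", "cached_mapping"]

# The anti-persistent side extends to -4 so that signal-type targets up
# to ~1.89 (spiky, HFO-like) stay invertible at common window lengths.
DEFAULT_ALPHA_GRID = np.round(np.arange(-4.0, 3.0 + 1e-9, 0.05), 10)


@dataclass(frozen=True)
class MappingTable:
    """Tabulated mean signal-type value per scaling exponent, for windows
    of ``n_samples`` samples, averaged over ``reps`` realizations."""

    n_samples: int
    alphas: np.ndarray
    mean_signal_type: np.ndarray
    reps: int
    seed: int

    def __post_init__(self) -> None:
        alphas = np.asarray(self.alphas, dtype=float)
        mst = np.asarray(self.mean_signal_type, dtype=float)
        if alphas.shape != mst.shape or alphas.ndim != 1 or alphas.size < 2:
            raise ConfigError("alphas and mean_signal_type must match, >= 2")
        if np.any(np.diff(alphas) <= 0):
            raise ConfigError("alpha grid must be strictly ascending")
        if np.any(np.diff(mst) > 0):
            raise ConfigError("mean_signal_type must be non-increasing")
        object.__setattr__(self, "alphas", alphas)
        object.__setattr__(self, "mean_signal_type", mst)

    @property
    def achievable_range(self) -> tuple[float, float]:
        """(min, max) signal-type values the table can resolve."""
        return float(self.mean_signal_type[-1]), float(self.mean_signal_type[0])

    def save(self, path) -> None:
        """Write as delimited text: header comments carry the metadata;
        floats use repr precision so a reload is bit-identical."""
        with open(path, "w") as fh:
            fh.write(f"# n_samples={self.n_samples}\n")
            fh.write(f"# reps={self.reps}\n")
            fh.write(f"# seed={self.seed}\n")
            fh.write("alpha,mean_signal_type\n")
            for a, t in zip(self.alphas, self.mean_signal_type):
                fh.write(f"{float(a)!r},{float(t)!r}\n")

    @classmethod
    def load(cls, path) -> "MappingTable":
        meta = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    key, _, val = line.lstrip("# ").partition("=")
                    meta[key.strip()] = int(val)
                elif line and not line.startswith("alpha"):
                    a, _, t = line.partition(",")
                    rows.append((float(a), float(t)))
        arr = np.array(rows)
        return cls(
            n_samples=meta["n_samples"],
            alphas=arr[:, 0],
            mean_signal_type=arr[:, 1],
            reps=meta["reps"],
            seed=meta["seed"],
        )


def build_mapping(
    n_samples: int,
    alpha_grid=None,
    reps: Optional[int] = None,
    seed: int = 0,
) -> MappingTable:
    """Build the alpha -> signal type table by Monte-Carlo simulation.

    For each alpha, ``reps`` isotropic 2-D Gaussian realizations of
    length ``n_samples`` are spectrally shaped and their signal-type
    value measured; the mean per grid point is isotonically smoothed
    (non-increasing) to remove Monte-Carlo inversions.  ``reps`` defaults
    to 500, raised to 800 for windows shorter than 25 samples where the
    per-realization variance is larger.  Degenerate realizations (zero
    STD) are discarded; more than 10% discarded at a grid point is an
    error.
    """
    if alpha_grid is None:
        alpha_grid = DEFAULT_ALPHA_GRID
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if reps is None:
        reps = 800 if n_samples < 25 else 500
    if reps < 50:
        raise ConfigError("reps must be at least 50")
    rng = np.random.default_rng(seed)
    means = np.empty(alpha_grid.size)
    for i, alpha in enumerate(alpha_grid):
        white = rng.standard_normal((2, reps, n_samples))
        shaped = shape_spectrum(white, alpha)
        shaped = shaped - shaped.mean(axis=-1, keepdims=True)
        dx, dy = np.diff(shaped[0], axis=-1), np.diff(shaped[1], axis=-1)
        rms = np.sqrt(np.mean(dx**2 + dy**2, axis=-1))
        std = np.sqrt(np.var(shaped[0], axis=-1) + np.var(shaped[1], axis=-1))
        ok = std > 0.0
        if ok.sum() < 0.9 * reps:
            raise DegenerateSegmentError(
                f"more than 10% degenerate realizations at alpha={alpha}"
            )
        means[i] = np.mean(rms[ok] / std[ok])
    iso = IsotonicRegression(increasing=False)
    means = iso.fit_transform(alpha_grid, means)
    return MappingTable(
        n_samples=n_samples,
        alphas=alpha_grid,
        mean_signal_type=means,
        reps=reps,
        seed=seed,
    )


def lookup_alpha(target_signal_type: float, table: MappingTable) -> float:
    """Invert the table: the alpha whose expected signal type equals the
    target, by linear interpolation between grid points.

    Raises :class:`MappingRangeError` (naming the achievable interval)
    when the target falls outside the table's range for its window
    length.
    """
    lo, hi = table.achievable_range
    if not (lo < target_signal_type < hi):
        raise MappingRangeError(
            f"signal type {target_signal_type} outside achievable range "
            f"({lo:.4f}, {hi:.4f}) for n={table.n_samples}"
        )
    # table is non-increasing in alpha; reverse for ascending interp
    return float(
        np.interp(
            target_signal_type,
            table.mean_signal_type[::-1],
            table.alphas[::-1],
        )
    )


def cached_mapping(
    n_samples: int,
    cache_dir,
    alpha_grid=None,
    reps: Optional[int] = None,
    seed: int = 0,
) -> MappingTable:
    """Build (or reload from ``cache_dir``) a mapping table.

    The cache key hashes (n_samples, grid, reps, seed), so a cached table
    is only reused for an identical build request.
    """
    if alpha_grid is None:
        alpha_grid = DEFAULT_ALPHA_GRID
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if reps is None:
        reps = 800 if n_samples < 25 else 500
    buf = io.BytesIO()
    np.save(buf, alpha_grid)
    key = hashlib.sha256(
        f"{n_samples}|{reps}|{seed}|".encode() + buf.getvalue()
    ).hexdigest()[:16]
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    path = cache_dir / f"mapping_n{n_samples}_{key}.csv"
    if path.exists():
        return MappingTable.load(path)
    table = build_mapping(n_samples, alpha_grid=alpha_grid, reps=reps, seed=seed)
    table.save(path)
    return table
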