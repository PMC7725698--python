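"""Reading gaze recordings, extracting fixed-duration windows, writers.

Input is delimited text with a timestamp column (seconds), horizontal
and vertical gaze columns (degrees).  Column names, delimiter and the
nominal sampling frequency are configurable; when the stated frequency
disagrees with the median timestamp spacing by more than 10%, the
spacing-derived frequency wins (with a logged warning).  Rows with
missing gaze values are kept in the :class:`Recording` as NaN and
flagged; windows overlapping them are dropped during extraction, since
the measures require gap-free segments.

No vendor-specific formats and no pixel-to-degree conversion: data are
assumed to arrive in degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, ParseError
from .measures import GazeSegment

__all__ = ["Recording", "read_gaze", "extract_windows", "write_segment"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Recording:
    """A gaze recording before windowing: strictly increasing timestamps
    (seconds), gaze positions (degrees, NaN marks missing samples), the
    nominal sampling frequency and a free-text eye label."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fs: float
    eye_label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (t.size == x.size == y.size) or t.ndim != 1:
            raise ParseError("t, x, y must be 1-D and equal length")
        if t.size < 2:
            raise ParseError("recording needs at least 2 samples")
        if np.any(np.diff(t) <= 0):
            raise ParseError("timestamps must be strictly increasing")
        if self.fs <= 0:
            raise ConfigError("sampling frequency must be positive")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n_missing(self) -> int:
        """Samples with a missing x or y value."""
        return int(np.sum(np.isnan(self.x) | np.isnan(self.y)))


def read_gaze(
    path,
    time_col: str = "t",
    x_col: str = "x",
    y_col: str = "y",
    fs: Optional[float] = None,
    sep: Optional[str] = None,
    eye_label: str = "",
) -> Recording:
    """Read a delimited-text gaze recording.

    ``sep=None`` sniffs the delimiter.  ``fs`` may be omitted, in which
    case it is derived as 1/median timestamp spacing; if supplied but
    inconsistent with the spacing by more than 10%, the derived value is
    used and a warning logged.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    for col in (time_col, x_col, y_col):
        if col not in df.columns:
            raise ConfigError(
                f"column {col!r} not found; file has {list(df.columns)}"
            )
    t = df[time_col].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)):
        raise ParseError("timestamps contain missing or non-finite values")
    if np.any(np.diff(t) <= 0):
        raise ParseError("timestamps are not strictly increasing")
    derived_fs = 1.0 / float(np.median(np.diff(t)))
    if fs is None:
        fs = derived_fs
    elif abs(fs - derived_fs) > 0.1 * fs:
        log.warning(
            "stated fs=%.6g Hz inconsistent with median spacing (%.6g Hz); "
            "using the spacing-derived value",
            fs,
            derived_fs,
        )
        fs = derived_fs
    x = df[x_col].to_numpy(dtype=float)
    y = df[y_col].to_numpy(dtype=float)
    n_missing = int(np.sum(np.isnan(x) | np.isnan(y)))
    if n_missing:
        log.info("%d samples with missing gaze flagged in %s", n_missing, path)
    return Recording(t=t, x=x, y=y, fs=float(fs), eye_label=eye_label)


def extract_windows(
    rec: Recording, duration: float = 0.2, stride: Optional[float] = None
) -> List[GazeSegment]:
    """Cut half-open windows [t0, t0+duration) at a fixed stride.

    ``stride`` defaults to ``duration`` (non-overlapping tiling).
    Windows containing missing samples, or fewer than 2 samples, are
    dropped (count logged).  The empirical result may be empty.
    """
    if stride is None:
        stride = duration
    if duration * rec.fs < 2:
        raise ConfigError("window duration must cover at least 2 samples")
    if stride <= 0:
        raise ConfigError("stride must be positive")
    dt = 1.0 / rec.fs
    t0, t_end = rec.t[0], rec.t[-1] + dt
    eps = 1e-9 * max(1.0, abs(t_end))
    segments: List[GazeSegment] = []
    n_dropped = 0
    start = t0
    while start + duration <= t_end + eps:
        mask = (rec.t >= start - eps) & (rec.t < start + duration - eps)
        xs, ys = rec.x[mask], rec.y[mask]
        if xs.size >= 2 and np.all(np.isfinite(xs)) and np.all(np.isfinite(ys)):
            segments.append(GazeSegment(x=xs, y=ys, fs=rec.fs))
        else:
            n_dropped += 1
        start += stride
    if n_dropped:
        log.info("dropped %d windows (missing samples or too short)", n_dropped)
    return segments


def write_segment(seg: GazeSegment, path, sep: str = ",") -> None:
    """Write a segment as delimited text (t, x, y) readable by
    :func:`read_gaze`; timestamps start at 0 and step 1/fs."""
    t = np.arange(len(seg)) / seg.fs
    pd.DataFrame({"t": t, "x": seg.x, "y": seg.y}).to_csv(
        path, sep=sep, index=False, float_format="%.10g"
    )
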