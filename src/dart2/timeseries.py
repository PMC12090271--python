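"""Downsampling and steady-state window averaging of CoM traces.

Frames are captured at 1 frame/s but the statistic is conventionally
analyzed at 1 frame/10 s; :func:`downsample` performs that decimation.
The summary statistic of an assay is the *average CoM*: the arithmetic
mean of the per-frame CoM over an odor-specific steady-state window
(e.g. 20-60 min for benzaldehyde, 5-25 min for propionic acid), chosen
because each odor reaches its maximal, approximately steady response on
its own schedule.  The shipped window table can be overridden by the
user for odors it does not list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
import yaml

#: Aliases mapping common shorthand to canonical odor names.
_ODOR_ALIASES = {
    "ba": "benzaldehyde",
    "pa": "propionic acid",
    "propionic_acid": "propionic acid",
    "iva": "isovaleric acid",
    "isovaleric_acid": "isovaleric acid",
    "lg": "lemongrass",
    "r-lim": "r-limonene",
    "r_limonene": "r-limonene",
    "limonene": "r-limonene",
    "allyl isothiocyanate": "aitc",
    "citr": "citronellal",
}


@dataclass(frozen=True)
class CoMSeries:
    """Time-stamped normalized CoM trace for one tube.

    ``values`` may contain NaN for frames where no pixel crossed the
    threshold; those samples are excluded from window averages and never
    imputed.  ``cadence_s`` is the sampling interval in seconds.
    """

    times: np.ndarray
    values: np.ndarray
    cadence_s: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=np.float64)
        v = np.asarray(self.values, dtype=np.float64)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError("times and values must be 1-D and equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("CoM values must lie in [0, 1] (or be missing)")
        if self.cadence_s <= 0 or not math.isfinite(self.cadence_s):
            raise ValueError("cadence_s must be positive and finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.times.size)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, value_col: str = "com") -> "CoMSeries":
        """Build a series from a per-frame tracking table (time_s column)."""
        t = df["time_s"].to_numpy(dtype=np.float64)
        if t.size >= 2:
            cadence = float(t[1] - t[0])
        else:
            cadence = 1.0
        return cls(times=t, values=df[value_col].to_numpy(dtype=np.float64), cadence_s=cadence)

    def mirrored(self) -> "CoMSeries":
        """The trace as seen from the opposite tube end (values -> 1 - values)."""
        return replace(self, values=1.0 - self.values)


@dataclass(frozen=True)
class OdorWindow:
    """Steady-state averaging window for one odor, in minutes."""

    odor: str
    start_min: float
    end_min: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_min < self.end_min <= 60):
            raise ValueError(
                f"need 0 <= start < end <= 60 min, got [{self.start_min}, {self.end_min}]"
            )


def downsample(series: CoMSeries, interval_s: float) -> CoMSeries:
    """Keep every (interval_s / cadence)-th sample, starting at the first.

    ``interval_s`` must be a positive integer multiple of the input
    cadence; the output cadence is updated accordingly.
    """
    if interval_s <= 0:
        raise ValueError("interval_s must be positive")
    ratio = interval_s / series.cadence_s
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-9:
        raise ValueError(
            f"interval {interval_s}s is not a positive multiple of the cadence {series.cadence_s}s"
        )
    idx = np.arange(0, len(series), k)
    return CoMSeries(times=series.times[idx], values=series.values[idx], cadence_s=series.cadence_s * k)


def window_average(series: CoMSeries, window: OdorWindow) -> float:
    """Arithmetic mean of non-missing samples with start <= t <= end.

    Window endpoints are inclusive on both sides.  Returns NaN when the
    window holds no non-missing sample (flagged as a missing value).
    """
    lo, hi = window.start_min * 60.0, window.end_min * 60.0
    sel = (series.times >= lo) & (series.times <= hi)
    vals = series.values[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return math.nan
    return float(vals.mean())


def _load_window_table() -> dict:
    with resources.files("dart2.data").joinpath("odor_windows.yaml").open("r") as fh:
        return yaml.safe_load(fh)


def canonical_odor_name(odor: str) -> str:
    key = odor.strip().lower()
    return _ODOR_ALIASES.get(key, key)


def default_window(odor: str, override: Optional[OdorWindow] = None) -> OdorWindow:
    """Steady-state window for a known odor, or an explicit override.

    Unknown odors are rejected unless ``override`` is supplied, because
    the window is part of each odor's assay definition, not a derived
    quantity.
    """
    if override is not None:
        return override
    table = _load_window_table()
    name = canonical_odor_name(odor)
    if name not in table:
        raise KeyError(
            f"no default steady-state window for odor {odor!r}; supply an explicit OdorWindow"
        )
    start, end = table[name]
    return OdorWindow(odor=name, start_min=float(start), end_min=float(end))
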