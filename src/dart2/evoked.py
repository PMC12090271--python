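"""Peak-minus-baseline quantification of stimulus-evoked traces.

Three recording modalities share the same summary rule — the amplitude
of the peak response minus the mean baseline over a window preceding
the stimulus:

* **EAG** (electroantennogram): odor-puff evoked antennal field
  potential; baseline is the 5 s before the puff, the response is the
  largest deflection in the 10 s after it, reported as a positive
  magnitude (the raw deflection is downward).  Recordings whose
  amplitude stays below 0.05 mV are excluded as non-responders.
* **DCFDA fluorescence**: a reactive-oxygen-species dye read out every
  3 s after a UV flash; the response is the *steady-state peak* — the
  maximum of a short moving average of the post-stimulus record — minus
  the 30 s baseline mean, reported both raw (dF) and normalized to the
  baseline (dF/F0).
* **Patch clamp**: agonist-evoked whole-cell current; peak magnitude in
  the application epoch minus the 5 s baseline mean.

The peak-minus-baseline amplitude is invariant to adding a constant
offset to a trace and scales linearly with the trace; dF/F0 is *not*
offset-invariant, which is why both are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

Modality = Literal["eag", "dcfda", "patch"]

#: Default response-window length (s after stimulus) per modality; the
#: patch default of None means "the full record after the stimulus".
DEFAULT_RESPONSE_WINDOW_S: dict[str, Optional[float]] = {
    "eag": 10.0,
    "dcfda": 120.0,
    "patch": None,
}

#: EAG recordings with peak amplitude below this (mV) are excluded as
#: non-responders.
EAG_EXCLUSION_MV = 0.05


@dataclass(frozen=True)
class Trace:
    """One evoked-response recording."""

    times: np.ndarray
    signal: np.ndarray
    stim_time: float
    modality: Modality
    units: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=np.float64)
        s = np.asarray(self.signal, dtype=np.float64)
        if t.ndim != 1 or s.ndim != 1 or t.size != s.size:
            raise ValueError("times and signal must be 1-D and equal length")
        if t.size < 2:
            raise ValueError("trace must hold at least 2 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not (t[0] <= self.stim_time <= t[-1]):
            raise ValueError("stim_time must lie within the record")
        if self.modality not in ("eag", "dcfda", "patch"):
            raise ValueError(f"unknown modality {self.modality!r}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", s)


@dataclass(frozen=True)
class PeakResponse:
    """Peak-minus-baseline summary of one trace.

    ``amplitude`` is in the trace's signal units; for EAG and patch it
    is the peak *magnitude* of the deflection from baseline (reported
    positive by convention).  Excluded responses carry a machine-readable
    ``reason``.  ``dff0`` is populated for DCFDA traces only.
    """

    amplitude: float
    baseline_mean: float
    modality: Modality
    excluded: bool = False
    reason: Optional[str] = None
    dff0: Optional[float] = None

    def __post_init__(self) -> None:
        if self.excluded and not self.reason:
            raise ValueError("excluded responses must carry a reason")


def _baseline_mean(trace: Trace, baseline_s: float) -> float:
    lo = trace.stim_time - baseline_s
    if lo < trace.times[0] - 1e-9:
        raise ValueError(
            f"baseline window [{lo:.3f}, {trace.stim_time:.3f}) starts before the record"
        )
    sel = (trace.times >= lo) & (trace.times < trace.stim_time)
    if not sel.any():
        raise ValueError("baseline window holds no samples")
    return float(trace.signal[sel].mean())


def quantify_peak(
    trace: Trace,
    baseline_s: float = 5.0,
    response_window_s: Optional[float] = None,
    exclusion_threshold: Optional[float] = None,
) -> PeakResponse:
    """Peak response amplitude minus the pre-stimulus baseline mean.

    The baseline is the mean signal over ``baseline_s`` seconds before
    the stimulus; the amplitude is the largest absolute deflection from
    that baseline within the response window (per-modality default, see
    :data:`DEFAULT_RESPONSE_WINDOW_S`), reported as a positive
    magnitude.  EAG responses below the exclusion threshold
    (default 0.05 mV) are flagged excluded rather than dropped.
    """
    if baseline_s <= 0:
        raise ValueError("baseline_s must be positive")
    baseline = _baseline_mean(trace, baseline_s)
    if response_window_s is None:
        response_window_s = DEFAULT_RESPONSE_WINDOW_S[trace.modality]
    sel = trace.times > trace.stim_time
    if response_window_s is not None:
        sel &= trace.times <= trace.stim_time + response_window_s
    if not sel.any():
        raise ValueError("no samples in the response window")
    dev = trace.signal[sel] - baseline
    amplitude = float(np.max(np.abs(dev)))
    if exclusion_threshold is None and trace.modality == "eag":
        exclusion_threshold = EAG_EXCLUSION_MV
    excluded = False
    reason = None
    if exclusion_threshold is not None and amplitude < exclusion_threshold:
        excluded = True
        reason = f"no_response_below_{exclusion_threshold:g}{trace.units or ''}"
    return PeakResponse(
        amplitude=amplitude,
        baseline_mean=baseline,
        modality=trace.modality,
        excluded=excluded,
        reason=reason,
    )


def percent_of_control(test: PeakResponse, control: PeakResponse) -> float:
    """Test amplitude as a percentage of the control amplitude."""
    if control.excluded:
        raise ValueError(f"control response is excluded ({control.reason})")
    if test.excluded:
        raise ValueError(f"test response is excluded ({test.reason})")
    if control.amplitude == 0 or not math.isfinite(control.amplitude):
        raise ValueError("control amplitude is zero or non-finite; percentage undefined")
    return float(100.0 * test.amplitude / control.amplitude)


def dcfda_response(
    trace: Trace,
    baseline_s: float = 30.0,
    post_s: float = 120.0,
    smooth_window_samples: int = 3,
) -> PeakResponse:
    """Steady-state fluorescence response to a UV flash.

    The baseline is the mean fluorescence over ``baseline_s`` before the
    stimulus.  The *steady-state peak* of the post-stimulus record is
    the maximum of a ``smooth_window_samples``-point moving average
    (3 samples = 9 s at the 3 s acquisition cadence), honoring both
    "steady state" and "peak".  Reports dF = peak - baseline (negative
    values permitted) and dF/F0 = dF / baseline.
    """
    if trace.modality != "dcfda":
        raise ValueError(f"dcfda_response requires a dcfda trace, got {trace.modality!r}")
    if smooth_window_samples < 1:
        raise ValueError("smooth_window_samples must be >= 1")
    baseline = _baseline_mean(trace, baseline_s)
    sel = (trace.times > trace.stim_time) & (trace.times <= trace.stim_time + post_s)
    post = trace.signal[sel]
    if post.size == 0:
        raise ValueError("no post-stimulus samples recorded")
    w = min(smooth_window_samples, post.size)
    smoothed = np.convolve(post, np.ones(w) / w, mode="valid")
    peak = float(smoothed.max())
    df = peak - baseline
    dff0 = df / baseline if baseline != 0 else math.nan
    return PeakResponse(
        amplitude=float(df),
        baseline_mean=baseline,
        modality="dcfda",
        excluded=False,
        reason=None,
        dff0=float(dff0),
    )
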