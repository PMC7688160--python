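"""Aortic-valve Doppler hemodynamics.

Velocity-envelope traces are gated into cardiac cycles at ECG R-peak
times; each cycle yields a peak systolic velocity (mm/s) and a mean
transvalvular pressure gradient (mmHg) via the simplified Bernoulli
relation dP = 4 v^2 with v in m/s. Cycle metrics average to image-level
summaries, image summaries average to mouse-level summaries, and the
mouse-level peak velocity classifies hemodynamically severe disease
against a fixed threshold (1320 mm/s, the 95th percentile of peak
velocity in an established hyperlipidemic reference model).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import median_filter

__all__ = [
    "VelocityTrace",
    "CardiacCycle",
    "HemodynamicSummary",
    "SummaryLevel",
    "GatingError",
    "segment_cycles",
    "detect_ejection_window",
    "peak_systolic_velocity",
    "mean_pressure_gradient",
    "analyze_trace",
    "summarize_mouse",
    "classify_severe",
    "SEVERITY_THRESHOLD_MM_S",
]

log = logging.getLogger(__name__)

#: Previously reported 95th-percentile peak velocity of a reference CAVD model.
SEVERITY_THRESHOLD_MM_S = 1320.0


class GatingError(ValueError):
    """Raised when R-peak gating cannot define at least one cardiac cycle."""


class EmptyWindowError(ValueError):
    """Raised when no ejection window exists (e.g. an all-zero cycle)."""


@dataclass(frozen=True)
class VelocityTrace:
    """Uniformly sampled Doppler velocity envelope with R-peak annotations.

    time: seconds, strictly increasing; velocity: mm/s, non-negative;
    r_peaks: R-wave times in seconds, strictly increasing, inside the
    time range of the trace.
    """

    time: np.ndarray
    velocity: np.ndarray
    r_peaks: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=np.float64)
        v = np.asarray(self.velocity, dtype=np.float64)
        r = np.asarray(self.r_peaks, dtype=np.float64)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("time and velocity must be 1-D arrays of equal length")
        dt = np.diff(t)
        if len(t) < 2 or np.any(dt <= 0):
            raise ValueError("time must be strictly increasing with >= 2 samples")
        if dt.max() / dt.min() >= 1.5:
            raise ValueError("sampling is not approximately uniform")
        if np.any(v < 0):
            raise ValueError("velocity must be non-negative")
        if r.size and (np.any(np.diff(r) <= 0) or r[0] < t[0] or r[-1] > t[-1]):
            raise ValueError("r_peaks must be strictly increasing and within the time range")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "velocity", v)
        object.__setattr__(self, "r_peaks", r)

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    @classmethod
    def from_csv(cls, trace_path: str | Path, rpeaks_path: str | Path) -> "VelocityTrace":
        """Read a time_s,velocity_mm_s trace CSV and a single-column R-peak CSV."""
        import pandas as pd

        df = pd.read_csv(trace_path)
        peaks = pd.read_csv(rpeaks_path)
        return cls(
            df["time_s"].to_numpy(),
            df["velocity_mm_s"].to_numpy(),
            peaks[peaks.columns[0]].to_numpy(),
        )

    def to_csv(self, trace_path: str | Path, rpeaks_path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"time_s": self.time, "velocity_mm_s": self.velocity}).to_csv(
            trace_path, index=False
        )
        pd.DataFrame({"time_s": self.r_peaks}).to_csv(rpeaks_path, index=False)


@dataclass(frozen=True)
class CardiacCycle:
    """One R-to-R cardiac cycle: the trace restricted to [start, end)."""

    start: float
    end: float
    time: np.ndarray
    velocity: np.ndarray

    def __post_init__(self) -> None:
        if self.end <= self.start or len(self.time) == 0:
            raise ValueError("cycle interval must be non-empty")


class SummaryLevel(str, Enum):
    CYCLE = "cycle"
    IMAGE = "image"
    MOUSE = "mouse"


@dataclass(frozen=True)
class HemodynamicSummary:
    peak_velocity: float  # mm/s
    mean_gradient: float  # mmHg
    n_cycles: int
    level: SummaryLevel

    def __post_init__(self) -> None:
        if self.peak_velocity < 0 or self.mean_gradient < 0:
            raise ValueError("hemodynamic metrics must be non-negative")


def segment_cycles(trace: VelocityTrace) -> list[CardiacCycle]:
    """Gate the trace into cardiac cycles at the annotated R-peaks.

    Cycles are half-open [R_i, R_{i+1}) so the partition is disjoint. If
    the trace extends at least one median R-R interval beyond the last
    R-peak, a terminal cycle of that median length is appended, so a
    recording whose R-peaks mark cycle *starts* yields one cycle per peak.
    """
    r = trace.r_peaks
    dt = 1.0 / trace.sampling_rate
    boundaries = list(r)
    if len(r) >= 2:
        rr_med = float(np.median(np.diff(r)))
        if trace.time[-1] >= r[-1] + rr_med - dt / 2:
            boundaries.append(r[-1] + rr_med)
    if len(boundaries) < 2:
        raise GatingError("need at least 2 R-peaks to define a cardiac cycle")

    cycles = []
    for start, end in zip(boundaries[:-1], boundaries[1:]):
        sel = (trace.time >= start) & (trace.time < end)
        if not sel.any():
            log.warning("discarding empty cycle [%g, %g)", start, end)
            continue
        cycles.append(CardiacCycle(start, end, trace.time[sel], trace.velocity[sel]))
    return cycles


def detect_ejection_window(cycle: CardiacCycle, threshold_frac: float = 0.1) -> tuple[int, int]:
    """Longest contiguous sample run with velocity above a fraction of the
    cycle maximum (default 10%).

    Returns (i0, i1) half-open sample indices into the cycle.
    """
    v = cycle.velocity
    if len(v) < 3:
        raise ValueError("cycle must contain at least 3 samples")
    vmax = v.max()
    if vmax <= 0:
        raise EmptyWindowError("cycle velocity is identically zero; no ejection window")
    above = v > threshold_frac * vmax
    best, cur_start, best_len = (0, 0), None, 0
    for i, flag in enumerate(np.append(above, False)):
        if flag and cur_start is None:
            cur_start = i
        elif not flag and cur_start is not None:
            if i - cur_start > best_len:
                best, best_len = (cur_start, i), i - cur_start
            cur_start = None
    return best


def _extend_window(v: np.ndarray, i0: int, i1: int) -> tuple[int, int]:
    # Walk each window edge outward while velocity keeps strictly decreasing,
    # capturing the full flow lobe below the detection threshold.
    while i0 > 0 and v[i0 - 1] < v[i0]:
        i0 -= 1
    while i1 < len(v) and v[i1] < v[i1 - 1]:
        i1 += 1
    return i0, i1


def peak_systolic_velocity(cycle: CardiacCycle, smooth_ms: float = 0.0) -> float:
    """Maximum velocity within the cycle (mm/s).

    `smooth_ms` > 0 applies a median filter of that duration first, which
    suppresses the upward bias of a raw max on noisy envelopes.
    """
    if len(cycle.velocity) == 0:
        raise ValueError("empty cycle")
    v = cycle.velocity
    if smooth_ms > 0:
        v = _smooth(v, cycle.time, smooth_ms)
    return float(v.max())


def _smooth(v: np.ndarray, t: np.ndarray, smooth_ms: float) -> np.ndarray:
    dt = float(np.median(np.diff(t)))
    size = max(1, int(round(smooth_ms * 1e-3 / dt)))
    if size % 2 == 0:
        size += 1
    return median_filter(v, size=size, mode="nearest") if size > 1 else v


def mean_pressure_gradient(
    cycle: CardiacCycle,
    window: tuple[int, int] | None = None,
    threshold_frac: float = 0.1,
) -> float:
    """Mean transvalvular pressure gradient (mmHg) over the ejection phase.

    Simplified Bernoulli: dP = 4 v^2 with v in m/s, time-averaged over the
    ejection window. When `window` is None the 10%-of-max run is detected
    and extended outward along its monotonically decreasing shoulders so
    the whole flow lobe (not just the above-threshold core) is averaged.
    """
    if window is None:
        i0, i1 = detect_ejection_window(cycle, threshold_frac)
        i0, i1 = _extend_window(cycle.velocity, i0, i1)
    else:
        i0, i1 = window
    if i1 <= i0:
        raise EmptyWindowError("empty ejection window")
    v_ms = cycle.velocity[i0:i1] / 1000.0
    return float(np.mean(4.0 * v_ms**2))


def analyze_trace(
    trace: VelocityTrace,
    smooth_ms: float = 2.0,
    threshold_frac: float = 0.1,
) -> tuple[HemodynamicSummary, list[HemodynamicSummary]]:
    """Per-cycle metrics and their unweighted image-level average.

    A short median filter (default 2 ms) is applied to the envelope before
    cycle metrics are computed; degenerate cycles (no ejection window) are
    logged and skipped.
    """
    smoothed = VelocityTrace(trace.time, _smooth(trace.velocity, trace.time, smooth_ms), trace.r_peaks)
    cycle_summaries = []
    for cyc in segment_cycles(smoothed):
        try:
            peak = peak_systolic_velocity(cyc)
            grad = mean_pressure_gradient(cyc, threshold_frac=threshold_frac)
        except (EmptyWindowError, ValueError) as exc:
            log.warning("skipping degenerate cycle at %.4f s: %s", cyc.start, exc)
            continue
        cycle_summaries.append(HemodynamicSummary(peak, grad, 1, SummaryLevel.CYCLE))
    if not cycle_summaries:
        raise ValueError("no analyzable cardiac cycle in trace")
    image = HemodynamicSummary(
        float(np.mean([c.peak_velocity for c in cycle_summaries])),
        float(np.mean([c.mean_gradient for c in cycle_summaries])),
        len(cycle_summaries),
        SummaryLevel.IMAGE,
    )
    return image, cycle_summaries


def summarize_mouse(images: Sequence[HemodynamicSummary]) -> HemodynamicSummary:
    """Unweighted mean of image-level summaries (typically 3 images/mouse)."""
    if not images:
        raise ValueError("need at least one image-level summary")
    if any(s.level is not SummaryLevel.IMAGE for s in images):
        raise ValueError("summarize_mouse expects image-level summaries")
    return HemodynamicSummary(
        float(np.mean([s.peak_velocity for s in images])),
        float(np.mean([s.mean_gradient for s in images])),
        int(sum(s.n_cycles for s in images)),
        SummaryLevel.MOUSE,
    )


def classify_severe(
    summary: HemodynamicSummary, threshold: float = SEVERITY_THRESHOLD_MM_S
) -> bool:
    """Hemodynamically severe disease: mouse peak velocity strictly above
    the threshold (ties are not severe)."""
    if summary.level is not SummaryLevel.MOUSE:
        raise ValueError("severity is classified on mouse-level summaries")
    return summary.peak_velocity > threshold
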