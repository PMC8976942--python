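"""Smoothing and respiration-phase segmentation of nostril temperature traces.

A breathing cycle at the nostril reads as: a temperature descent while
cool ambient air is inhaled (inspiration), a rise while warm humid air is
exhaled (expiration), and a near-flat plateau while lung volume is held
(expiratory pause).  The trace is low-pass filtered (second-order
Butterworth, zero-phase) and segmented by locating local temperature
minima — maximum-inspiration points — then walking outward along the
curve until the local slope becomes negligible, which marks the
boundaries of the expiratory pause.  Three transition points (end of
pause, maximum inspiration, start of pause) delimit one cycle; each phase
is quantified by duration (s), amplitude (|deltaT| in degC) and slope
(amplitude/duration, degC/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .qc import TemperatureTrace

__all__ = [
    "TransitionPoints",
    "RespirationPhase",
    "RespirationCycle",
    "smooth_trace",
    "detect_transition_points",
    "build_cycles",
    "phase_metrics",
    "residual_trace",
    "mean_cycle",
    "segment_trace",
    "breathing_rate",
    "interpolated_median",
    "cycles_to_frame",
]

DEFAULT_FILTER_ORDER = 2
DEFAULT_CRITICAL_FREQUENCY = 1.0 / 5.0  # normalized cutoff in Nyquist units
DEFAULT_MIN_PROMINENCE_C = 0.1
DEFAULT_MIN_CYCLE_SPACING_S = 0.5
DEFAULT_SLOPE_WINDOW_FRAMES = 5
DEFAULT_SLOPE_EPSILON_FRACTION = 0.1

PHASE_ORDER = ("inspiration", "expiration", "expiratory_pause")


@dataclass(frozen=True)
class TransitionPoints:
    """The three transition frames delimiting one respiration cycle.

    ``pause_end_frame`` — end of the preceding expiratory pause, i.e. the
    start of active inspiration; ``max_inspiration_frame`` — the local
    temperature minimum; ``pause_start_frame`` — end of expiration / start
    of the expiratory pause.
    """

    pause_end_frame: int
    max_inspiration_frame: int
    pause_start_frame: int

    def __post_init__(self) -> None:
        if not (self.pause_end_frame < self.max_inspiration_frame < self.pause_start_frame):
            raise ValueError(
                "transition points must satisfy pause_end < max_inspiration "
                f"< pause_start, got {self}"
            )


@dataclass
class RespirationPhase:
    """One phase interval [start_frame, end_frame) with its metrics."""

    kind: str                 # inspiration | expiration | expiratory_pause
    start_frame: int
    end_frame: int
    duration_s: float
    amplitude_C: float
    slope: float              # degC/s, amplitude / duration
    complete: bool = True


@dataclass
class RespirationCycle:
    """An ordered (inspiration, expiration, expiratory_pause) triple."""

    cycle_id: int
    phases: list[RespirationPhase]
    complete: bool = True
    cycle_type: str | None = None  # Call | Pre-call | Post-call | Quiet

    @property
    def start_frame(self) -> int:
        return self.phases[0].start_frame

    @property
    def end_frame(self) -> int:
        return self.phases[-1].end_frame

    @property
    def duration_s(self) -> float:
        return sum(p.duration_s for p in self.phases)


def smooth_trace(
    trace: TemperatureTrace,
    order: int = DEFAULT_FILTER_ORDER,
    critical_frequency: float = DEFAULT_CRITICAL_FREQUENCY,
    cutoff_Hz: float | None = None,
) -> TemperatureTrace:
    """Zero-phase low-pass Butterworth smoothing of the temperature trace.

    ``critical_frequency`` is the normalized cutoff in Nyquist units
    (0.2 = 3 Hz at 30 fps); pass ``cutoff_Hz`` to specify it in hertz
    instead.  Forward-backward filtering keeps transition timing unlagged.
    """
    wn = critical_frequency if cutoff_Hz is None else cutoff_Hz / (trace.fps / 2.0)
    if not (0.0 < wn < 1.0):
        raise ValueError(f"normalized cutoff must be in (0, 1), got {wn}")
    b, a = sps.butter(order, wn, btype="low")
    padlen = 3 * (max(len(a), len(b)) - 1)
    if len(trace) <= padlen:
        raise ValueError(
            f"trace of {len(trace)} frames is too short for the filter "
            f"warm-up ({padlen} frames)"
        )
    smoothed = sps.filtfilt(b, a, trace.temperature_C)
    return TemperatureTrace(
        segment_id=trace.segment_id,
        individual_id=trace.individual_id,
        fps=trace.fps,
        frames=trace.frames.copy(),
        temperature_C=smoothed,
        interpolated_mask=trace.interpolated_mask.copy(),
    )


def local_slope(values: np.ndarray, fps: float,
                window_frames: int = DEFAULT_SLOPE_WINDOW_FRAMES) -> np.ndarray:
    """Per-frame local slope (degC/s) by centred least-squares fit.

    Equivalent to a first-order Savitzky-Golay derivative over a window of
    ``window_frames`` frames; edges use shrunken one-sided windows.
    """
    n = len(values)
    half = window_frames // 2
    slopes = np.empty(n)
    # centred least-squares slope of y on t over the window
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        t = np.arange(lo, hi, dtype=float)
        y = values[lo:hi]
        tc = t - t.mean()
        denom = np.sum(tc * tc)
        slopes[i] = np.sum(tc * (y - y.mean())) / denom if denom > 0 else 0.0
    return slopes * fps


def _default_slope_epsilon(values: np.ndarray, slopes: np.ndarray,
                           minima: np.ndarray) -> float:
    """Threshold below which the local slope counts as 'infinitesimal'.

    Taken as a fraction of the median (over cycles) peak slope of the
    rising expiration limb following each detected minimum, so the plateau
    criterion scales with how briskly this animal breathes.  Using the
    limb's characteristic peak slope rather than a whole-trace average
    keeps the threshold well above any residual drift of the expiratory
    pause, which is what separates plateau from limb.
    """
    peaks = []
    for m in minima:
        j = m
        while j + 1 < len(values) and values[j + 1] > values[j]:
            j += 1
        if j > m:
            peaks.append(np.max(np.abs(slopes[m:j + 1])))
    if not peaks:
        return DEFAULT_SLOPE_EPSILON_FRACTION * float(np.median(np.abs(slopes)) + 1e-12)
    return DEFAULT_SLOPE_EPSILON_FRACTION * float(np.median(peaks))


def _kink_fit(raw: np.ndarray, cand: int, halfwin: int,
              max_shift: float, step: float = 0.125) -> float:
    """Sub-frame curvature-changepoint position near ``cand``.

    Fits v(t) = L + a (t-b)^2_- + c (t-b)^2_+ over a window around the
    candidate, scanning the breakpoint b on a fine grid.  Phase boundaries
    are curvature changepoints (both limbs and plateaus start and end with
    near-zero slope), and on the unsmoothed trace the changepoint is not
    spread out by the zero-phase filter, so this pins the boundary that
    the slope walk can only localise to within a couple of frames.
    """
    n = len(raw)
    lo, hi = max(cand - halfwin, 0), min(cand + halfwin + 1, n)
    t = np.arange(lo, hi, dtype=float)
    y = raw[lo:hi]
    if len(t) < 7:
        return float(cand)
    best, best_sse = float(cand), np.inf
    for beta in np.arange(cand - max_shift, cand + max_shift + 1e-9, step):
        X = np.column_stack([
            np.ones_like(t),
            np.minimum(t - beta, 0.0) ** 2,
            np.maximum(t - beta, 0.0) ** 2,
        ])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(np.sum((y - X @ coef) ** 2))
        if sse < best_sse:
            best_sse, best = sse, beta
    return best


def _refine_boundary(raw: np.ndarray, cand: int, lo: int, hi: int) -> int:
    """Two-pass changepoint refinement of a walk-located boundary,
    clipped to the open interval (lo, hi)."""
    b1 = int(round(_kink_fit(raw, cand, halfwin=6, max_shift=5.0)))
    b2 = int(round(_kink_fit(raw, b1, halfwin=4, max_shift=2.5)))
    return int(np.clip(b2, lo + 1, hi - 1))


def detect_transition_points(
    smoothed: TemperatureTrace,
    min_prominence_C: float = DEFAULT_MIN_PROMINENCE_C,
    min_cycle_spacing_s: float = DEFAULT_MIN_CYCLE_SPACING_S,
    slope_epsilon_C_per_s: float | None = None,
    slope_window_frames: int = DEFAULT_SLOPE_WINDOW_FRAMES,
    raw_values: np.ndarray | None = None,
) -> list[TransitionPoints]:
    """Locate the transition-point triple of every detectable cycle.

    Local minima of the smoothed trace (prominence >= ``min_prominence_C``,
    spacing >= ``min_cycle_spacing_s``) mark maximum inspiration.  From
    each minimum the curve is walked backward, across the descending
    inspiration limb, to the first frame where the local slope magnitude
    drops below ``slope_epsilon_C_per_s`` — the end of the preceding
    pause — and forward across the rising expiration limb to the first
    sub-threshold frame — the start of the pause.  When ``raw_values``
    (the unsmoothed trace) is supplied, each walked boundary is refined by
    a local curvature-changepoint fit on it, undoing the boundary
    spreading introduced by the zero-phase filter.  Indices are positions
    within the trace (add ``trace.frames[0]`` for absolute frame numbers).
    Returns an empty list when no qualifying minima exist.
    """
    values = smoothed.temperature_C
    fps = smoothed.fps
    distance = max(1, int(round(min_cycle_spacing_s * fps)))
    minima, _ = sps.find_peaks(-values, prominence=min_prominence_C, distance=distance)
    if minima.size == 0:
        return []
    slopes = local_slope(values, fps, slope_window_frames)
    eps = (slope_epsilon_C_per_s if slope_epsilon_C_per_s is not None
           else _default_slope_epsilon(values, slopes, minima))

    transitions: list[TransitionPoints] = []
    for k, m in enumerate(minima):
        lo = int(minima[k - 1]) if k > 0 else -1
        hi = int(minima[k + 1]) if k + 1 < len(minima) else len(values)
        start = _walk_to_plateau(values, slopes, m, -1, eps, fps, lo)
        stop = _walk_to_plateau(values, slopes, m, +1, eps, fps, hi)
        # fallback when the plateau never registers (a pause whose drift
        # stays above threshold): the temperature maximum between minima
        # is the best single estimate of the turning region
        if start is None:
            if k == 0:
                continue  # inspiration truncated by the segment edge
            start = lo + 1 + int(np.argmax(values[lo + 1:m]))
        if stop is None:
            if k + 1 == len(minima):
                continue  # expiration truncated by the segment edge
            stop = int(m) + 1 + int(np.argmax(values[m + 1:hi]))
        if raw_values is not None:
            start = _refine_boundary(raw_values, start, lo, int(m))
            stop = _refine_boundary(raw_values, stop, int(m), hi)
        transitions.append(TransitionPoints(
            pause_end_frame=start, max_inspiration_frame=int(m),
            pause_start_frame=stop,
        ))
    return _reconcile(transitions, raw_values)


def _joint_pause_fit(raw: np.ndarray, m1: int, m2: int,
                     cand1: int, cand2: int) -> tuple[int, int] | None:
    """Jointly locate both pause boundaries between two temperature minima.

    Fits the C1 model  v(t) = c0 + c1 t + a (t-b1)^2_- + c (t-b2)^2_+
    (expiration tail | linearly drifting plateau | inspiration onset),
    scanning (b1, b2) on the frame grid near the collapse point.  Used to
    recover pauses whose drift never falls below the slope threshold, so
    the outward walks collapse onto a single point.  The scan is kept
    local — b2 near the collapsed candidates (an upward-drifting pause
    ends at the local temperature maximum) and b1 within a plausible
    pause length before it — because the quadratic tails only represent
    the concave ends of the limbs, not their full S shape.
    """
    c_lo, c_hi = min(cand1, cand2), max(cand1, cand2)
    b2_lo = max(m1 + 3, c_lo - 4)
    b2_hi = min(m2 - 2, c_hi + 5)
    b1_lo = max(m1 + 2, c_lo - 18)
    if b2_hi <= b2_lo or b1_lo >= b2_hi:
        return None
    w_lo, w_hi = max(m1 + 1, b1_lo - 5), min(m2, b2_hi + 5)
    t = np.arange(w_lo, w_hi, dtype=float)
    y = raw[w_lo:w_hi]
    if len(t) < 8:
        return None
    ones = np.ones_like(t)
    best, best_sse = None, np.inf
    for b1 in range(b1_lo, b2_hi - 1):
        left = np.minimum(t - b1, 0.0) ** 2
        for b2 in range(max(b1 + 1, b2_lo), b2_hi):
            X = np.column_stack([ones, t, left, np.maximum(t - b2, 0.0) ** 2])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            sse = float(np.sum((y - X @ coef) ** 2))
            if sse < best_sse:
                best_sse = sse
                best = (b1, b2)
    return best


def _reconcile(ts: list[TransitionPoints],
               raw_values: np.ndarray | None,
               min_pause_frames: int = 4) -> list[TransitionPoints]:
    """Repair collapsed or crossing pause boundaries of consecutive cycles.

    When a pause is short or steep the forward walk of one cycle and the
    backward walk of the next can collapse onto (or cross past) each
    other.  If the raw trace is available the two boundaries are re-fit
    jointly with :func:`_joint_pause_fit`; otherwise, crossing boundaries
    are replaced by their midpoint, yielding a degenerate pause while
    keeping the phase sequence contiguous.
    """
    out = list(ts)
    for i in range(len(out) - 1):
        a, b = out[i], out[i + 1]
        gap = b.pause_end_frame - a.pause_start_frame
        if gap >= min_pause_frames:
            continue
        fitted = None
        if raw_values is not None:
            fitted = _joint_pause_fit(raw_values, a.max_inspiration_frame,
                                      b.max_inspiration_frame,
                                      a.pause_start_frame, b.pause_end_frame)
        if fitted is not None:
            b1, b2 = fitted
            # polish each boundary with the local changepoint fit
            b1 = int(np.clip(round(_kink_fit(raw_values, b1, 4, 2.0)),
                             a.max_inspiration_frame + 1, b2))
            b2 = int(np.clip(round(_kink_fit(raw_values, b2, 4, 2.0)),
                             b1, b.max_inspiration_frame - 1))
        elif gap < 0:
            mid = int(np.clip((a.pause_start_frame + b.pause_end_frame) // 2,
                              a.max_inspiration_frame + 1,
                              b.max_inspiration_frame - 1))
            b1 = b2 = mid
        else:
            continue
        out[i] = TransitionPoints(a.pause_end_frame,
                                  a.max_inspiration_frame, b1)
        out[i + 1] = TransitionPoints(b2, b.max_inspiration_frame,
                                      b.pause_start_frame)
    return out


def _walk_to_plateau(values: np.ndarray, slopes: np.ndarray, start: int,
                     step: int, eps: float, fps: float,
                     bound: int) -> int | None:
    """First frame beyond the active limb where the slope becomes negligible.

    Walks from ``start`` in direction ``step``, first leaving the
    near-zero-slope neighbourhood of the extremum, then continuing while
    the windowed slope stays steep; stops before crossing ``bound`` (the
    neighbouring temperature minimum, or the segment edge) and returns
    None if the limb never plateaus inside that range.  Because the
    windowed slope mixes a few limb frames into the plateau side, the
    stopping frame is finally refined back toward the extremum while the
    single frame-to-frame step remains flat, pinning the boundary to
    where the curve actually turns.
    """
    def in_range(idx: int) -> bool:
        return 0 <= idx < len(slopes) and idx != bound

    i = start + step
    # skip the flat neighbourhood of the minimum itself
    while in_range(i) and abs(slopes[i]) < eps:
        i += step
    if not in_range(i):
        return None
    # traverse the steep limb
    while in_range(i) and abs(slopes[i]) >= eps:
        i += step
    if not in_range(i):
        return None
    # refine: pull the boundary back while adjacent-frame steps are flat
    while (i - step) != start:
        j = i - step
        one_step = abs(values[i] - values[j]) * fps
        if one_step >= eps:
            break
        i = j
    return int(i)


def build_cycles(
    transitions: Sequence[TransitionPoints],
    smoothed: TemperatureTrace,
    metric_values: np.ndarray | None = None,
) -> list[RespirationCycle]:
    """Assemble phase triples into cycles between consecutive transitions.

    Cycle *i* comprises inspiration [pause_end_i, max_insp_i), expiration
    [max_insp_i, pause_start_i) and expiratory pause
    [pause_start_i, pause_end_{i+1}).  The final transition triple lacks a
    bounding successor, so its pause cannot be closed: its inspiration and
    expiration are emitted as an incomplete trailing cycle.  This edge
    effect is why per-phase sample counts differ in practice.
    """
    ts = sorted(transitions, key=lambda t: t.max_inspiration_frame)
    overlap_tol = 3  # frames: boundary collisions on very short pauses
    for a, b in zip(ts, ts[1:]):
        if a.pause_start_frame > b.pause_end_frame + overlap_tol:
            raise ValueError(
                f"overlapping transitions: pause starting at {a.pause_start_frame} "
                f"extends past next pause end {b.pause_end_frame}"
            )
    mv = smoothed.temperature_C if metric_values is None else np.asarray(metric_values)
    cycles: list[RespirationCycle] = []
    for i, t in enumerate(ts):
        next_pause_end = ts[i + 1].pause_end_frame if i + 1 < len(ts) else None
        insp = _make_phase("inspiration", t.pause_end_frame,
                           t.max_inspiration_frame, mv, smoothed.fps)
        exp = _make_phase("expiration", t.max_inspiration_frame,
                          t.pause_start_frame, mv, smoothed.fps)
        if next_pause_end is not None and next_pause_end > t.pause_start_frame:
            pause = _make_phase("expiratory_pause", t.pause_start_frame,
                                next_pause_end, mv, smoothed.fps)
            cycles.append(RespirationCycle(cycle_id=i, phases=[insp, exp, pause]))
        elif next_pause_end is not None:
            # pause too short for its boundaries to resolve as distinct
            # frames: emit the cycle without a measurable pause
            cycles.append(RespirationCycle(cycle_id=i, phases=[insp, exp],
                                           complete=False))
        else:
            # inspiration and expiration are fully bounded by this triple's
            # transitions; only the unclosed pause is missing
            cycles.append(RespirationCycle(cycle_id=i, phases=[insp, exp],
                                           complete=False))
    return cycles


def _make_phase(kind: str, start: int, end: int,
                values: np.ndarray, fps: float) -> RespirationPhase:
    duration_s, amplitude_C, slope = phase_metrics(start, end, values, fps)
    return RespirationPhase(kind=kind, start_frame=start, end_frame=end,
                            duration_s=duration_s, amplitude_C=amplitude_C,
                            slope=slope)


def phase_metrics(start_frame: int, end_frame: int,
                  values: np.ndarray | TemperatureTrace,
                  fps: float | None = None) -> tuple[float, float, float]:
    """(duration_s, amplitude_C, slope) of the interval [start, end).

    Duration is the frame span over the frame rate; amplitude is the
    absolute temperature change between the two boundary frames; slope is
    amplitude/duration by definition.  ``values`` may be a trace (its own
    fps is used) or a plain array with ``fps`` given.  Amplitudes are read
    from whichever trace is passed; the unsmoothed trace is preferred for
    metrics because zero-phase filtering rounds off the extrema and
    systematically shrinks phase amplitudes.
    """
    if isinstance(values, TemperatureTrace):
        fps = values.fps if fps is None else fps
        values = values.temperature_C
    if fps is None:
        raise ValueError("fps required when values is a plain array")
    if end_frame <= start_frame:
        raise ValueError(f"zero-length phase [{start_frame}, {end_frame})")
    duration_s = (end_frame - start_frame) / fps
    amplitude_C = abs(float(values[end_frame] - values[start_frame]))
    return duration_s, amplitude_C, amplitude_C / duration_s


def residual_trace(values: np.ndarray) -> np.ndarray:
    """Residual temperature: per-frame value minus the segment mean."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty segment")
    return values - values.mean()


def mean_cycle(
    cycles: Sequence[RespirationCycle],
    smoothed: TemperatureTrace,
    n_points: int = 100,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Average residual-temperature waveform across complete cycles.

    Each complete cycle's residual trace (relative to the whole-segment
    mean) is linearly resampled to ``n_points``; the pointwise mean and a
    percentile-based confidence band are returned as a DataFrame with
    columns point, mean_residual_C, ci_low, ci_high.
    """
    complete = [c for c in cycles if c.complete]
    if len(complete) < 2:
        raise ValueError("mean cycle requires at least 2 complete cycles")
    resid = residual_trace(smoothed.temperature_C)
    grid = np.linspace(0.0, 1.0, n_points)
    stack = np.empty((len(complete), n_points))
    for i, c in enumerate(complete):
        seg = resid[c.start_frame:c.end_frame + 1]
        x = np.linspace(0.0, 1.0, len(seg))
        stack[i] = np.interp(grid, x, seg)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.percentile(stack, [100 * alpha, 100 * (1 - alpha)], axis=0)
    return pd.DataFrame({
        "point": np.arange(n_points),
        "mean_residual_C": stack.mean(axis=0),
        "ci_low": lo,
        "ci_high": hi,
    })


def interpolated_median(values: np.ndarray, resolution: float) -> float:
    """Median of grid-quantized values, interpolated within the median bin.

    Phase durations are integer frame counts over the frame rate, so their
    plain sample median is stuck on the 1/fps grid.  Treating each
    observed value v as the bin [v - r/2, v + r/2) and interpolating the
    cumulative distribution inside the bin that crosses 0.5 (the grouped
    median of classical descriptive statistics) recovers sub-grid
    resolution.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty sample")
    m = float(np.median(v))
    in_bin = np.abs(v - m) < resolution / 2.0
    f_bin = in_bin.mean()
    if f_bin == 0.0:
        return m
    f_below = float((v < m - resolution / 2.0).mean())
    return (m - resolution / 2.0) + (0.5 - f_below) / f_bin * resolution


def breathing_rate(transitions: Sequence[TransitionPoints],
                   fps: float) -> float:
    """Mean breathing rate (cycles/s) from maximum-inspiration spacing.

    Successive maximum-inspiration points are one full cycle apart, so the
    rate is (n - 1) cycles over the time between the first and last.
    """
    if len(transitions) < 2:
        raise ValueError("rate estimation requires >= 2 detected cycles")
    ts = sorted(t.max_inspiration_frame for t in transitions)
    return (len(ts) - 1) / ((ts[-1] - ts[0]) / fps)


def segment_trace(
    trace: TemperatureTrace,
    order: int = DEFAULT_FILTER_ORDER,
    critical_frequency: float = DEFAULT_CRITICAL_FREQUENCY,
    min_prominence_C: float = DEFAULT_MIN_PROMINENCE_C,
    min_cycle_spacing_s: float = DEFAULT_MIN_CYCLE_SPACING_S,
    slope_epsilon_C_per_s: float | None = None,
    slope_window_frames: int = DEFAULT_SLOPE_WINDOW_FRAMES,
) -> tuple[TemperatureTrace, list[RespirationCycle]]:
    """Smooth a trace and segment it into cycles (convenience wrapper)."""
    smoothed = smooth_trace(trace, order=order, critical_frequency=critical_frequency)
    transitions = detect_transition_points(
        smoothed,
        min_prominence_C=min_prominence_C,
        min_cycle_spacing_s=min_cycle_spacing_s,
        slope_epsilon_C_per_s=slope_epsilon_C_per_s,
        slope_window_frames=slope_window_frames,
        raw_values=trace.temperature_C,
    )
    return smoothed, build_cycles(transitions, smoothed,
                                  metric_values=trace.temperature_C)


def cycles_to_frame(cycles: Sequence[RespirationCycle],
                    segment_id: str = "seg0") -> pd.DataFrame:
    """Flatten cycles into a tidy per-phase DataFrame for CSV export."""
    rows = []
    for c in cycles:
        for p in c.phases:
            rows.append({
                "segment_id": segment_id,
                "cycle_id": c.cycle_id,
                "phase": p.kind,
                "start_frame": p.start_frame,
                "end_frame": p.end_frame,
                "duration_s": p.duration_s,
                "amplitude_C": p.amplitude_C,
                "slope": p.slope,
                "complete": p.complete,
                "cycle_type": c.cycle_type,
            })
    return pd.DataFrame(rows)
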