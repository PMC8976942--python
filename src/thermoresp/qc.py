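"""Quality control of nostril-detection tables and trace assembly.

The pose-estimation detector emits one row per (frame, nostril side) with
pixel coordinates and a confidence score.  Analysable segments must span
at least three respiration cycles (150 frames at 30 fps), contain no run
of more than 5 consecutive frames without a valid detection, and have both
nostrils detected (front-view head orientation) at confidence >= 0.95.
Segments passing QC are assembled into gap-filled temperature traces and
screened for a clear respiratory periodicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence, Union

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "DetectionRecord",
    "TemperatureTrace",
    "min_segment_frames",
    "select_segments",
    "build_trace",
    "inspect_periodicity",
    "PeriodicityReport",
]

DEFAULT_MIN_LEN = 150       # frames: >= 3 cycles at the mean respiration rate
DEFAULT_MAX_GAP = 5         # frames: longest tolerated detection gap
DEFAULT_MIN_CONF = 0.95     # detector certainty cut-off
DEFAULT_FPS = 30.0


@dataclass(frozen=True)
class DetectionRecord:
    """One nostril detection: frame index, side, pixel position, confidence."""

    frame: int
    side: str  # "left" or "right"
    x: float
    y: float
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")


@dataclass
class TemperatureTrace:
    """Per-frame nostril temperature series for one analysable segment.

    ``frames`` are strictly increasing and contiguous after gap filling;
    ``interpolated_mask`` flags frames whose value was filled rather than
    measured.
    """

    segment_id: str
    individual_id: str
    fps: float
    frames: np.ndarray          # int, contiguous
    temperature_C: np.ndarray   # float, same length
    interpolated_mask: np.ndarray = field(default=None)  # bool, same length

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        if self.interpolated_mask is None:
            self.interpolated_mask = np.zeros(len(self.frames), dtype=bool)
        self.interpolated_mask = np.asarray(self.interpolated_mask, dtype=bool)
        if len(self.frames) != len(self.temperature_C):
            raise ValueError("frames and temperature_C length mismatch")
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) == 1):
            raise ValueError("trace frames must be contiguous")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        return len(self.frames) / self.fps

    @property
    def time_s(self) -> np.ndarray:
        return self.frames / self.fps


def min_segment_frames(
    n_cycles: int = 3, mean_cycle_s: float = 1.6, fps: float = DEFAULT_FPS
) -> int:
    """Minimum segment length implied by the QC rationale.

    A segment must span at least ``n_cycles`` full respiration cycles to
    make the periodicity identifiable: n_cycles x mean cycle duration x
    frame rate (3 x 1.6 s x 30 fps = 144 frames, rounded up to the 150
    frame / 5 s default cut-off in practice).
    """
    return int(np.ceil(round(n_cycles * mean_cycle_s * fps, 9)))


def _coverage(
    detections: Union[pd.DataFrame, Sequence[DetectionRecord]],
    min_conf: float,
    require_both: bool,
) -> np.ndarray:
    """Sorted array of covered frame indices."""
    if isinstance(detections, pd.DataFrame):
        df = detections
    else:
        df = pd.DataFrame(
            [(d.frame, d.side, d.confidence) for d in detections],
            columns=["frame", "side", "confidence"],
        )
    if df.empty:
        return np.array([], dtype=int)
    ok = df[df["confidence"] >= min_conf]
    if require_both:
        sides = ok.groupby("frame")["side"].nunique()
        covered = sides.index[sides >= 2].to_numpy()
    else:
        covered = ok["frame"].unique()
    return np.sort(np.asarray(covered, dtype=int))


def select_segments(
    detections: Union[pd.DataFrame, Sequence[DetectionRecord]],
    min_len: int = DEFAULT_MIN_LEN,
    max_gap: int = DEFAULT_MAX_GAP,
    min_conf: float = DEFAULT_MIN_CONF,
    require_both: bool = True,
) -> list[tuple[int, int]]:
    """Frame intervals passing all QC rules, as inclusive (start, end) pairs.

    A frame is *covered* iff both nostril sides (or any side when
    ``require_both`` is false) are detected at confidence >= ``min_conf``.
    Maximal runs of covered frames are formed, tolerating interior gaps of
    at most ``max_gap`` consecutive uncovered frames; gaps at run edges are
    trimmed (runs start and end on covered frames).  Runs spanning fewer
    than ``min_len`` frames are dropped.
    """
    covered = _coverage(detections, min_conf, require_both)
    if covered.size == 0:
        return []
    gaps = np.diff(covered)  # gap of g-1 uncovered frames where diff == g
    breaks = np.nonzero(gaps > max_gap + 1)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [covered.size - 1]))
    segments = []
    for s, e in zip(starts, ends):
        start_f, end_f = int(covered[s]), int(covered[e])
        if end_f - start_f + 1 >= min_len:
            segments.append((start_f, end_f))
    return segments


def build_trace(
    temperatures: pd.DataFrame,
    interval: tuple[int, int],
    segment_id: str = "seg0",
    individual_id: str = "ind0",
    fps: float = DEFAULT_FPS,
    side_policy: Literal["mean", "left", "right"] = "mean",
    max_gap: int = DEFAULT_MAX_GAP,
    gap_fill: Literal["interpolate", "ffill"] = "interpolate",
) -> TemperatureTrace:
    """Assemble a gap-filled temperature trace over a QC-passing interval.

    ``temperatures`` is a per-frame table with columns ``frame``, ``side``
    and ``temperature_C`` (the output of ROI extraction + radiometric
    conversion).  Under the default ``side_policy='mean'`` the per-frame
    value is the mean of left and right nostril temperatures where both
    exist, a single side's value otherwise.  Interior gaps of at most
    ``max_gap`` frames are filled (linear interpolation by default,
    carry-forward with ``gap_fill='ffill'``) and flagged in
    ``interpolated_mask``; a longer interior gap is an internal
    consistency error because QC should have split the segment.
    """
    start, end = interval
    df = temperatures[(temperatures["frame"] >= start) & (temperatures["frame"] <= end)]
    if side_policy in ("left", "right"):
        df = df[df["side"] == side_policy]
    per_frame = df.groupby("frame")["temperature_C"].mean()

    frames = np.arange(start, end + 1)
    values = per_frame.reindex(frames).to_numpy(dtype=float)
    missing = np.isnan(values)
    if missing[0] or missing[-1]:
        raise ValueError(
            f"segment {segment_id}: interval endpoints {start}/{end} lack data; "
            "intervals must start and end on measured frames"
        )
    if missing.any():
        run_lengths = _max_missing_run(missing)
        if run_lengths > max_gap:
            raise ValueError(
                f"segment {segment_id}: interior gap of {run_lengths} frames "
                f"exceeds max_gap={max_gap}; QC should have split this interval"
            )
        idx = np.arange(len(values))
        if gap_fill == "interpolate":
            values[missing] = np.interp(idx[missing], idx[~missing], values[~missing])
        else:  # carry the last measured value forward
            filled = pd.Series(values).ffill().to_numpy()
            values = filled
    return TemperatureTrace(
        segment_id=segment_id,
        individual_id=individual_id,
        fps=fps,
        frames=frames,
        temperature_C=values,
        interpolated_mask=missing,
    )


def _max_missing_run(missing: np.ndarray) -> int:
    best = run = 0
    for m in missing:
        run = run + 1 if m else 0
        best = max(best, run)
    return best


@dataclass(frozen=True)
class PeriodicityReport:
    usable: bool
    dominant_frequency_Hz: float
    peak_to_median_power: float


def inspect_periodicity(
    trace: TemperatureTrace,
    band_Hz: tuple[float, float] = (0.2, 2.0),
    min_peak_to_median: float = 10.0,
) -> PeriodicityReport:
    """Automated stand-in for visual screening of cyclic breathing patterns.

    Welch power spectrum of the mean-subtracted trace; the dominant
    frequency is the in-band spectral peak, and the trace is ``usable``
    when that peak lies in the physiological band and its power exceeds
    ``min_peak_to_median`` times the median spectral power (a prominence
    guard that rejects aperiodic noise).
    """
    x = trace.temperature_C - np.mean(trace.temperature_C)
    nperseg = min(len(x), 256)
    freqs, psd = sps.welch(x, fs=trace.fps, nperseg=nperseg)
    in_band = (freqs >= band_Hz[0]) & (freqs <= band_Hz[1])
    if not in_band.any() or np.all(psd == 0):
        return PeriodicityReport(False, float("nan"), 0.0)
    band_psd = psd[in_band]
    peak_i = int(np.argmax(band_psd))
    dominant = float(freqs[in_band][peak_i])
    ratio = float(band_psd[peak_i] / np.median(psd[psd > 0]))
    usable = ratio >= min_peak_to_median
    return PeriodicityReport(usable=usable, dominant_frequency_Hz=dominant,
                             peak_to_median_power=ratio)
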