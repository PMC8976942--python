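"""Synthetic nostril-temperature traces with known ground truth.

Generates phase-structured breathing waveforms at video frame rate: a
cosine-ramp temperature descent (inspiration), a cosine-ramp rise
(expiration) and a gently drifting plateau (expiratory pause), with
per-cycle phase durations and amplitudes drawn from per-condition
(Quiet / Call / Pre-call / Post-call) log-normal distributions
parameterised by median and IQR.  Default parameters reproduce the
summary statistics of wild-meerkat sunning-call recordings: a mean
respiration rate near 0.603 Hz, Quiet expiration amplitude median
0.78 degC (Call 1.14), Quiet expiratory-pause duration median 0.9 s
(Call 0.65), plus additive high-frequency Gaussian sensor noise.

Every simulation returns the exact transition frames, phase metrics,
cycle types and call events that generated the trace, so the detection
pipeline can be scored against ground truth.  Matching detection tables,
call-label files and raw-count frame stacks exercise the QC and
radiometric stages end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationConstants, RoiSpec, temperature_to_raw
from .sync import CallEvent, SyncMap

__all__ = [
    "LogNormalSpec",
    "ConditionParams",
    "BreathModelParams",
    "GroundTruthCycle",
    "GroundTruth",
    "simulate_trace",
    "simulate_dataset",
    "simulate_raw_stack",
    "condition_sequence_for_calls",
]

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal


@dataclass(frozen=True)
class LogNormalSpec:
    """Positive-support distribution parameterised by median and IQR.

    Log-normal with mu = ln(median) and sigma solved from
    IQR = median * 2 sinh(z75 * sigma); an IQR of zero degenerates to a
    point mass at the median, which makes noiseless deterministic traces
    easy to request.
    """

    median: float
    iqr: float = 0.0

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise ValueError(f"median must be > 0, got {self.median}")
        if self.iqr < 0:
            raise ValueError(f"iqr must be >= 0, got {self.iqr}")

    @property
    def sigma(self) -> float:
        return float(np.arcsinh(self.iqr / (2.0 * self.median)) / _Z75)

    def draw(self, rng: np.random.Generator, size=None):
        if self.iqr == 0.0:
            return self.median if size is None else np.full(size, self.median)
        return rng.lognormal(mean=np.log(self.median), sigma=self.sigma, size=size)


@dataclass(frozen=True)
class ConditionParams:
    """Phase-parameter distributions for one cycle condition."""

    insp_duration_s: LogNormalSpec
    exp_duration_s: LogNormalSpec
    pause_duration_s: LogNormalSpec
    insp_amplitude_C: LogNormalSpec
    exp_amplitude_C: LogNormalSpec
    pause_amplitude_C: LogNormalSpec


def _default_conditions() -> dict[str, ConditionParams]:
    # Medians/IQRs follow the field-data summaries this simulator emulates:
    # expiration amplitude 0.78/0.40 (Quiet) vs 1.14/0.73 (Call), pause
    # duration 0.9/0.65 vs 0.65/0.53, pause amplitude 0.16/0.26 (Quiet) and
    # 0.22/0.33 (Pre-call), inspiration amplitude 0.87/0.48 vs 1.21/0.83.
    # Inspiration/expiration durations are not reported; 0.29 s medians give
    # a mean cycle duration of 1.656 s (0.603 Hz mean rate) with a ~1.0
    # inspiration/expiration time ratio.  Call limb durations of 0.40 s are
    # back-computed from the reported Call amplitude/slope medians.
    quiet = ConditionParams(
        insp_duration_s=LogNormalSpec(0.29, 0.15),
        exp_duration_s=LogNormalSpec(0.29, 0.15),
        pause_duration_s=LogNormalSpec(0.90, 0.65),
        insp_amplitude_C=LogNormalSpec(0.87, 0.48),
        exp_amplitude_C=LogNormalSpec(0.78, 0.40),
        pause_amplitude_C=LogNormalSpec(0.16, 0.26),
    )
    call = ConditionParams(
        insp_duration_s=LogNormalSpec(0.40, 0.20),
        exp_duration_s=LogNormalSpec(0.40, 0.20),
        pause_duration_s=LogNormalSpec(0.65, 0.53),
        insp_amplitude_C=LogNormalSpec(1.21, 0.83),
        exp_amplitude_C=LogNormalSpec(1.14, 0.73),
        pause_amplitude_C=LogNormalSpec(0.20, 0.26),
    )
    precall = ConditionParams(
        insp_duration_s=LogNormalSpec(0.29, 0.15),
        exp_duration_s=LogNormalSpec(0.29, 0.15),
        pause_duration_s=LogNormalSpec(0.90, 0.65),
        insp_amplitude_C=LogNormalSpec(0.90, 0.48),
        exp_amplitude_C=LogNormalSpec(0.80, 0.40),
        pause_amplitude_C=LogNormalSpec(0.22, 0.33),
    )
    postcall = ConditionParams(
        insp_duration_s=LogNormalSpec(0.29, 0.15),
        exp_duration_s=LogNormalSpec(0.29, 0.15),
        pause_duration_s=LogNormalSpec(0.90, 0.65),
        insp_amplitude_C=LogNormalSpec(0.92, 0.48),
        exp_amplitude_C=LogNormalSpec(0.80, 0.40),
        pause_amplitude_C=LogNormalSpec(0.20, 0.26),
    )
    return {"Quiet": quiet, "Call": call, "Pre-call": precall,
            "Post-call": postcall}


@dataclass(frozen=True)
class BreathModelParams:
    """Generator configuration for phase-structured breathing traces.

    ``noise_sd_C`` is the standard deviation of the additive per-frame
    Gaussian sensor noise; ``call_duration_s`` models the short, soft
    sunning calls (~50 ms) of the emulated recordings.  When
    ``derive_insp_amplitude`` is set (default) the per-cycle inspiration
    amplitude equals expiration amplitude + pause amplitude so that each
    cycle returns to its starting temperature and the trace has no secular
    drift; the configured inspiration-amplitude distribution is then a
    descriptive reference only.
    """

    fps: float = 30.0
    baseline_temp_C: float = 32.0
    noise_sd_C: float = 0.02
    call_duration_s: LogNormalSpec = field(default_factory=lambda: LogNormalSpec(0.05, 0.02))
    conditions: dict[str, ConditionParams] = field(default_factory=_default_conditions)
    derive_insp_amplitude: bool = True
    lead_in_s: float = 0.5
    max_pause_drift_C_per_s: float = 0.8

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.noise_sd_C < 0:
            raise ValueError("noise_sd_C must be >= 0")


@dataclass
class GroundTruthCycle:
    """True parameters of one generated cycle."""

    cycle_id: int
    condition: str
    insp_start_frame: int    # end of the preceding pause
    max_insp_frame: int
    pause_start_frame: int
    pause_end_frame: int     # start of the next cycle's inspiration
    insp_duration_s: float
    exp_duration_s: float
    pause_duration_s: float
    insp_amplitude_C: float
    exp_amplitude_C: float
    pause_amplitude_C: float


@dataclass
class GroundTruth:
    """Everything the generator knows about a simulated trace."""

    cycles: list[GroundTruthCycle]
    focal_calls: list[CallEvent]
    nonfocal_calls: list[CallEvent]
    seed: int

    @property
    def mean_rate_Hz(self) -> float:
        total = sum(c.insp_duration_s + c.exp_duration_s + c.pause_duration_s
                    for c in self.cycles)
        return len(self.cycles) / total

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cycles:
            for kind, d, a in (
                ("inspiration", c.insp_duration_s, c.insp_amplitude_C),
                ("expiration", c.exp_duration_s, c.exp_amplitude_C),
                ("expiratory_pause", c.pause_duration_s, c.pause_amplitude_C),
            ):
                rows.append({"cycle_id": c.cycle_id, "condition": c.condition,
                             "phase": kind, "duration_s": d, "amplitude_C": a,
                             "slope": a / d})
        return pd.DataFrame(rows)


def condition_sequence_for_calls(n_cycles: int,
                                 call_cycles: Sequence[int]) -> list[str]:
    """Cycle-type sequence implied by placing focal calls in given cycles."""
    seq = ["Quiet"] * n_cycles
    for k in call_cycles:
        seq[k] = "Call"
    for k in call_cycles:
        if k - 1 >= 0 and seq[k - 1] == "Quiet":
            seq[k - 1] = "Pre-call"
        if k + 1 < n_cycles and seq[k + 1] == "Quiet":
            seq[k + 1] = "Post-call"
    return seq


def _cosine_ramp(t: np.ndarray, duration: float) -> np.ndarray:
    """Smooth 0->1 ramp with zero slope at both ends."""
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(t, 0.0, duration) / duration))


def simulate_trace(
    params: BreathModelParams,
    n_cycles: int,
    condition_sequence: Sequence[str] | None = None,
    seed: int = 0,
    rng: np.random.Generator | None = None,
):
    """Generate one temperature trace and its ground truth.

    Returns ``(trace, ground_truth)`` where ``trace`` is a
    :class:`~thermoresp.qc.TemperatureTrace` starting with a short flat
    lead-in (so the first inspiration onset is an interior plateau
    boundary, detectable like any other).  Focal calls are placed inside
    the expiration phase of Call cycles, where mammalian vocal production
    overlaps exhalation.  Fully reproducible from ``seed``.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if condition_sequence is None:
        condition_sequence = ["Quiet"] * n_cycles
    if len(condition_sequence) != n_cycles:
        raise ValueError("condition_sequence length must equal n_cycles")
    unknown = set(condition_sequence) - set(params.conditions)
    if unknown:
        raise ValueError(f"unknown conditions: {sorted(unknown)}")
    if rng is None:
        rng = np.random.default_rng(seed)
    fps = params.fps
    dt = 1.0 / fps

    # draw per-cycle parameters
    cycles: list[dict] = []
    for k, cond in enumerate(condition_sequence):
        cp = params.conditions[cond]
        a_exp = float(cp.exp_amplitude_C.draw(rng))
        a_pause = float(cp.pause_amplitude_C.draw(rng))
        d_pause = float(cp.pause_duration_s.draw(rng))
        # the pause is a rest phase: its drift stays well below the active
        # limbs in amplitude and below a stability bound in peak slope
        a_pause = min(a_pause, 0.5 * a_exp,
                      (2.0 / np.pi) * params.max_pause_drift_C_per_s * d_pause)
        if params.derive_insp_amplitude:
            a_insp = a_exp + a_pause
        else:
            a_insp = float(cp.insp_amplitude_C.draw(rng))
        cycles.append({
            "condition": cond,
            "d_insp": float(cp.insp_duration_s.draw(rng)),
            "d_exp": float(cp.exp_duration_s.draw(rng)),
            "d_pause": d_pause,
            "a_insp": a_insp, "a_exp": a_exp, "a_pause": a_pause,
        })

    total_s = params.lead_in_s + sum(c["d_insp"] + c["d_exp"] + c["d_pause"]
                                     for c in cycles)
    n_frames = int(np.ceil(total_s * fps)) + 1
    t = np.arange(n_frames) * dt
    temp = np.full(n_frames, params.baseline_temp_C)

    gt_cycles: list[GroundTruthCycle] = []
    focal_calls: list[CallEvent] = []
    t0 = params.lead_in_s
    level = params.baseline_temp_C
    for k, c in enumerate(cycles):
        t1 = t0 + c["d_insp"]          # max inspiration
        t2 = t1 + c["d_exp"]           # pause start
        t3 = t2 + c["d_pause"]         # pause end / next inspiration start
        sl = slice(np.searchsorted(t, t0, "left"), np.searchsorted(t, t3, "left"))
        tt = t[sl]
        y = np.empty_like(tt)
        in_insp = tt < t1
        in_exp = (tt >= t1) & (tt < t2)
        in_pause = tt >= t2
        y[in_insp] = level - c["a_insp"] * _cosine_ramp(tt[in_insp] - t0, c["d_insp"])
        y[in_exp] = (level - c["a_insp"]
                     + c["a_exp"] * _cosine_ramp(tt[in_exp] - t1, c["d_exp"]))
        # derived mode: pause drifts back up by a_insp - a_exp = a_pause,
        # closing the cycle; free mode lets the baseline wander
        drift = c["a_insp"] - c["a_exp"] if params.derive_insp_amplitude else c["a_pause"]
        y[in_pause] = (level - c["a_insp"] + c["a_exp"]
                       + drift * _cosine_ramp(tt[in_pause] - t2, c["d_pause"]))
        temp[sl] = y
        pause_level = level - c["a_insp"] + c["a_exp"] + drift
        temp[sl.stop:] = pause_level

        if c["condition"] == "Call":
            onset = t1 + rng.uniform(0.1, 0.5) * c["d_exp"]
            dur = float(params.call_duration_s.draw(rng))
            focal_calls.append(CallEvent(onset_s=onset, offset_s=onset + dur,
                                         caller="focal"))
        gt_cycles.append(GroundTruthCycle(
            cycle_id=k, condition=c["condition"],
            insp_start_frame=int(round(t0 * fps)),
            max_insp_frame=int(round(t1 * fps)),
            pause_start_frame=int(round(t2 * fps)),
            pause_end_frame=int(round(t3 * fps)),
            insp_duration_s=c["d_insp"], exp_duration_s=c["d_exp"],
            pause_duration_s=c["d_pause"], insp_amplitude_C=c["a_insp"],
            exp_amplitude_C=c["a_exp"], pause_amplitude_C=abs(drift),
        ))
        t0 = t3
        level = pause_level

    if params.noise_sd_C > 0:
        temp = temp + rng.normal(0.0, params.noise_sd_C, size=n_frames)

    from .qc import TemperatureTrace  # local import avoids cycle at module load
    trace = TemperatureTrace(
        segment_id="sim", individual_id="sim", fps=fps,
        frames=np.arange(n_frames), temperature_C=temp,
    )
    gt = GroundTruth(cycles=gt_cycles, focal_calls=focal_calls,
                     nonfocal_calls=[], seed=seed)
    return trace, gt


def simulate_dataset(
    n_individuals: int,
    cycles_per_individual: int,
    calls_per_individual: int,
    params: BreathModelParams | None = None,
    nf_calls_per_individual: int = 2,
    seed: int = 0,
):
    """Simulate a multi-individual dataset mirroring a field recording set.

    For each individual a trace is generated with ``calls_per_individual``
    focal calls in non-adjacent cycles, plus non-focal calls placed inside
    Quiet stretches.  Returns a dict per individual with the trace, ground
    truth, a detection table (both nostrils at confidence 0.99), the call
    events on the audio clock and the sync map; the audio clock runs ahead
    of video by a per-individual offset.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    params = params or BreathModelParams()
    master = np.random.default_rng(seed)
    dataset = []
    for i in range(n_individuals):
        rng = np.random.default_rng(master.integers(2**31))
        n = cycles_per_individual
        eligible = np.arange(1, n - 1)
        call_cycles: list[int] = []
        rng.shuffle(eligible)
        for c in eligible:
            if len(call_cycles) >= calls_per_individual:
                break
            if all(abs(c - k) > 2 for k in call_cycles):
                call_cycles.append(int(c))
        seq = condition_sequence_for_calls(n, call_cycles)
        trace, gt = simulate_trace(params, n, seq, rng=rng)
        trace.segment_id = f"seg{i}"
        trace.individual_id = f"ind{i}"

        offset = float(rng.uniform(2.0, 10.0))
        sync = SyncMap(offset_s=offset, fps=params.fps)
        gt.focal_calls = [
            CallEvent(e.onset_s + offset, e.offset_s + offset, "focal")
            for e in gt.focal_calls
        ]
        # NF calls inside Quiet cycles not adjacent to focal calls
        quiet_ids = [c.cycle_id for c in gt.cycles if c.condition == "Quiet"]
        rng.shuffle(quiet_ids)
        nf = []
        for cid in quiet_ids[:nf_calls_per_individual]:
            c = gt.cycles[cid]
            onset = (c.insp_start_frame / params.fps
                     + rng.uniform(0.2, 0.8)
                     * (c.pause_end_frame - c.insp_start_frame) / params.fps)
            dur = float(params.call_duration_s.draw(rng))
            nf.append(CallEvent(onset + offset, onset + offset + dur, "nonfocal"))
        gt.nonfocal_calls = sorted(nf, key=lambda e: e.onset_s)

        detections = pd.DataFrame({
            "frame": np.repeat(trace.frames, 2),
            "side": np.tile(["left", "right"], len(trace)),
            "x": 100.0, "y": 50.0, "confidence": 0.99,
        })
        dataset.append({
            "individual_id": f"ind{i}", "trace": trace, "ground_truth": gt,
            "detections": detections, "sync": sync,
            "calls": sorted(gt.focal_calls + gt.nonfocal_calls,
                            key=lambda e: e.onset_s),
        })
    return dataset


def simulate_raw_stack(
    trace,
    calib: CalibrationConstants,
    frame_size: tuple[int, int] = (60, 80),
    nostril_centers: Sequence[tuple[int, int]] = ((30, 40), (50, 40)),
    patch_size: tuple[int, int] = (14, 9),
    background_temp_C: float = 20.0,
):
    """Raw-count frame stack whose nostril patches encode the trace.

    Each frame is the background temperature's raw level with warm
    rectangular patches (``patch_size`` = width x height around each
    nostril center) at the trace temperature's raw level, so that ROI
    median extraction followed by radiometric inversion reproduces the
    input trace exactly.  Returns ``(stack, detections)`` with a float
    stack (no quantisation) and the matching detection table.
    """
    h, w = frame_size
    bg_raw = temperature_to_raw(background_temp_C, calib)
    stack = np.full((len(trace), h, w), bg_raw, dtype=float)
    pw, ph = patch_size
    for temp, frame in zip(trace.temperature_C, stack):
        raw = temperature_to_raw(float(temp), calib)
        for cx, cy in nostril_centers:
            x0 = max(cx - (pw - 1) // 2, 0)
            y0 = max(cy - (ph - 1) // 2, 0)
            frame[y0:min(y0 + ph, h), x0:min(x0 + pw, w)] = raw
    rows = []
    for fi in trace.frames:
        for side, (cx, cy) in zip(("left", "right"), nostril_centers):
            rows.append({"frame": int(fi), "side": side, "x": float(cx),
                         "y": float(cy), "confidence": 0.99})
    return stack, pd.DataFrame(rows)


def write_manifest(path: str | Path, seed: int,
                   params: BreathModelParams) -> None:
    """Record the seed and full generator parameterisation as JSON."""
    def encode(o):
        if isinstance(o, (LogNormalSpec, ConditionParams, BreathModelParams)):
            return asdict(o)
        raise TypeError(type(o))
    with open(path, "w") as fh:
        json.dump({"seed": seed, "params": asdict(params)}, fh,
                  indent=2, default=encode)
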