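"""Pipeline configuration and stage orchestration.

Each stage is a pure function of (input files, config, seed) writing
deterministic, diff-friendly outputs: QC -> smoothing/segmentation ->
cycle classification -> permutation statistics.  The CLI in
:mod:`thermoresp.cli` wraps these stages as shell commands.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from . import qc as qc_mod
from . import segmentation as seg_mod
from . import vcrm
from .simulate import BreathModelParams, simulate_dataset
from .sync import SyncMap, load_call_labels, load_sync_markers, build_sync_map

logger = logging.getLogger("thermoresp")

__all__ = [
    "PipelineConfig",
    "load_config",
    "stage_simulate",
    "stage_qc",
    "stage_segment",
    "stage_classify",
    "stage_stats",
    "run_all",
]


@dataclass
class QCSection:
    min_len: int = qc_mod.DEFAULT_MIN_LEN        # 150 frames (5 s at 30 fps)
    max_gap: int = qc_mod.DEFAULT_MAX_GAP        # 5 consecutive frames
    min_conf: float = qc_mod.DEFAULT_MIN_CONF    # detector certainty 0.95
    require_both: bool = True                    # both nostrils detected
    side_policy: str = "mean"
    gap_fill: str = "interpolate"

    def validate(self) -> list[str]:
        errs = []
        if self.min_len < 1:
            errs.append(f"qc.min_len must be >= 1, got {self.min_len}")
        if self.max_gap < 0:
            errs.append(f"qc.max_gap must be >= 0, got {self.max_gap}")
        if not (0.0 <= self.min_conf <= 1.0):
            errs.append(f"qc.min_conf must be in [0, 1], got {self.min_conf}")
        if self.side_policy not in ("mean", "left", "right"):
            errs.append(f"qc.side_policy invalid: {self.side_policy}")
        if self.gap_fill not in ("interpolate", "ffill"):
            errs.append(f"qc.gap_fill invalid: {self.gap_fill}")
        return errs


@dataclass
class FilterSection:
    order: int = seg_mod.DEFAULT_FILTER_ORDER            # 2nd order
    critical_frequency: float = seg_mod.DEFAULT_CRITICAL_FREQUENCY  # 1/5

    def validate(self) -> list[str]:
        errs = []
        if self.order < 1:
            errs.append(f"filter.order must be >= 1, got {self.order}")
        if not (0.0 < self.critical_frequency < 1.0):
            errs.append("filter.critical_frequency must be in (0, 1), "
                        f"got {self.critical_frequency}")
        return errs


@dataclass
class DetectionSection:
    min_prominence_C: float = seg_mod.DEFAULT_MIN_PROMINENCE_C
    min_cycle_spacing_s: float = seg_mod.DEFAULT_MIN_CYCLE_SPACING_S
    slope_epsilon_C_per_s: float | None = None   # None -> adaptive default
    slope_window_frames: int = seg_mod.DEFAULT_SLOPE_WINDOW_FRAMES

    def validate(self) -> list[str]:
        errs = []
        if self.min_prominence_C <= 0:
            errs.append("detection.min_prominence_C must be > 0")
        if self.slope_window_frames < 3:
            errs.append("detection.slope_window_frames must be >= 3")
        return errs


@dataclass
class ClassifySection:
    edge_window_s: float = vcrm.DEFAULT_EDGE_WINDOW_S    # 2 s
    precedence: tuple = ("Call", "Post-call", "Pre-call")

    def validate(self) -> list[str]:
        errs = []
        if self.edge_window_s < 0:
            errs.append("classify.edge_window_s must be >= 0")
        return errs


@dataclass
class StatsSection:
    n_permutations: int = vcrm.DEFAULT_N_PERMUTATIONS    # 10,000
    seed: int = 0
    parameters: tuple = ("duration_s", "amplitude_C", "slope")
    groups: tuple = ("Call", "Quiet")

    def validate(self) -> list[str]:
        errs = []
        if self.n_permutations < 1:
            errs.append("stats.n_permutations must be >= 1")
        return errs


@dataclass
class PipelineConfig:
    """Structured per-stage configuration; defaults follow the documented
    field protocol (30 fps video, 150/5/0.95 QC, 2nd-order 1/5 filter,
    2 s edge window, 10,000 permutations)."""

    fps: float = 30.0
    qc: QCSection = field(default_factory=QCSection)
    filter: FilterSection = field(default_factory=FilterSection)
    detection: DetectionSection = field(default_factory=DetectionSection)
    classify: ClassifySection = field(default_factory=ClassifySection)
    stats: StatsSection = field(default_factory=StatsSection)
    calibration_file: str | None = None

    def validate(self) -> None:
        errs = []
        if self.fps <= 0:
            errs.append(f"fps must be > 0, got {self.fps}")
        for section in (self.qc, self.filter, self.detection,
                        self.classify, self.stats):
            errs.extend(section.validate())
        if errs:
            raise ValueError("invalid config: " + "; ".join(errs))


_SECTIONS = {"qc": QCSection, "filter": FilterSection,
             "detection": DetectionSection, "classify": ClassifySection,
             "stats": StatsSection}


def load_config(path: Union[str, Path, None]) -> PipelineConfig:
    """Load a YAML config with per-stage sections; unknown keys error."""
    if path is None:
        cfg = PipelineConfig()
        cfg.validate()
        return cfg
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    kwargs = {}
    for key, value in data.items():
        if key in _SECTIONS:
            cls = _SECTIONS[key]
            valid = set(cls.__dataclass_fields__)
            unknown = set(value) - valid
            if unknown:
                raise ValueError(
                    f"unknown keys in config section '{key}': {sorted(unknown)}")
            for tup in ("precedence", "parameters", "groups"):
                if tup in value:
                    value[tup] = tuple(value[tup])
            kwargs[key] = cls(**value)
        elif key in ("fps", "calibration_file"):
            kwargs[key] = value
        else:
            raise ValueError(f"unknown config key: {key!r}")
    cfg = PipelineConfig(**kwargs)
    cfg.validate()
    return cfg


def stage_simulate(out_dir: Union[str, Path], n_individuals: int = 5,
                   cycles_per_individual: int = 30,
                   calls_per_individual: int = 3,
                   params: BreathModelParams | None = None,
                   seed: int = 0) -> list[Path]:
    """Write a simulated dataset in the file formats the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = params or BreathModelParams()
    dataset = simulate_dataset(n_individuals, cycles_per_individual,
                               calls_per_individual, params=params, seed=seed)
    written = []
    for item in dataset:
        ind = item["individual_id"]
        trace = item["trace"]
        item["detections"].to_csv(out / f"{ind}_detections.csv", index=False)
        temps = pd.DataFrame({
            "frame": np.repeat(trace.frames, 2),
            "side": np.tile(["left", "right"], len(trace)),
            "temperature_C": np.repeat(trace.temperature_C, 2),
        })
        temps.to_csv(out / f"{ind}_temperatures.csv", index=False)
        pd.DataFrame(
            [(e.onset_s, e.offset_s, "F" if e.caller == "focal" else "NF")
             for e in item["calls"]],
            columns=["onset_s", "offset_s", "caller"],
        ).to_csv(out / f"{ind}_calls.csv", index=False)
        sync = item["sync"]
        pd.DataFrame({"audio_time_s": [sync.offset_s], "video_frame": [0]}
                     ).to_csv(out / f"{ind}_sync.csv", index=False)
        written.extend(out.glob(f"{ind}_*.csv"))
    logger.info("simulated %d individuals into %s", n_individuals, out)
    return written


def stage_qc(detections_csv: Union[str, Path], cfg: PipelineConfig,
             out_csv: Union[str, Path]) -> pd.DataFrame:
    """Select analyzable segments from a detection table; write segments CSV."""
    det = pd.read_csv(detections_csv)
    segments = qc_mod.select_segments(
        det, min_len=cfg.qc.min_len, max_gap=cfg.qc.max_gap,
        min_conf=cfg.qc.min_conf, require_both=cfg.qc.require_both)
    df = pd.DataFrame(
        [(f"seg{i}", s, e) for i, (s, e) in enumerate(segments)],
        columns=["segment_id", "start_frame", "end_frame"],
    )
    df.to_csv(out_csv, index=False)
    logger.info("QC: %d segments from %s", len(df), detections_csv)
    return df


def stage_segment(temperatures_csv: Union[str, Path],
                  segments_csv: Union[str, Path], cfg: PipelineConfig,
                  out_csv: Union[str, Path],
                  individual_id: str = "ind0") -> pd.DataFrame:
    """Smooth each segment's trace and write the per-phase cycles CSV."""
    temps = pd.read_csv(temperatures_csv)
    segs = pd.read_csv(segments_csv)
    frames = []
    for row in segs.itertuples():
        trace = qc_mod.build_trace(
            temps, (int(row.start_frame), int(row.end_frame)),
            segment_id=row.segment_id, individual_id=individual_id,
            fps=cfg.fps, side_policy=cfg.qc.side_policy,
            max_gap=cfg.qc.max_gap, gap_fill=cfg.qc.gap_fill)
        _, cycles = seg_mod.segment_trace(
            trace, order=cfg.filter.order,
            critical_frequency=cfg.filter.critical_frequency,
            min_prominence_C=cfg.detection.min_prominence_C,
            min_cycle_spacing_s=cfg.detection.min_cycle_spacing_s,
            slope_epsilon_C_per_s=cfg.detection.slope_epsilon_C_per_s,
            slope_window_frames=cfg.detection.slope_window_frames)
        df = seg_mod.cycles_to_frame(cycles, segment_id=row.segment_id)
        if not df.empty:
            df["individual_id"] = individual_id
            df["segment_start_frame"] = int(row.start_frame)
            frames.append(df)
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=["segment_id", "cycle_id", "phase",
                                      "start_frame", "end_frame", "duration_s",
                                      "amplitude_C", "slope", "complete",
                                      "cycle_type", "individual_id",
                                      "segment_start_frame"]))
    out = out.sort_values(["individual_id", "segment_id", "start_frame"],
                          kind="stable").reset_index(drop=True)
    out.to_csv(out_csv, index=False)
    logger.info("segment: %d phases from %s", len(out), temperatures_csv)
    return out


def stage_classify(cycles_csv: Union[str, Path], calls_path: Union[str, Path],
                   sync_path: Union[str, Path], cfg: PipelineConfig,
                   out_csv: Union[str, Path]) -> pd.DataFrame:
    """Label cycles by focal calls and Quiet-cycle phases by NF calls."""
    phases = pd.read_csv(cycles_csv)
    events = load_call_labels(calls_path)
    sync = build_sync_map(load_sync_markers(sync_path), fps=cfg.fps)
    focal = [e for e in events if e.caller == "focal"]
    nonfocal = [e for e in events if e.caller == "nonfocal"]

    labelled = []
    for seg_id, seg_phases in phases.groupby("segment_id", sort=True):
        offset = int(seg_phases["segment_start_frame"].iloc[0]) \
            if "segment_start_frame" in seg_phases else 0
        cycles = _phases_to_cycles(seg_phases)
        vcrm.classify_cycles(cycles, focal, sync, frame_offset=offset,
                             edge_window_s=cfg.classify.edge_window_s,
                             precedence=cfg.classify.precedence)
        seg_phases = seg_phases.copy()
        type_by_id = {c.cycle_id: c.cycle_type for c in cycles}
        seg_phases["cycle_type"] = seg_phases["cycle_id"].map(type_by_id)
        quiet = seg_phases[seg_phases["cycle_type"] == "Quiet"]
        nf = vcrm.label_nf_phases(quiet, nonfocal, sync, frame_offset=offset)
        seg_phases["nf_label"] = nf.reindex(seg_phases.index)
        labelled.append(seg_phases)
    out = pd.concat(labelled, ignore_index=True) if labelled else phases
    out.to_csv(out_csv, index=False)
    return out


def _phases_to_cycles(seg_phases: pd.DataFrame) -> list:
    cycles = []
    for cid, grp in seg_phases.groupby("cycle_id", sort=True):
        phs = [seg_mod.RespirationPhase(
            kind=r.phase, start_frame=int(r.start_frame),
            end_frame=int(r.end_frame), duration_s=float(r.duration_s),
            amplitude_C=float(r.amplitude_C), slope=float(r.slope),
            complete=bool(r.complete)) for r in grp.itertuples()]
        cycles.append(seg_mod.RespirationCycle(
            cycle_id=int(cid), phases=phs,
            complete=all(p.complete for p in phs)))
    cycles.sort(key=lambda c: c.start_frame)
    return cycles


def stage_stats(labelled_csv: Union[str, Path], cfg: PipelineConfig,
                out_json: Union[str, Path],
                null_dir: Union[str, Path, None] = None) -> dict:
    """Run the within-individual permutation tests; write results JSON."""
    records = pd.read_csv(labelled_csv)
    records = records[records["complete"]]
    results = {}
    seq = np.random.SeedSequence(cfg.stats.seed)
    for phase in seg_mod.PHASE_ORDER:
        for param in cfg.stats.parameters:
            sub_seed = int(seq.spawn(1)[0].generate_state(1)[0] % (2**31))
            key = f"{phase}.{param}"
            try:
                res = vcrm.permutation_test(
                    records, parameter=param, phase=phase,
                    groups=tuple(cfg.stats.groups),
                    n_permutations=cfg.stats.n_permutations, seed=sub_seed)
            except ValueError as exc:
                logger.warning("stats %s skipped: %s", key, exc)
                continue
            results[key] = {
                "parameter": res.parameter, "phase": res.phase,
                "groups": list(res.groups), "n_A": res.n_a, "n_B": res.n_b,
                "delta_mean": res.delta_mean_observed,
                "pseudo_p": res.pseudo_p,
                "n_permutations": res.n_permutations, "seed": res.seed,
            }
            if null_dir is not None:
                Path(null_dir).mkdir(parents=True, exist_ok=True)
                pd.DataFrame({"delta_perm_mean": res.null_deltas}).to_csv(
                    Path(null_dir) / f"null_{phase}_{param}.csv", index=False)
    with open(out_json, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    return results


def run_all(data_dir: Union[str, Path], out_dir: Union[str, Path],
            cfg: PipelineConfig | None = None) -> dict:
    """Chain QC -> segmentation -> classification -> statistics.

    ``data_dir`` holds per-individual files named
    ``<id>_detections.csv``, ``<id>_temperatures.csv``, ``<id>_calls.csv``
    and ``<id>_sync.csv`` (the layout :func:`stage_simulate` writes).
    Returns the statistics results dict; intermediate tables are written
    under ``out_dir``.
    """
    cfg = cfg or PipelineConfig()
    cfg.validate()
    data_dir, out = Path(data_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    individuals = sorted(p.name[:-len("_detections.csv")]
                         for p in data_dir.glob("*_detections.csv"))
    if not individuals:
        raise FileNotFoundError(f"no *_detections.csv files in {data_dir}")
    labelled_parts = []
    for ind in individuals:
        seg_csv = out / f"{ind}_segments.csv"
        cyc_csv = out / f"{ind}_cycles.csv"
        lab_csv = out / f"{ind}_labelled.csv"
        stage_qc(data_dir / f"{ind}_detections.csv", cfg, seg_csv)
        stage_segment(data_dir / f"{ind}_temperatures.csv", seg_csv, cfg,
                      cyc_csv, individual_id=ind)
        stage_classify(cyc_csv, data_dir / f"{ind}_calls.csv",
                       data_dir / f"{ind}_sync.csv", cfg, lab_csv)
        labelled_parts.append(pd.read_csv(lab_csv))
    all_labelled = pd.concat(labelled_parts, ignore_index=True)
    all_labelled = all_labelled.sort_values(
        ["individual_id", "segment_id", "start_frame"], kind="stable")
    combined = out / "labelled_phases.csv"
    all_labelled.to_csv(combined, index=False)
    return stage_stats(combined, cfg, out / "results.json",
                       null_dir=out / "null_distributions")
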