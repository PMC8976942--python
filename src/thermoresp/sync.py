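"""Audio-video synchronization and call-annotation ingest.

Field recordings pair a focal audio track with thermal video.  Shared
sync markers (an event visible on both tracks, e.g. a lighter click with a
heat signature) anchor an affine map between the audio clock and video
frame indices.  Call annotations carry onset/offset times on the audio
clock and a caller label distinguishing the focal individual from
non-focal (NF) conspecific neighbours.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "SyncMarker",
    "SyncMap",
    "CallEvent",
    "SyncDriftError",
    "build_sync_map",
    "audio_time_to_frame",
    "frame_to_audio_time",
    "load_call_labels",
    "write_call_labels",
    "load_sync_markers",
]

DEFAULT_FPS = 30.0


class SyncDriftError(ValueError):
    """Raised when sync markers are inconsistent with a pure-offset map."""


@dataclass(frozen=True)
class SyncMarker:
    audio_time_s: float
    video_frame: int

    def __post_init__(self) -> None:
        if self.audio_time_s < 0 or self.video_frame < 0:
            raise ValueError("sync marker times and frames must be non-negative")


@dataclass(frozen=True)
class SyncMap:
    """Affine map between audio seconds and video frames.

    ``offset_s`` is the audio time of frame 0; frames are 0-based.
    """

    offset_s: float
    fps: float = DEFAULT_FPS
    marker_residuals_s: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")


@dataclass(frozen=True)
class CallEvent:
    """A focal or non-focal vocalization interval on the audio clock."""

    onset_s: float
    offset_s: float
    caller: str  # "focal" or "nonfocal"

    def __post_init__(self) -> None:
        if self.offset_s < self.onset_s:
            raise ValueError(
                f"call offset {self.offset_s} precedes onset {self.onset_s}"
            )
        if self.caller not in ("focal", "nonfocal"):
            raise ValueError(f"caller must be 'focal' or 'nonfocal', got {self.caller!r}")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def build_sync_map(
    markers: Sequence[SyncMarker],
    fps: float = DEFAULT_FPS,
    drift_tolerance_s: float | None = None,
    fit_rate: bool = False,
) -> SyncMap:
    """Fit the audio->frame map from synchronization markers.

    The offset is the mean over markers of ``audio_time - frame/fps``.
    Residuals of each marker under the fitted map are stored on the result;
    a maximum residual above ``drift_tolerance_s`` (default one frame
    period) raises :class:`SyncDriftError`, mirroring the no-drift
    assumption appropriate for short recordings.  ``fit_rate=True``
    instead least-squares-fits both offset and rate (two markers minimum),
    for datasets where clock drift is real.
    """
    if not markers:
        raise ValueError("at least one sync marker is required")
    if drift_tolerance_s is None:
        drift_tolerance_s = 1.0 / fps
    times = np.array([m.audio_time_s for m in markers], dtype=float)
    frames = np.array([m.video_frame for m in markers], dtype=float)
    if fit_rate:
        if len(markers) < 2:
            raise ValueError("rate fitting requires at least two markers")
        # audio_time = offset + frame / fps_fit
        slope, offset = np.polyfit(frames, times, 1)
        if slope <= 0:
            raise SyncDriftError("fitted frame period is non-positive")
        fps = 1.0 / slope
    else:
        offset = float(np.mean(times - frames / fps))
    residuals = times - (offset + frames / fps)
    if np.max(np.abs(residuals)) > drift_tolerance_s:
        raise SyncDriftError(
            f"max sync-marker residual {np.max(np.abs(residuals)):.4f} s exceeds "
            f"drift tolerance {drift_tolerance_s:.4f} s: audio/video clock drift"
        )
    return SyncMap(offset_s=float(offset), fps=fps,
                   marker_residuals_s=tuple(float(r) for r in residuals))


def audio_time_to_frame(t_s: Union[float, np.ndarray], sync: SyncMap):
    """Nearest video frame index for an audio-clock time."""
    frame = np.rint((np.asarray(t_s, dtype=float) - sync.offset_s) * sync.fps).astype(int)
    return int(frame) if np.isscalar(t_s) else frame


def frame_to_audio_time(frame: Union[int, np.ndarray], sync: SyncMap):
    """Audio-clock time of a video frame (inverse of audio_time_to_frame
    up to half a frame period)."""
    t = sync.offset_s + np.asarray(frame, dtype=float) / sync.fps
    return float(t) if np.isscalar(frame) else t


_CALLER_ALIASES = {
    "f": "focal", "focal": "focal",
    "nf": "nonfocal", "nonfocal": "nonfocal", "non-focal": "nonfocal",
}


def _parse_caller(label: str, lineno: int) -> str:
    key = label.strip().lower()
    if key not in _CALLER_ALIASES:
        raise ValueError(f"line {lineno}: unknown caller label {label!r} "
                         "(expected F/focal or NF/nonfocal)")
    return _CALLER_ALIASES[key]


def load_call_labels(path: Union[str, Path]) -> list[CallEvent]:
    """Read call annotations from CSV or tab-separated label-track text.

    Accepted layouts: CSV with header containing onset/offset/caller
    columns, headerless CSV ``onset,offset,caller``, or a tab-separated
    label track ``start<TAB>end<TAB>label``.  Events are returned sorted by
    onset; malformed rows raise with their line number.
    """
    path = Path(path)
    events: list[CallEvent] = []
    with open(path, newline="") as fh:
        text = fh.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        fields = line.split("\t") if "\t" in line else next(csv.reader([line]))
        if len(fields) < 3:
            raise ValueError(f"{path}, line {lineno}: expected 3 fields, got {len(fields)}")
        if lineno == 1 and not _is_number(fields[0]):
            continue  # header row
        try:
            onset, offset = float(fields[0]), float(fields[1])
        except ValueError as exc:
            raise ValueError(f"{path}, line {lineno}: non-numeric time field") from exc
        if offset < onset:
            raise ValueError(f"{path}, line {lineno}: offset {offset} precedes onset {onset}")
        try:
            caller = _parse_caller(fields[2], lineno)
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
        events.append(CallEvent(onset_s=onset, offset_s=offset, caller=caller))
    events.sort(key=lambda e: e.onset_s)
    return events


def write_call_labels(events: Iterable[CallEvent], path: Union[str, Path]) -> None:
    """Write call annotations as CSV (onset_s, offset_s, caller)."""
    df = pd.DataFrame(
        [(e.onset_s, e.offset_s, e.caller) for e in events],
        columns=["onset_s", "offset_s", "caller"],
    )
    df.to_csv(path, index=False)


def load_sync_markers(path: Union[str, Path]) -> list[SyncMarker]:
    """Read sync markers from CSV (audio_time_s, video_frame)."""
    df = pd.read_csv(path)
    return [
        SyncMarker(audio_time_s=float(r.audio_time_s), video_frame=int(r.video_frame))
        for r in df.itertuples()
    ]


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
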