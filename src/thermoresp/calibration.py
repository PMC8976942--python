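"""Radiometric conversion between raw thermal-sensor counts and temperature.

Long-wave infrared cameras record raw sensor counts that relate to object
temperature through a camera-specific Planck calibration plus corrections
for surface emissivity, reflected background radiation and atmospheric
attenuation along the viewing path.  This module implements the standard
FLIR-style conversion chain: a water-vapour-dependent atmospheric
transmittance model, the Planck inversion itself, its exact algebraic
inverse (used by the simulator), and median-intensity extraction from a
rectangular region of interest (ROI) over a nostril.

Temperatures are degrees Celsius throughout; raw counts are dimensionless
sensor units (typically 16-bit).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

import numpy as np
import yaml

__all__ = [
    "CalibrationConstants",
    "RoiSpec",
    "atmospheric_transmittance",
    "raw_to_temperature",
    "temperature_to_raw",
    "extract_roi_median",
    "load_calibration",
    "load_frame_stack",
    "write_frame_stack",
    "temperatures_from_stack",
]

_KELVIN = 273.15


@dataclass(frozen=True)
class CalibrationConstants:
    """Camera Planck coefficients plus scene/atmosphere parameters.

    The Planck scalars (``planck_R1``, ``planck_R2``, ``planck_B``,
    ``planck_O``, ``planck_F``) are unique to each camera and normally read
    from the radiometric file metadata.  The atmospheric coefficients
    (``atm_alpha*``, ``atm_beta*``, ``atm_X``) parameterise water-vapour
    attenuation and default to the standard values used by open FLIR
    conversion tooling.  Scene parameters (emissivity, reflected and
    atmospheric temperature, relative humidity, object distance) are
    recorded per session; one instance per recording session is applied to
    all frames of that session.
    """

    planck_R1: float = 21106.77
    planck_R2: float = 0.012545258
    planck_B: float = 1501.0
    planck_O: float = -7340.0
    planck_F: float = 1.0
    atm_alpha1: float = 0.006569
    atm_alpha2: float = 0.01262
    atm_beta1: float = -0.002276
    atm_beta2: float = -0.00667
    atm_X: float = 1.9
    emissivity: float = 0.95
    reflected_temp_C: float = 20.0
    atm_temp_C: float = 20.0
    rel_humidity: float = 0.5
    object_distance_m: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.emissivity <= 1.0):
            raise ValueError(f"emissivity must be in (0, 1], got {self.emissivity}")
        for name in ("planck_R1", "planck_R2", "planck_B"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not (0.0 <= self.rel_humidity <= 1.0):
            raise ValueError(
                f"rel_humidity must be a fraction in [0, 1], got {self.rel_humidity}"
            )
        if self.object_distance_m < 0:
            raise ValueError(
                f"object_distance_m must be >= 0, got {self.object_distance_m}"
            )


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular ROI: integer center, 0-based pixel coordinates.

    Width runs along x (columns), height along y (rows).  For even sizes the
    extra pixel is placed on the high-coordinate side of the center (right /
    below).  Edges are clipped to frame bounds.
    """

    center_x: int
    center_y: int
    width_px: int = 10
    height_px: int = 5

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("ROI width_px and height_px must be >= 1")

    def bounds(self, frame_shape: tuple[int, int]) -> tuple[int, int, int, int]:
        """Clipped (y0, y1, x0, x1) half-open bounds inside ``frame_shape``."""
        h, w = frame_shape
        x0 = self.center_x - (self.width_px - 1) // 2
        y0 = self.center_y - (self.height_px - 1) // 2
        x1 = x0 + self.width_px
        y1 = y0 + self.height_px
        x0c, x1c = max(x0, 0), min(x1, w)
        y0c, y1c = max(y0, 0), min(y1, h)
        return y0c, y1c, x0c, x1c


def _saturated_vapour_density(temp_C: float) -> float:
    # Empirical water-vapour content term from the published FLIR
    # atmospheric model (g/m^3 at 100% RH).
    return np.exp(
        1.5587
        + 0.06939 * temp_C
        - 0.00027816 * temp_C**2
        + 0.00000068455 * temp_C**3
    )


def atmospheric_transmittance(calib: CalibrationConstants) -> float:
    """Atmospheric transmittance tau in (0, 1] along the viewing path.

    Uses the published FLIR water-vapour attenuation formula::

        h2o = RH * exp(1.5587 + 0.06939 T - 0.00027816 T^2 + 6.8455e-7 T^3)
        tau = X exp(-sqrt(d) (a1 + b1 sqrt(h2o)))
              + (1 - X) exp(-sqrt(d) (a2 + b2 sqrt(h2o)))

    with T the atmospheric temperature (degC), RH the relative-humidity
    fraction and d the object distance in metres.  tau equals 1 at zero
    distance and decreases with path length under the default coefficients.
    """
    h2o = calib.rel_humidity * _saturated_vapour_density(calib.atm_temp_C)
    sqrt_d = np.sqrt(calib.object_distance_m)
    sqrt_h2o = np.sqrt(h2o)
    tau = calib.atm_X * np.exp(
        -sqrt_d * (calib.atm_alpha1 + calib.atm_beta1 * sqrt_h2o)
    ) + (1.0 - calib.atm_X) * np.exp(
        -sqrt_d * (calib.atm_alpha2 + calib.atm_beta2 * sqrt_h2o)
    )
    tau = float(tau)
    if not (0.0 < tau <= 1.0 + 1e-12):
        raise ValueError(
            f"computed transmittance {tau:.6f} outside (0, 1]; "
            "check atmospheric coefficients and scene parameters"
        )
    return min(tau, 1.0)


def _planck_raw(temp_C: Union[float, np.ndarray], calib: CalibrationConstants):
    """Idealised raw counts of a blackbody at ``temp_C`` (bare Planck)."""
    t_K = np.asarray(temp_C, dtype=float) + _KELVIN
    if np.any(t_K <= 0):
        raise ValueError("temperature below absolute zero")
    return calib.planck_R1 / (
        calib.planck_R2 * (np.exp(calib.planck_B / t_K) - calib.planck_F)
    ) - calib.planck_O


def raw_to_temperature(
    raw_counts: Union[float, np.ndarray],
    calib: CalibrationConstants,
    frame: int | None = None,
) -> Union[float, np.ndarray]:
    """Convert raw sensor counts to object temperature in degC.

    Removes the reflected-background and atmospheric-path contributions
    from the measured signal, scales by emissivity and transmittance, and
    inverts the camera's Planck calibration:

        raw_obj = raw/(e*tau) - (1-e)/e * raw_refl - (1-tau)/(e*tau) * raw_atm
        T = B / ln(R1 / (R2 (raw_obj + O)) + F) - 273.15

    With emissivity = 1 and tau = 1 this reduces to the bare Planck
    inversion.  Raises a domain error (naming ``frame`` if given) when the
    corrected radiance is physically impossible.
    """
    raw = np.asarray(raw_counts, dtype=float)
    e = calib.emissivity
    tau = atmospheric_transmittance(calib)
    raw_refl = _planck_raw(calib.reflected_temp_C, calib)
    raw_atm = _planck_raw(calib.atm_temp_C, calib)
    raw_obj = (
        raw / (e * tau)
        - (1.0 - e) / e * raw_refl
        - (1.0 - tau) / (e * tau) * raw_atm
    )
    log_arg = calib.planck_R1 / (calib.planck_R2 * (raw_obj + calib.planck_O)) + calib.planck_F
    if np.any(~np.isfinite(log_arg)) or np.any(log_arg <= 1.0):
        where = f" at frame {frame}" if frame is not None else ""
        raise ValueError(
            f"non-physical radiance{where}: corrected raw signal yields "
            "non-positive logarithm argument in the Planck inversion"
        )
    temp = calib.planck_B / np.log(log_arg) - _KELVIN
    return float(temp) if np.isscalar(raw_counts) else temp


def temperature_to_raw(
    temp_C: Union[float, np.ndarray], calib: CalibrationConstants
) -> Union[float, np.ndarray]:
    """Exact algebraic inverse of :func:`raw_to_temperature`.

    Forward-models the raw sensor signal produced by an object at
    ``temp_C`` under the calibration's emissivity, reflected temperature
    and atmospheric path.  Strictly increasing in temperature.
    """
    e = calib.emissivity
    tau = atmospheric_transmittance(calib)
    raw_obj = _planck_raw(temp_C, calib)
    raw_refl = _planck_raw(calib.reflected_temp_C, calib)
    raw_atm = _planck_raw(calib.atm_temp_C, calib)
    raw = e * tau * raw_obj + tau * (1.0 - e) * raw_refl + (1.0 - tau) * raw_atm
    return float(raw) if np.isscalar(temp_C) else raw


def extract_roi_median(
    frame: np.ndarray, roi: RoiSpec, frame_index: int | None = None
) -> float:
    """Median pixel intensity inside the ROI rectangle, clipped to bounds.

    Raises if the clipped ROI is empty (entirely outside the frame).
    """
    arr = np.asarray(frame)
    if arr.ndim != 2:
        raise ValueError(f"frame must be 2-D, got shape {arr.shape}")
    y0, y1, x0, x1 = roi.bounds(arr.shape)
    if y0 >= y1 or x0 >= x1:
        where = f" (frame {frame_index})" if frame_index is not None else ""
        raise ValueError(
            f"ROI centered at ({roi.center_x}, {roi.center_y}) lies entirely "
            f"outside frame of shape {arr.shape}{where}"
        )
    return float(np.median(arr[y0:y1, x0:x1]))


def load_frame_stack(directory: Union[str, Path],
                     pattern: str = "*") -> tuple[np.ndarray, list[int]]:
    """Read a numbered greyscale frame sequence (TIFF/PNG) from a directory.

    The frame index is parsed as the last run of digits in each filename;
    frames are returned sorted by index as a (n, h, w) array together with
    the index list.  16-bit integer and float frames are both accepted.
    """
    import re

    import imageio.v3 as iio

    directory = Path(directory)
    found: list[tuple[int, Path]] = []
    for p in sorted(directory.glob(pattern)):
        if p.suffix.lower() not in (".tif", ".tiff", ".png"):
            continue
        digits = re.findall(r"\d+", p.stem)
        if not digits:
            raise ValueError(f"cannot parse frame index from {p.name}")
        found.append((int(digits[-1]), p))
    if not found:
        raise FileNotFoundError(f"no TIFF/PNG frames in {directory}")
    found.sort()
    frames = np.stack([np.asarray(iio.imread(p)) for _, p in found])
    if frames.ndim != 3:
        raise ValueError("frames must be single-channel greyscale")
    return frames, [i for i, _ in found]


def write_frame_stack(stack: np.ndarray, directory: Union[str, Path],
                      indices: list[int] | None = None,
                      prefix: str = "frame") -> list[Path]:
    """Write frames as numbered TIFFs (inverse of :func:`load_frame_stack`).

    Float stacks are written as 32-bit float TIFF to preserve the exact
    raw counts; integer stacks as 16-bit greyscale.
    """
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    indices = indices if indices is not None else list(range(len(stack)))
    paths = []
    for i, frame in zip(indices, stack):
        arr = (frame.astype(np.float32) if np.issubdtype(frame.dtype, np.floating)
               else frame.astype(np.uint16))
        p = directory / f"{prefix}_{i:06d}.tif"
        tifffile.imwrite(p, arr)
        paths.append(p)
    return paths


def temperatures_from_stack(
    stack: np.ndarray,
    indices: list[int],
    detections,
    calib: CalibrationConstants,
    roi_width_px: int = 10,
    roi_height_px: int = 5,
):
    """Per-frame nostril temperatures from a raw frame stack.

    For each detection row (columns frame, side, x, y) the median raw
    intensity of the ROI centred on the detected nostril is extracted and
    converted radiometrically.  Returns a DataFrame with columns frame,
    side, median_intensity, temperature_C — the table the trace-assembly
    stage consumes.
    """
    import pandas as pd

    by_index = {idx: stack[i] for i, idx in enumerate(indices)}
    rows = []
    for r in detections.itertuples():
        frame = by_index.get(int(r.frame))
        if frame is None:
            continue
        roi = RoiSpec(center_x=int(round(r.x)), center_y=int(round(r.y)),
                      width_px=roi_width_px, height_px=roi_height_px)
        med = extract_roi_median(frame, roi, frame_index=int(r.frame))
        rows.append({
            "frame": int(r.frame), "side": r.side, "median_intensity": med,
            "temperature_C": raw_to_temperature(med, calib, frame=int(r.frame)),
        })
    return pd.DataFrame(rows)


def load_calibration(path: Union[str, Path]) -> CalibrationConstants:
    """Read session calibration constants from a YAML config file.

    Keys are the :class:`CalibrationConstants` field names; missing keys
    fall back to defaults, unknown keys are rejected.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    valid = set(CalibrationConstants.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown calibration keys in {path}: {sorted(unknown)}")
    return CalibrationConstants(**data)


def save_calibration(calib: CalibrationConstants, path: Union[str, Path]) -> None:
    """Write calibration constants as YAML (inverse of :func:`load_calibration`)."""
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(calib), fh, sort_keys=False)
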