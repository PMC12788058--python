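"""Synthetic six-channel SPR image stacks for end-to-end testing.

The generator renders time-ordered, per-LED 2-D intensity frames of a flow
cell whose channels (rectangular ROIs) follow prescribed refractive-index
time courses — NaCl staircases or 1:1 Langmuir binding — through the full
multilayer forward model. Tracking and calibration code can therefore be
exercised closed-loop against a known ground truth with no instrument and no
external data.

Conventions: 16-bit unsigned frames with full scale = reflectance 1.0,
round-half-even quantization, additive Gaussian pixel noise, everything
deterministic under the scenario seed. Background (non-channel) pixels carry
a fixed non-resonant reflectance level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import tifffile
import yaml

from .acquisition import LedBank, default_led_bank
from .optics import LayerStack, rp_multilayer

__all__ = [
    "RoiMap",
    "Staircase",
    "LangmuirBinding",
    "ScenarioSpec",
    "FrameStack",
    "ScenarioError",
    "langmuir_delta_ri",
    "course_delta_ri",
    "render_frames",
    "extract_roi_series",
    "six_channel_roi_map",
    "DEFAULT_PIXEL_NOISE_SD",
]

#: Default per-pixel additive noise (fraction of full scale). Calibrated so
#: that ROI-averaged tracking of a quiet Band-1 water baseline (the 10-min
#: pure-water baseline protocol, ~160-pixel channel ROI) lands at the
#: 0.014 nm RW noise floor of a well-behaved bench system; Band-3 baselines
#: track ~4x quieter because the wider LED spacing stiffens the parabola
#: vertex (see docs/methods.md for the calibration).
DEFAULT_PIXEL_NOISE_SD = 0.00067


class ScenarioError(ValueError):
    """Inconsistent synthetic scenario."""


@dataclass(frozen=True)
class RoiMap:
    """Named rectangles (x0, y0, x1, y1), 0-based half-open, on a H x W grid."""

    shape: tuple  # (H, W)
    rois: dict  # name -> (x0, y0, x1, y1)

    def __post_init__(self) -> None:
        h, w = self.shape
        boxes = list(self.rois.items())
        for name, (x0, y0, x1, y1) in boxes:
            if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                raise ScenarioError(f"ROI '{name}' out of bounds for {h}x{w}")
        for i, (na, a) in enumerate(boxes):
            for nb, b in boxes[i + 1 :]:
                if a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]:
                    raise ScenarioError(f"ROIs '{na}' and '{nb}' overlap")

    def slices(self, name: str) -> tuple:
        x0, y0, x1, y1 = self.rois[name]
        return slice(y0, y1), slice(x0, x1)


def six_channel_roi_map(shape: tuple = (48, 64)) -> RoiMap:
    """Six parallel vertical channels, mimicking the 1 mm x 10 mm flow cell."""
    h, w = shape
    gap = w // 13  # channel width == gap width
    rois = {}
    for i in range(6):
        x0 = gap + i * 2 * gap
        rois[f"ch{i + 1}"] = (x0, h // 12, x0 + gap, h - h // 12)
    return RoiMap(shape, rois)


@dataclass(frozen=True)
class Staircase:
    """Piecewise-constant RI offsets: level k holds for dwell_s seconds."""

    levels: tuple  # RIU offsets over the base index
    dwell_s: float

    def __post_init__(self) -> None:
        if len(self.levels) == 0 or self.dwell_s <= 0:
            raise ScenarioError("staircase needs levels and a positive dwell")
        object.__setattr__(self, "levels", tuple(float(v) for v in self.levels))


@dataclass(frozen=True)
class LangmuirBinding:
    """1:1 binding kinetics expressed as an RI offset time course.

    Association from ``t_on_s`` at analyte concentration ``conc_m`` (M) with
    rate constants ``kon`` (1/(M s)) and ``koff`` (1/s) toward the saturation
    response ``rmax_riu``; exponential dissociation at ``koff`` after
    ``t_off_s`` (the buffer rinse).
    """

    kon: float
    koff: float
    conc_m: float
    rmax_riu: float
    t_on_s: float
    t_off_s: float

    def __post_init__(self) -> None:
        if min(self.kon, self.koff, self.conc_m, self.rmax_riu) < 0:
            raise ScenarioError("rates, concentration and rmax must be >= 0")
        if self.t_off_s < self.t_on_s:
            raise ScenarioError("t_off_s must be >= t_on_s")
        if self.kon == 0 and self.conc_m > 0:
            raise ScenarioError("degenerate kinetics: kon = 0 with conc > 0")


def langmuir_delta_ri(t, spec: LangmuirBinding):
    """RI offset of the 1:1 Langmuir model at time(s) *t* (seconds).

    Association: ``dn(t) = rmax C/(C+KD) (1 - exp(-(kon C + koff)(t-t_on)))``
    with ``KD = koff/kon``; dissociation after ``t_off`` decays at ``koff``,
    continuous at the switch.
    """
    t = np.asarray(t, dtype=float)
    k_obs = spec.kon * spec.conc_m + spec.koff
    if spec.koff == 0:
        plateau = spec.rmax_riu if spec.conc_m > 0 else 0.0
    else:
        kd = spec.koff / spec.kon if spec.kon > 0 else math.inf
        plateau = spec.rmax_riu * spec.conc_m / (spec.conc_m + kd)
    assoc = plateau * (1.0 - np.exp(-k_obs * np.clip(t - spec.t_on_s, 0, None)))
    at_off = plateau * (1.0 - math.exp(-k_obs * (spec.t_off_s - spec.t_on_s)))
    dissoc = at_off * np.exp(-spec.koff * np.clip(t - spec.t_off_s, 0, None))
    out = np.where(t < spec.t_on_s, 0.0, np.where(t <= spec.t_off_s, assoc, dissoc))
    return out[()] if out.ndim == 0 else out


Course = Union[Staircase, LangmuirBinding]


def course_delta_ri(course: Course, t):
    """RI offset of any course type at time(s) *t*."""
    if isinstance(course, LangmuirBinding):
        return langmuir_delta_ri(t, course)
    t = np.asarray(t, dtype=float)
    idx = np.minimum((t // course.dwell_s).astype(int), len(course.levels) - 1)
    out = np.asarray(course.levels)[idx]
    return out[()] if out.ndim == 0 else out


@dataclass(frozen=True)
class ScenarioSpec:
    """A complete synthetic experiment: per-ROI RI courses, timing and noise."""

    courses: dict  # roi name -> Course
    base_ri: float = 1.333
    frame_period_s: float = 5.0
    duration_s: float = 300.0
    noise_sd: float = DEFAULT_PIXEL_NOISE_SD
    background_level: float = 0.85
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_period_s <= 0 or self.duration_s <= 0:
            raise ScenarioError("frame period and duration must be positive")
        if self.noise_sd < 0:
            raise ScenarioError("noise_sd must be >= 0")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(0.0, self.duration_s + 1e-9, self.frame_period_s)


@dataclass
class FrameStack:
    """Per-LED 2-D frames over time: uint array (T, L, H, W) plus metadata."""

    data: np.ndarray
    times_s: np.ndarray
    led_centers_nm: np.ndarray
    bit_depth: int = 16
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)

    @property
    def full_scale(self) -> int:
        return (1 << self.bit_depth) - 1

    def save(self, directory) -> None:
        """Write one multi-page TIFF per LED plus a YAML metadata sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for li, center in enumerate(self.led_centers_nm):
            tifffile.imwrite(
                directory / f"led{li + 1}_{center:.0f}nm.tif",
                self.data[:, li],
                photometric="minisblack",
            )
        meta = dict(self.meta)
        meta.update(
            times_s=[float(t) for t in self.times_s],
            led_centers_nm=[float(c) for c in self.led_centers_nm],
            bit_depth=int(self.bit_depth),
            seed=None if self.seed is None else int(self.seed),
        )
        (directory / "metadata.yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def load(cls, directory) -> "FrameStack":
        directory = Path(directory)
        meta = yaml.safe_load((directory / "metadata.yaml").read_text())
        centers = meta["led_centers_nm"]
        planes = [
            tifffile.imread(directory / f"led{li + 1}_{c:.0f}nm.tif")
            for li, c in enumerate(centers)
        ]
        data = np.stack(planes, axis=1)
        return cls(
            data=data,
            times_s=np.asarray(meta["times_s"], dtype=float),
            led_centers_nm=np.asarray(centers, dtype=float),
            bit_depth=meta.get("bit_depth", 16),
            seed=meta.get("seed"),
            meta=meta,
        )


def render_frames(
    scenario: ScenarioSpec,
    stack: LayerStack,
    leds: Optional[LedBank] = None,
    roi_map: Optional[RoiMap] = None,
    angle_deg: Optional[float] = None,
) -> FrameStack:
    """Render the scenario through the multilayer forward model.

    Every ROI pixel at time t under LED l carries the reflectance of the
    sensor stack with that ROI's instantaneous analyte index, scaled to the
    bit depth; background pixels carry the fixed non-resonant level. Additive
    Gaussian noise (sd ``scenario.noise_sd`` in reflectance units) is applied
    per pixel, then round-half-even quantization. Bit-identical under the
    scenario seed.
    """
    leds = leds or default_led_bank()
    roi_map = roi_map or six_channel_roi_map()
    missing = set(scenario.courses) - set(roi_map.rois)
    if missing:
        raise ScenarioError(f"courses reference unknown ROIs: {sorted(missing)}")
    centers = leds.centers_nm
    times = scenario.times_s
    h, w = roi_map.shape
    signal = np.full(
        (times.size, centers.size, h, w), scenario.background_level, dtype=float
    )
    for name, course in scenario.courses.items():
        ys, xs = roi_map.slices(name)
        dn = np.asarray(course_delta_ri(course, times), dtype=float)
        for ti in range(times.size):
            s = stack.with_analyte_index(scenario.base_ri + dn[ti])
            rp = rp_multilayer(s, centers, angle_deg)
            for li in range(centers.size):
                signal[ti, li, ys, xs] = rp[li]
    rng = np.random.default_rng(scenario.seed)
    if scenario.noise_sd > 0:
        signal = signal + rng.normal(0.0, scenario.noise_sd, size=signal.shape)
    full = (1 << scenario.bit_depth) - 1
    data = np.clip(np.rint(signal * full), 0, full).astype(
        np.uint16 if scenario.bit_depth <= 16 else np.uint32
    )
    meta = {
        "rois": {k: list(map(int, v)) for k, v in roi_map.rois.items()},
        "shape": [int(h), int(w)],
        "base_ri": float(scenario.base_ri),
        "background_level": float(scenario.background_level),
        "noise_sd": float(scenario.noise_sd),
    }
    return FrameStack(
        data=data,
        times_s=times,
        led_centers_nm=centers,
        bit_depth=scenario.bit_depth,
        seed=scenario.seed,
        meta=meta,
    )


def extract_roi_series(
    frames: FrameStack,
    roi_map: RoiMap,
    flatfield_gains=None,
) -> Dict[str, np.ndarray]:
    """Mean ROI intensity per (time, LED), normalized to full scale.

    Returns ``roi name -> (T, L)`` float arrays in [0, 1]. Optional
    *flatfield_gains* (one per LED) divide each LED's series, cancelling
    unequal LED powers when the frames were not recorded at equal power.
    """
    t, l, h, w = frames.data.shape
    if (h, w) != tuple(roi_map.shape):
        raise ScenarioError("ROI map shape does not match the frames")
    gains = None
    if flatfield_gains is not None:
        gains = np.asarray(flatfield_gains, dtype=float)
        if gains.shape != (l,) or np.any(gains <= 0):
            raise ScenarioError("flatfield_gains must be L positive values")
    out = {}
    for name in roi_map.rois:
        ys, xs = roi_map.slices(name)
        if frames.data[0, 0, ys, xs].size == 0:
            raise ScenarioError(f"ROI '{name}' is empty")
        series = frames.data[:, :, ys, xs].mean(axis=(2, 3)) / frames.full_scale
        out[name] = series / gains if gains is not None else series
    return out
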