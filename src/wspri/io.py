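"""Structured-text configuration loading and table round-tripping.

All configs are YAML; dispersion tables are 3-column delimited text;
sensorgrams and sweep tables are tab-separated values with a header row.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Tuple

import pandas as pd
import yaml

from .acquisition import LedBank, LedChannel, TimingModel
from .dispersion import (
    Constant,
    DispersionModel,
    DrudeLorentz,
    LorentzOscillator,
    load_nk_table,
    packaged_table,
)
from .optics import SEMI_INFINITE, LayerStack, OpticalLayer
from .synth import LangmuirBinding, RoiMap, ScenarioSpec, Staircase

__all__ = [
    "ConfigError",
    "load_dispersion",
    "load_stack",
    "load_acquisition",
    "load_scenario",
    "load_roi_map",
    "write_sensorgram",
    "read_sensorgram",
]


class ConfigError(ValueError):
    """Malformed configuration file."""


def load_dispersion(spec: dict, base_dir: Optional[Path] = None) -> DispersionModel:
    """Build a dispersion model from its config mapping.

    ``variant`` selects the model: ``constant`` (n, k), ``tabulated``
    (``table``: packaged table name or a path to a 3-column text file,
    resolved relative to *base_dir*), or ``drude_lorentz``.
    """
    try:
        variant = spec["variant"]
    except (TypeError, KeyError):
        raise ConfigError(f"dispersion spec needs a 'variant': {spec!r}")
    if variant == "constant":
        return Constant(float(spec["n"]), float(spec.get("k", 0.0)))
    if variant == "tabulated":
        ref = str(spec["table"])
        candidate = (base_dir / ref) if base_dir is not None else Path(ref)
        if candidate.is_file():
            return load_nk_table(candidate)
        if Path(ref).is_file():
            return load_nk_table(ref)
        return packaged_table(ref)
    if variant == "drude_lorentz":
        oscs = tuple(
            LorentzOscillator(float(o["f"]), float(o["energy_ev"]), float(o["gamma_ev"]))
            for o in spec.get("oscillators", [])
        )
        return DrudeLorentz(
            float(spec["eps_inf"]),
            float(spec["plasma_energy_ev"]),
            float(spec["damping_ev"]),
            oscs,
        )
    raise ConfigError(f"unknown dispersion variant '{variant}'")


def load_stack(path) -> LayerStack:
    """Read a layer-stack YAML config (see README for the schema)."""
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    try:
        layers = []
        for entry in cfg["layers"]:
            thickness = entry.get("thickness_nm")
            layers.append(
                OpticalLayer(
                    name=str(entry["name"]),
                    thickness_nm=SEMI_INFINITE if thickness is None else float(thickness),
                    dispersion=load_dispersion(entry["dispersion"], path.parent),
                )
            )
        return LayerStack(tuple(layers), float(cfg["incident_angle_deg"]))
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"{path}: invalid stack config ({exc})") from exc


def load_acquisition(path) -> Tuple[LedBank, TimingModel]:
    """Read LED centers, optional FWHM and timing constants."""
    cfg = yaml.safe_load(Path(path).read_text())
    centers = cfg.get("led_centers_nm", [730, 740, 756, 777, 805])
    fwhm = cfg.get("fwhm_nm")
    response = float(cfg.get("led_response_ms", 2.0))
    bank = LedBank(
        tuple(
            LedChannel(i + 1, float(c), None if fwhm is None else float(fwhm), response)
            for i, c in enumerate(centers)
        )
    )
    timing = TimingModel(response, float(cfg.get("exposure_ms", 33.0)))
    return bank, timing


def _load_course(spec: dict):
    kind = spec.get("kind")
    if kind == "staircase":
        return Staircase(tuple(spec["levels"]), float(spec["dwell_s"]))
    if kind == "langmuir":
        return LangmuirBinding(
            kon=float(spec["kon"]),
            koff=float(spec["koff"]),
            conc_m=float(spec["conc_m"]),
            rmax_riu=float(spec["rmax_riu"]),
            t_on_s=float(spec["t_on_s"]),
            t_off_s=float(spec["t_off_s"]),
        )
    raise ConfigError(f"unknown course kind '{kind}'")


def load_scenario(path) -> Tuple[ScenarioSpec, RoiMap]:
    """Read a synthetic-imaging scenario: ROI layout plus RI time courses."""
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    try:
        shape = tuple(int(v) for v in cfg.get("shape", (48, 64)))
        rois, courses = {}, {}
        for name, entry in cfg["rois"].items():
            rois[name] = tuple(int(v) for v in entry["rect"])
            if "course" in entry:
                courses[name] = _load_course(entry["course"])
            else:  # ROI with no course: flat baseline
                courses[name] = Staircase((0.0,), 1.0)
        roi_map = RoiMap(shape, rois)
        scenario = ScenarioSpec(
            courses=courses,
            base_ri=float(cfg.get("base_ri", 1.333)),
            frame_period_s=float(cfg.get("frame_period_s", 5.0)),
            duration_s=float(cfg.get("duration_s", 300.0)),
            noise_sd=float(cfg.get("noise_sd", ScenarioSpec.noise_sd)),
            background_level=float(cfg.get("background_level", 0.85)),
            bit_depth=int(cfg.get("bit_depth", 16)),
            seed=int(cfg.get("seed", 0)),
        )
        return scenario, roi_map
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"{path}: invalid scenario config ({exc})") from exc


def load_roi_map(path) -> RoiMap:
    """Read a standalone ROI-map YAML (shape + name -> rect)."""
    cfg = yaml.safe_load(Path(path).read_text())
    try:
        shape = tuple(int(v) for v in cfg["shape"])
        rois = {
            name: tuple(int(v) for v in rect) for name, rect in cfg["rois"].items()
        }
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"{path}: invalid ROI map ({exc})") from exc
    return RoiMap(shape, rois)


def write_sensorgram(sensorgram: pd.DataFrame, path) -> None:
    sensorgram.to_csv(path, sep="\t", index=False)


def read_sensorgram(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
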