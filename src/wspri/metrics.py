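"""Calibration and figure-of-merit analytics for RW sensorgrams.

Sensitivity is the slope S of the linear calibration of resonance-wavelength
response against refractive index (nm/RIU) or analyte concentration. From it
follow the standard biosensor figures of merit:

* refractive-index resolution  sigma_RI = RMS_noise / S  (RIU),
* limit of detection           LOD = 3 * sd_blank / S    (concentration),
* dynamic range                the analyte-RI span over which the tracker
  still follows the dip within a stated wavelength tolerance.

Sensorgrams are tidy DataFrames (``time_s, roi_id, rw_nm, band_id, clamped``)
as produced by :func:`wspri.asf.asf_track`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .acquisition import LedBank, SampledPoints, default_led_bank, bands_from_leds
from .asf import AsfState, asf_converge, fullscan_init
from .optics import BoundaryMinimumError, LayerStack, rp_multilayer, true_rw

__all__ = [
    "CalibrationCurve",
    "NoiseStats",
    "BlankStats",
    "CalibrationError",
    "linear_calibration",
    "rir",
    "lod",
    "nacl_to_delta_ri",
    "baseline_rms",
    "net_shift",
    "dynamic_range",
    "NACL_RIU_PER_PERCENT",
]

#: Linear NaCl concentration -> refractive-index coefficient (RIU per % w/v),
#: anchored to the 13% <-> 0.0241 RIU endpoint of the dynamic-range protocol.
NACL_RIU_PER_PERCENT = 0.0241 / 13.0


class CalibrationError(ValueError):
    """Degenerate or invalid calibration input."""


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line y = slope*x + intercept with squared Pearson correlation."""

    slope: float
    intercept: float
    r_squared: float
    x: np.ndarray
    y: np.ndarray

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass(frozen=True)
class NoiseStats:
    """Baseline noise: RMS about the window mean, in nm."""

    rms_nm: float
    window_s: tuple
    n_samples: int


@dataclass(frozen=True)
class BlankStats:
    """Standard deviation of the blank/control channel response."""

    sd: float


def linear_calibration(x, y=None) -> CalibrationCurve:
    """Ordinary least-squares calibration line.

    Accepts either two sequences ``(x, y)`` or one sequence of ``(x, y)``
    pairs. Requires at least two distinct x values.
    """
    if y is None:
        pairs = np.asarray(x, dtype=float)
        x, y = pairs[:, 0], pairs[:, 1]
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise CalibrationError("calibration needs >= 2 distinct x values")
    res = stats.linregress(x, y)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        x=x,
        y=y,
    )


def rir(curve: CalibrationCurve, noise: NoiseStats) -> float:
    """Refractive-index resolution: baseline RMS divided by sensitivity.

    ``sigma_RI = (sigma_n / sigma_s) * RMS`` with ``sigma_n/sigma_s`` the
    reciprocal calibration slope (RIU per nm), so the result is in RIU when
    the calibration x-axis is refractive index.
    """
    if curve.slope <= 0:
        raise CalibrationError("rir needs a positive calibration slope")
    if noise.rms_nm < 0:
        raise CalibrationError("noise RMS must be >= 0")
    return noise.rms_nm / curve.slope


def lod(blank: BlankStats, curve: CalibrationCurve) -> float:
    """Limit of detection: 3 x blank standard deviation over the slope."""
    if curve.slope <= 0:
        raise CalibrationError("lod needs a positive calibration slope")
    if blank.sd < 0:
        raise CalibrationError("blank sd must be >= 0")
    return 3.0 * blank.sd / curve.slope


def nacl_to_delta_ri(percent_w_v: float) -> float:
    """Refractive-index increment of aqueous NaCl over pure water.

    Linear conversion anchored at 13% w/v <-> 0.0241 RIU; outside the
    validated 0-13% range the linear extrapolation is returned with a
    warning.
    """
    if not 0.0 <= percent_w_v <= 13.0:
        warnings.warn(
            f"NaCl concentration {percent_w_v}% outside the validated 0-13% "
            "range; extrapolating the linear coefficient",
            stacklevel=2,
        )
    return percent_w_v * NACL_RIU_PER_PERCENT


def _roi_window(
    sensorgram: pd.DataFrame, roi: str, window_s: tuple
) -> np.ndarray:
    df = sensorgram[sensorgram["roi_id"] == roi]
    lo, hi = window_s
    sel = df[(df["time_s"] >= lo) & (df["time_s"] <= hi)]["rw_nm"].to_numpy()
    return sel[np.isfinite(sel)]


def baseline_rms(
    sensorgram: pd.DataFrame, roi: str, window_s: tuple
) -> NoiseStats:
    """RMS of the RW about its mean over a quiet baseline window."""
    vals = _roi_window(sensorgram, roi, window_s)
    if vals.size < 10:
        raise CalibrationError("baseline window must contain >= 10 samples")
    rms = float(np.sqrt(np.mean((vals - vals.mean()) ** 2)))
    return NoiseStats(rms_nm=rms, window_s=tuple(window_s), n_samples=vals.size)


def net_shift(
    sensorgram: pd.DataFrame, roi: str, pre_window_s: tuple, post_window_s: tuple
) -> float:
    """Net RW shift: mean over the post-reaction window minus the pre one."""
    pre = _roi_window(sensorgram, roi, pre_window_s)
    post = _roi_window(sensorgram, roi, post_window_s)
    if pre.size == 0 or post.size == 0:
        raise CalibrationError("both windows must lie inside the trace")
    return float(post.mean() - pre.mean())


def dynamic_range(
    stack: LayerStack,
    angle_deg: Optional[float] = None,
    leds: Optional[LedBank] = None,
    tolerance_nm: float = 0.5,
    ri_bounds: tuple = (1.315, 1.345),
    ri_step: float = 5e-4,
) -> float:
    """Analyte-RI span over which noise-free ASF tracking stays accurate.

    Scans the analyte refractive index across *ri_bounds*; at each RI the
    true RW comes from a dense-grid search over a window generously wider
    than the LED span, and the ASF estimate from a noise-free five-point
    initialization plus convergence. The dynamic range is the width (RIU) of
    the widest contiguous RI interval with ``|ASF - true| <= tolerance_nm``;
    RIs whose dip lies outside the LED span fail automatically.

    The default 0.5 nm tolerance is strict relative to the tracker's
    intrinsic fit bias on a realistic multilayer dip (a few nm, see the
    package docs); pass the accuracy envelope you are willing to accept.
    """
    leds = leds or default_led_bank()
    bands = bands_from_leds(leds)
    centers = leds.centers_nm
    span = (centers[0], centers[-1])
    wide = (max(span[0] - 60.0, 1.0), span[1] + 90.0)
    ris = np.arange(ri_bounds[0], ri_bounds[1] + 0.5 * ri_step, ri_step)
    ok = np.zeros(ris.size, dtype=bool)
    for i, ri in enumerate(ris):
        s = stack.with_analyte_index(float(ri))
        try:
            truth = true_rw(s, angle_deg, search_range_nm=wide, grid_step_nm=0.02)
        except BoundaryMinimumError:
            continue
        if not (span[0] < truth < span[1]):
            continue
        intens = rp_multilayer(s, centers, angle_deg)
        init = fullscan_init(SampledPoints(centers, intens), bands)

        def sampler(led_ids, _s=s):
            idx = [j - 1 for j in led_ids]
            return SampledPoints(
                centers[idx], rp_multilayer(_s, centers[idx], angle_deg)
            )

        est, _ = asf_converge(AsfState(init.band_id), sampler, bands)
        ok[i] = abs(est.rw_nm - truth) <= tolerance_nm
    # widest contiguous accurate stretch
    best = current = 0
    for flag in ok:
        current = current + 1 if flag else 0
        best = max(best, current)
    return float(max(best - 1, 0) * ri_step)
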