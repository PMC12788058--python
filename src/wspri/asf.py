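"""Adaptive second-order fitting (ASF): sparse resonance-wavelength tracking.

The tracker reconstructs the SPR resonance wavelength (RW) from a handful of
LED samples instead of a full spectral scan:

1. *Initialization* — all five LEDs are sampled once and an exact
   fourth-order interpolant through the five points gives a coarse starting
   RW, which selects the active three-LED band.
2. *Tracking* — each cycle samples only the active band's three LEDs and
   fits the exact parabola through them. If the parabola vertex (for an
   upward-opening fit) lies inside the band's fit range it is the RW
   estimate; otherwise the estimate clamps to the fit-range endpoint with
   the lower fitted intensity — the direction the dip moved.
3. *Band switching* — the estimate re-selects the active band (thresholds at
   740 and 756 nm by default, mirrored for blue-shifts), so a dip that left
   the band is chased across bands in at most two hand-overs. The deliberate
   overlap of adjacent bands (trigger bands) makes this hand-over stable.

All fits are exact interpolations (three points per parabola, five per
quartic): point counts equal parameter counts, so no least squares is
involved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .acquisition import (
    BandConfig,
    LedBank,
    SampledPoints,
    band_for_rw,
    default_bands,
    default_led_bank,
)

__all__ = [
    "QuadraticFit",
    "QuarticFit",
    "RwEstimate",
    "AsfState",
    "FitError",
    "quadratic_rw",
    "fullscan_init",
    "asf_step",
    "asf_converge",
    "asf_track",
]


class FitError(ValueError):
    """Singular interpolation (duplicate wavelengths, wrong point count)."""


@dataclass(frozen=True)
class QuadraticFit:
    """Exact parabola a*x^2 + b*x + c through three samples (x in nm)."""

    a: float
    b: float
    c: float
    domain_nm: tuple

    @property
    def vertex_nm(self) -> float:
        if self.a == 0:
            raise FitError("degenerate fit (a = 0) has no vertex")
        return -self.b / (2.0 * self.a)

    def __call__(self, x):
        return (self.a * x + self.b) * x + self.c


@dataclass(frozen=True)
class QuarticFit:
    """Exact degree-4 interpolant; coefficients highest power first."""

    coefficients: tuple
    domain_nm: tuple

    def __call__(self, x):
        return np.polyval(self.coefficients, x)


@dataclass(frozen=True)
class RwEstimate:
    """One RW reading: value, producing band, clamp flag and the fit."""

    rw_nm: float
    band_id: int
    clamped: bool
    fit: Union[QuadraticFit, QuarticFit]
    degenerate: bool = False


@dataclass(frozen=True)
class AsfState:
    """Tracker state: the active band and bookkeeping for one cycle."""

    active_band: int
    last_rw_nm: Optional[float] = None
    switch_count_this_cycle: int = 0


def _solve_centered(x: np.ndarray, y: np.ndarray, degree: int) -> tuple:
    """Exact polynomial interpolation in centered coordinates.

    Returns (coeffs highest-first in centered variable, center). Centering
    keeps the Vandermonde solve well-conditioned at wavelengths ~750 nm.
    """
    if np.unique(x).size != x.size:
        raise FitError("duplicate wavelengths make the interpolation singular")
    x0 = float(x.mean())
    coeffs = np.linalg.solve(np.vander(x - x0, degree + 1), y)
    return coeffs, x0


def quadratic_rw(
    points: SampledPoints,
    fit_range_nm: tuple,
    band_id: int = 0,
) -> RwEstimate:
    """RW from the exact parabola through three sampled points.

    The vertex is the estimate when the parabola opens upward (a > 0) and the
    vertex falls inside *fit_range_nm*. Otherwise — vertex out of range,
    downward-opening fit, or collinear points — the estimate clamps to the
    fit-range endpoint with the lower fitted intensity (the downhill
    direction), flagged ``clamped``; collinear points additionally flag
    ``degenerate``.
    """
    if len(points) != 3:
        raise FitError("quadratic_rw needs exactly 3 points")
    x, y = points.wavelengths_nm, points.intensities
    (a, bc, cc), x0 = _solve_centered(x, y, 2)
    lo, hi = float(fit_range_nm[0]), float(fit_range_nm[1])
    # uncentered coefficients for the public fit object
    b = bc - 2.0 * a * x0
    c = (a * x0 - bc) * x0 + cc
    fit = QuadraticFit(a, b, c, (lo, hi))

    span = hi - lo
    y_scale = max(np.ptp(y), abs(y).max(), 1e-30)
    degenerate = abs(a) * span**2 < 1e-12 * y_scale
    if not degenerate and a > 0:
        vertex = x0 - bc / (2.0 * a)
        if lo <= vertex <= hi:
            return RwEstimate(float(vertex), band_id, False, fit)
    f_lo = (a * (lo - x0) + bc) * (lo - x0) + cc
    f_hi = (a * (hi - x0) + bc) * (hi - x0) + cc
    rw = lo if f_lo <= f_hi else hi
    return RwEstimate(float(rw), band_id, True, fit, degenerate=degenerate)


def fullscan_init(
    points: SampledPoints,
    bands: Optional[Sequence[BandConfig]] = None,
) -> RwEstimate:
    """Coarse starting RW from a full five-LED scan.

    Interpolates the exact quartic through the five samples and returns its
    minimizer over the covered window (default 730–805 nm): interior roots of
    the derivative cubic with positive curvature compete with the window
    endpoints; the lowest fitted value wins (ties to the smaller wavelength).
    An endpoint winner is flagged ``clamped`` — the dip sits at or beyond the
    edge of the window.
    """
    bands = default_bands() if bands is None else tuple(bands)
    lo = bands[0].fit_range_nm[0]
    hi = bands[-1].fit_range_nm[1]
    if len(points) != 5:
        raise FitError("fullscan_init needs exactly 5 points")
    x, y = points.wavelengths_nm, points.intensities
    coeffs, x0 = _solve_centered(x, y, 4)
    deriv = np.polyder(coeffs)
    curv = np.polyder(deriv)
    candidates = []
    for root in np.roots(deriv):
        if abs(root.imag) < 1e-8:
            xr = root.real
            if lo - x0 <= xr <= hi - x0 and np.polyval(curv, xr) > 0:
                candidates.append(xr)
    candidates.sort()
    endpoints = [lo - x0, hi - x0]
    all_cands = candidates + endpoints
    values = [np.polyval(coeffs, c) for c in all_cands]
    best = int(np.argmin(values))  # ties resolve to first = smaller wavelength
    rw = all_cands[best] + x0
    clamped = best >= len(candidates)
    # uncentered coefficients via binomial shift
    shifted = np.poly1d(coeffs)(np.poly1d([1.0, -x0])).coeffs
    fit = QuarticFit(tuple(shifted), (lo, hi))
    return RwEstimate(float(rw), band_for_rw(rw, bands), clamped, fit)


def asf_step(
    state: AsfState,
    sampler: Callable,
    bands: Optional[Sequence[BandConfig]] = None,
) -> tuple:
    """One tracking cycle: sample the active triple, fit, re-select the band.

    *sampler* maps a triple of LED ids to :class:`SampledPoints` at those
    LEDs' centers. Returns ``(estimate, new_state)``; the band switch (if
    any) takes effect on the *next* step, mirroring the instrument's
    red-shift rules (estimate >= 756 nm -> band 3, >= 740 nm -> band >= 2)
    and their blue-shift mirrors. An estimate clamped at the *lower* edge of
    the active band's fit range means the dip moved blue past the band, so
    the tracker steps one band down even when the threshold value itself
    would re-select the current band (e.g. a Band-3 clamp at 756 nm).
    With three totally ordered bands a cycle needs at most two switches;
    further switches within the same cycle are suppressed.
    """
    bands = default_bands() if bands is None else tuple(bands)
    band = bands[state.active_band - 1]
    points = sampler(band.led_ids)
    est = quadratic_rw(points, band.fit_range_nm, band_id=band.band_id)
    new_band = band_for_rw(est.rw_nm, bands)
    if (
        est.clamped
        and est.rw_nm == band.fit_range_nm[0]
        and new_band >= state.active_band
    ):
        new_band = max(state.active_band - 1, 1)
    if new_band != state.active_band and state.switch_count_this_cycle >= 2:
        new_band = state.active_band
    switches = state.switch_count_this_cycle + (new_band != state.active_band)
    return est, AsfState(new_band, est.rw_nm, switches)


def asf_converge(
    state: AsfState,
    sampler: Callable,
    bands: Optional[Sequence[BandConfig]] = None,
    max_steps: int = 3,
) -> tuple:
    """Iterate :func:`asf_step` until the active band is stable.

    Stops as soon as a step leaves the band unchanged (the fixed point) or
    after *max_steps* fits. Because the three bands are totally ordered and
    each switch moves toward the dip, at most two switches — three fits —
    ever occur. Returns ``(final_estimate, final_state)``.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    state = replace(state, switch_count_this_cycle=0)
    est = None
    for _ in range(max_steps):
        previous = state.active_band
        est, state = asf_step(state, sampler, bands)
        if state.active_band == previous:
            break
    return est, state


def _roi_series(series) -> Dict[str, np.ndarray]:
    if isinstance(series, dict):
        return {str(k): np.asarray(v, dtype=float) for k, v in series.items()}
    return {"roi": np.asarray(series, dtype=float)}


def asf_track(
    series,
    times_s: Sequence[float],
    leds: Optional[LedBank] = None,
    bands: Optional[Sequence[BandConfig]] = None,
    reinit_after_clamped: int = 3,
) -> pd.DataFrame:
    """Track the RW through a time series of five-LED intensities per ROI.

    *series* is a mapping ``roi_id -> array (T, 5)`` of intensities, one
    column per LED in ascending center order (a single ``(T, 5)`` array is
    accepted for one ROI). Each ROI carries its own tracker state: a full
    five-point initialization at the first time point, then one
    :func:`asf_converge` call per time point. After more than
    *reinit_after_clamped* consecutive clamped estimates the tracker
    re-initializes from that time point's five samples (the dip may have
    jumped). Time points whose intensities are all zero are flagged missing
    and not fabricated.

    Returns the sensorgram as a tidy DataFrame with columns
    ``time_s, roi_id, rw_nm, band_id, clamped, missing``.
    """
    leds = leds or default_led_bank()
    bands = default_bands() if bands is None else tuple(bands)
    centers = leds.centers_nm
    times = np.asarray(times_s, dtype=float)
    rows = []
    for roi_id, data in _roi_series(series).items():
        if data.ndim != 2 or data.shape[1] != len(centers):
            raise ValueError(
                f"ROI '{roi_id}': expected (T, {len(centers)}) intensity array"
            )
        if data.shape[0] != times.size:
            raise ValueError(f"ROI '{roi_id}': series length != number of times")
        state: Optional[AsfState] = None
        clamped_streak = 0
        for ti, t in enumerate(times):
            intens = data[ti]
            if np.all(intens <= 0):
                rows.append((t, roi_id, np.nan, 0, False, True))
                continue
            if state is None or clamped_streak > reinit_after_clamped:
                init = fullscan_init(SampledPoints(centers, intens), bands)
                state = AsfState(init.band_id)
                clamped_streak = 0

            def sampler(led_ids, _intens=intens):
                idx = [i - 1 for i in led_ids]
                return SampledPoints(centers[idx], _intens[idx])

            est, state = asf_converge(state, sampler, bands)
            clamped_streak = clamped_streak + 1 if est.clamped else 0
            rows.append((t, roi_id, est.rw_nm, est.band_id, est.clamped, False))
    return pd.DataFrame(
        rows, columns=["time_s", "roi_id", "rw_nm", "band_id", "clamped", "missing"]
    )
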