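"""Five-LED illumination bank, fitting bands and scan-cycle timing.

The instrument covers 730–805 nm with five monochromatic LEDs (centers 730,
740, 756, 777 and 805 nm). Three overlapping three-LED fitting bands
partition the window:

======  =========  ============  ===============
band    LED triple  fit range     selection range
======  =========  ============  ===============
1       LEDs 1–3   730–756 nm    [730, 740) nm
2       LEDs 2–4   740–777 nm    [740, 756) nm
3       LEDs 3–5   756–805 nm    [756, 805] nm
======  =========  ============  ===============

The overlaps 740–756 nm and 756–777 nm act as *trigger bands*: a resonance
wavelength there is covered by two adjacent triples, which is what makes
hand-over between bands stable while the resonance drifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "LedChannel",
    "LedBank",
    "BandConfig",
    "TimingModel",
    "SampledPoints",
    "default_led_bank",
    "default_bands",
    "bands_from_leds",
    "sample_leds",
    "cycle_time_ms",
    "band_for_rw",
    "RwRangeError",
]


class RwRangeError(ValueError):
    """Resonance wavelength outside the LED-covered window."""


@dataclass(frozen=True)
class LedChannel:
    """One monochromatic LED: 1-based id, center wavelength, optional width.

    ``fwhm_nm=None`` means delta-function sampling at the center wavelength
    (the tracking algorithm's idealization); a finite FWHM models the LED as
    a Gaussian line profile.
    """

    id: int
    center_nm: float
    fwhm_nm: Optional[float] = None
    response_ms: float = 2.0

    def __post_init__(self) -> None:
        if self.fwhm_nm is not None and self.fwhm_nm <= 0:
            raise ValueError("fwhm_nm must be positive when set")
        if self.response_ms < 0:
            raise ValueError("response_ms must be >= 0")


@dataclass(frozen=True)
class LedBank:
    """Exactly five LEDs with strictly ascending center wavelengths."""

    channels: tuple

    def __post_init__(self) -> None:
        ch = tuple(self.channels)
        object.__setattr__(self, "channels", ch)
        if len(ch) != 5:
            raise ValueError("a LedBank holds exactly 5 channels")
        centers = [c.center_nm for c in ch]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("LED centers must be strictly ascending")

    @property
    def centers_nm(self) -> np.ndarray:
        return np.array([c.center_nm for c in self.channels])

    def triple(self, led_ids: Sequence[int]) -> tuple:
        return tuple(self.channels[i - 1] for i in led_ids)


@dataclass(frozen=True)
class BandConfig:
    """One three-LED fitting band.

    ``fit_range_nm`` is the span of the triple's centers (where the parabola
    vertex is accepted); ``selection_range_nm`` is the half-open interval of
    resonance wavelengths for which this band is the active one (the final
    band is closed at its upper edge).
    """

    band_id: int
    led_ids: tuple
    fit_range_nm: tuple
    selection_range_nm: tuple

    def __post_init__(self) -> None:
        if self.band_id not in (1, 2, 3):
            raise ValueError("band_id must be 1, 2 or 3")
        if len(self.led_ids) != 3:
            raise ValueError("a band uses exactly 3 consecutive LEDs")


def default_led_bank(fwhm_nm: Optional[float] = None) -> LedBank:
    """The instrument's LED set: centers 730, 740, 756, 777, 805 nm."""
    centers = (730.0, 740.0, 756.0, 777.0, 805.0)
    return LedBank(
        tuple(LedChannel(i + 1, c, fwhm_nm) for i, c in enumerate(centers))
    )


def bands_from_leds(bank: LedBank) -> tuple:
    """Three overlapping bands from consecutive LED triples.

    Selection thresholds are the centers of LED2 and LED3: once the estimated
    resonance reaches the second LED the next triple takes over, which puts
    every hand-over inside a trigger band (the overlap of adjacent triples).
    """
    c = bank.centers_nm
    return (
        BandConfig(1, (1, 2, 3), (c[0], c[2]), (c[0], c[1])),
        BandConfig(2, (2, 3, 4), (c[1], c[3]), (c[1], c[2])),
        BandConfig(3, (3, 4, 5), (c[2], c[4]), (c[2], c[4])),
    )


def default_bands() -> tuple:
    """Bands 730–756 / 740–777 / 756–805 nm with thresholds at 740 and 756 nm."""
    return bands_from_leds(default_led_bank())


def band_for_rw(rw_nm: float, bands: Optional[Sequence[BandConfig]] = None) -> int:
    """The active band for a resonance wavelength.

    Selection intervals are half-open ``[lo, hi)`` with the final band closed
    at its top, so every rw in the covered window maps to exactly one band:
    with the default thresholds, rw < 740 is band 1, 740 <= rw < 756 band 2
    and rw >= 756 band 3.
    """
    bands = default_bands() if bands is None else tuple(bands)
    lo = bands[0].selection_range_nm[0]
    hi = bands[-1].selection_range_nm[1]
    if not (lo <= rw_nm <= hi):
        raise RwRangeError(f"rw {rw_nm:.2f} nm outside the covered window [{lo}, {hi}]")
    for band in bands[:-1]:
        if band.selection_range_nm[0] <= rw_nm < band.selection_range_nm[1]:
            return band.band_id
    return bands[-1].band_id


@dataclass(frozen=True)
class TimingModel:
    """Per-wavelength acquisition cost: LED response plus camera exposure."""

    led_response_ms: float = 2.0
    exposure_ms: float = 33.0

    def __post_init__(self) -> None:
        if self.led_response_ms < 0 or self.exposure_ms < 0:
            raise ValueError("timing fields must be >= 0")


def cycle_time_ms(n_wavelengths: int, timing: TimingModel = TimingModel()) -> float:
    """Scan-cycle duration: n x (LED response + exposure).

    Three wavelengths at the default 2 ms + 33 ms give the instrument's
    105 ms cycle; a five-wavelength full scan takes 175 ms.
    """
    if n_wavelengths < 1:
        raise ValueError("need at least one wavelength per cycle")
    return n_wavelengths * (timing.led_response_ms + timing.exposure_ms)


@dataclass(frozen=True)
class SampledPoints:
    """Discrete (wavelength, intensity) samples, wavelengths ascending."""

    wavelengths_nm: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if wl.shape != y.shape or wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelengths/intensities must be 1-D, equal, non-empty")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly ascending")
        if np.any(y < 0):
            raise ValueError("intensities must be >= 0")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return self.wavelengths_nm.size


# Gauss–Legendre rule reused for LED line-profile weighting.
_GL_X, _GL_W = np.polynomial.legendre.leggauss(41)


def _profile_weighted(provider: Callable, center: float, fwhm: float) -> float:
    """Mean reflectance under a Gaussian LED line profile (+-3 sigma)."""
    sigma = fwhm / 2.3548200450309493
    lam = center + 3.0 * sigma * _GL_X
    w = _GL_W * np.exp(-0.5 * ((lam - center) / sigma) ** 2)
    vals = np.asarray(provider(lam), dtype=float)
    return float(np.sum(w * vals) / np.sum(w))


def sample_leds(
    provider: Callable,
    leds: Sequence[LedChannel],
    noise_sd: float = 0.0,
    rng_seed: Optional[int] = None,
) -> SampledPoints:
    """Sample a reflectance spectrum at a set of LED channels.

    *provider* maps wavelength (scalar or array, nm) to reflectance. Each LED
    contributes one point: the reflectance at its center (delta profile,
    default) or the Gaussian-profile-weighted mean when ``fwhm_nm`` is set.
    Additive zero-mean Gaussian noise of standard deviation *noise_sd* is
    applied afterwards, reproducibly under *rng_seed*; intensities are
    floored at zero (a camera cannot report negative counts).
    """
    if len(leds) == 0:
        raise ValueError("need at least one LED")
    leds = sorted(leds, key=lambda c: c.center_nm)
    centers = np.array([c.center_nm for c in leds])
    vals = np.empty_like(centers)
    delta = [c for c in leds if c.fwhm_nm is None]
    if delta:
        idx = [i for i, c in enumerate(leds) if c.fwhm_nm is None]
        out = np.atleast_1d(np.asarray(provider(centers[idx]), dtype=float))
        vals[idx] = out
    for i, c in enumerate(leds):
        if c.fwhm_nm is not None:
            vals[i] = _profile_weighted(provider, c.center_nm, c.fwhm_nm)
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
    return SampledPoints(centers, np.maximum(vals, 0.0))
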