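"""Dielectric dispersion models for the multilayer reflectance simulator.

Three model variants are supported, mirroring how optical constants are
usually available in practice:

* :class:`Constant` — a wavelength-independent complex index ``n + i k``
  (water, glass over a narrow band, index-matching oil ...).
* :class:`Tabulated` — a measured ``(wavelength, n, k)`` table with linear
  interpolation between rows and *no* extrapolation outside the table.
* :class:`DrudeLorentz` — an analytic free-electron model with optional
  Lorentz oscillators, convenient for smooth metal dispersion.

Sign convention: fields evolve as ``exp(-i omega t)``, so a passive medium has
``Im(eps) >= 0`` and the complex index is the principal square root of the
permittivity (``n >= 0``, ``k >= 0``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "Constant",
    "Tabulated",
    "DrudeLorentz",
    "LorentzOscillator",
    "DispersionModel",
    "DispersionError",
    "WavelengthRangeError",
    "permittivity",
    "refractive_index",
    "load_nk_table",
    "packaged_table",
    "gold_drude",
]

#: hc in eV * nm, used to convert photon energy <-> vacuum wavelength.
EV_NM = 1239.841984


class DispersionError(ValueError):
    """Invalid dispersion model or evaluation request."""


class WavelengthRangeError(DispersionError):
    """Requested wavelength lies outside a tabulated model's support."""


@dataclass(frozen=True)
class Constant:
    """Wavelength-independent complex refractive index ``n + i k``."""

    n: float
    k: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 0 or self.k < 0:
            raise DispersionError("passive media require n >= 0 and k >= 0")


@dataclass(frozen=True)
class Tabulated:
    """Linear-interpolation ``(wavelength_nm, n, k)`` table.

    Wavelengths must be strictly ascending; evaluation outside
    ``[wavelengths[0], wavelengths[-1]]`` raises :class:`WavelengthRangeError`
    rather than extrapolating.
    """

    wavelengths_nm: tuple
    n: tuple
    k: tuple
    label: str = "tabulated"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        n = np.asarray(self.n, dtype=float)
        k = np.asarray(self.k, dtype=float)
        if not (wl.size == n.size == k.size) or wl.size < 2:
            raise DispersionError("table needs >= 2 rows of equal length")
        if np.any(np.diff(wl) <= 0):
            raise DispersionError("table wavelengths must be strictly ascending")
        if np.any(n < 0) or np.any(k < 0):
            raise DispersionError("passive media require n >= 0 and k >= 0")
        object.__setattr__(self, "wavelengths_nm", tuple(wl))
        object.__setattr__(self, "n", tuple(n))
        object.__setattr__(self, "k", tuple(k))

    @property
    def support_nm(self) -> tuple:
        return (self.wavelengths_nm[0], self.wavelengths_nm[-1])


@dataclass(frozen=True)
class LorentzOscillator:
    """One Lorentz pole: strength f, resonance energy and damping in eV."""

    f: float
    energy_ev: float
    gamma_ev: float


@dataclass(frozen=True)
class DrudeLorentz:
    """eps(E) = eps_inf - Ep^2/(E^2 + i G E) + sum_j f_j Ej^2/(Ej^2 - E^2 - i Gj E)

    Energies in eV. With the exp(-i omega t) convention both terms contribute
    Im(eps) >= 0 for positive dampings.
    """

    eps_inf: float
    plasma_energy_ev: float
    damping_ev: float
    oscillators: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.plasma_energy_ev <= 0 or self.damping_ev < 0:
            raise DispersionError("plasma energy must be > 0, damping >= 0")
        object.__setattr__(self, "oscillators", tuple(self.oscillators))


DispersionModel = Union[Constant, Tabulated, DrudeLorentz]


def permittivity(model: DispersionModel, wavelength_nm) -> np.ndarray:
    """Complex relative permittivity of *model* at *wavelength_nm* (nm).

    Accepts a scalar or array of wavelengths; returns a complex scalar/array.
    For index-based models ``eps = (n + i k)**2``.
    """
    lam = np.asarray(wavelength_nm, dtype=float)
    if np.any(lam <= 0):
        raise DispersionError("wavelength must be positive")
    if isinstance(model, Constant):
        nk = complex(model.n, model.k)
        eps = np.full(lam.shape, nk * nk, dtype=complex)
    elif isinstance(model, Tabulated):
        lo, hi = model.support_nm
        if np.any(lam < lo) or np.any(lam > hi):
            raise WavelengthRangeError(
                f"wavelength outside tabulated support [{lo}, {hi}] nm "
                f"of table '{model.label}' (no extrapolation)"
            )
        n = np.interp(lam, model.wavelengths_nm, model.n)
        k = np.interp(lam, model.wavelengths_nm, model.k)
        eps = (n + 1j * k) ** 2
    elif isinstance(model, DrudeLorentz):
        e = EV_NM / lam
        eps = np.full(lam.shape, model.eps_inf, dtype=complex)
        eps -= model.plasma_energy_ev**2 / (e**2 + 1j * model.damping_ev * e)
        for osc in model.oscillators:
            eps += (
                osc.f
                * osc.energy_ev**2
                / (osc.energy_ev**2 - e**2 - 1j * osc.gamma_ev * e)
            )
    else:  # pragma: no cover - defensive
        raise DispersionError(f"unknown dispersion model: {model!r}")
    return eps[()] if eps.ndim == 0 else eps


def refractive_index(model: DispersionModel, wavelength_nm) -> np.ndarray:
    """Complex index ``n + i k`` (principal branch, so n >= 0 and k >= 0)."""
    return np.sqrt(permittivity(model, wavelength_nm))


def load_nk_table(path, label: str | None = None) -> Tabulated:
    """Read a 3-column delimited text table (wavelength_nm, n, k).

    Lines starting with ``#`` are comments; columns are whitespace- or
    tab-separated.
    """
    path = Path(path)
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] != 3:
        raise DispersionError(f"{path}: expected 3 columns (wavelength_nm, n, k)")
    return Tabulated(
        wavelengths_nm=tuple(data[:, 0]),
        n=tuple(data[:, 1]),
        k=tuple(data[:, 2]),
        label=label or path.stem,
    )


def packaged_table(name: str) -> Tabulated:
    """Load one of the optical-constant tables shipped with the package.

    Available names: ``au_nk`` (gold) and ``cr_nk_synthetic`` (chromium
    adhesion layer, synthetic representative values).
    """
    from importlib import resources

    ref = resources.files("wspri.data").joinpath(f"{name}.tsv")
    if not ref.is_file():
        raise DispersionError(f"no packaged optical-constant table named '{name}'")
    with resources.as_file(ref) as p:
        return load_nk_table(p, label=name)


def gold_drude() -> DrudeLorentz:
    """Simple Drude fit for gold in the NIR (eps_inf 9.84, Ep 9.01 eV, G 0.072 eV).

    Adequate above ~650 nm where interband transitions are weak; the packaged
    ``au_nk`` table is the default gold model, this one is the smooth analytic
    alternative.
    """
    return DrudeLorentz(eps_inf=9.84, plasma_energy_ev=9.01, damping_ev=0.072)
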