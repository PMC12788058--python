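"""Kretschmann-configuration multilayer reflectance and resonance location.

The forward model computes the p-polarized (TM) reflectance of a planar
multilayer — prism / chromium / gold / analyte in the default sensor — with
the standard 2x2 characteristic-matrix method. At a fixed incident angle the
reflectance versus wavelength shows the SPR dip; the wavelength of minimum
reflectance is the resonance wavelength (RW) that the tracking algorithm
reconstructs from sparse LED samples.

Conventions
-----------
* time dependence ``exp(-i omega t)``: passive media have ``Im(eps) >= 0`` and
  the decaying-wave branch of the normal wavevector has ``Im(kz) >= 0``;
* angles are degrees at the API surface, radians internally;
* wavelengths are nanometres everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence, Union

import numpy as np

from .dispersion import (
    Constant,
    DispersionModel,
    Tabulated,
    packaged_table,
    permittivity,
    refractive_index,
)

__all__ = [
    "SEMI_INFINITE",
    "OpticalLayer",
    "LayerStack",
    "ReflectanceSpectrum",
    "StackError",
    "BoundaryMinimumError",
    "SingularConfigurationError",
    "rp_multilayer",
    "spr_spectrum",
    "true_rw",
    "refine_minimum",
    "resonance_residual",
    "kretschmann_stack",
    "sf11_sellmeier_index",
]

#: Marker thickness for the two outer half-spaces.
SEMI_INFINITE = math.inf


class StackError(ValueError):
    """Malformed layer stack."""


class BoundaryMinimumError(RuntimeError):
    """The reflectance minimum sits on the search-range boundary (dip outside)."""


class SingularConfigurationError(RuntimeError):
    """eps_metal + eps_dielectric ~ 0: the surface-plasmon pole is singular."""


@dataclass(frozen=True)
class OpticalLayer:
    """One planar medium: a name, a thickness in nm and a dispersion model.

    Outer half-spaces carry ``thickness_nm = SEMI_INFINITE``.
    """

    name: str
    thickness_nm: float
    dispersion: DispersionModel

    def __post_init__(self) -> None:
        t = self.thickness_nm
        if t != SEMI_INFINITE and not (np.isfinite(t) and t > 0):
            raise StackError(
                f"layer '{self.name}': thickness must be > 0 nm or SEMI_INFINITE"
            )

    @property
    def semi_infinite(self) -> bool:
        return self.thickness_nm == SEMI_INFINITE


@dataclass(frozen=True)
class LayerStack:
    """Ordered media, incidence side first (prism), analyte last.

    The first and last layers must be semi-infinite, interior layers finite.
    ``incident_angle_deg`` is measured from the stack normal inside the
    incidence medium.
    """

    layers: tuple
    incident_angle_deg: float

    def __post_init__(self) -> None:
        layers = tuple(self.layers)
        object.__setattr__(self, "layers", layers)
        if len(layers) < 2:
            raise StackError("a stack needs at least two media")
        if not (layers[0].semi_infinite and layers[-1].semi_infinite):
            raise StackError("first and last layers must be semi-infinite")
        if any(l.semi_infinite for l in layers[1:-1]):
            raise StackError("interior layers must have finite thickness")
        if not 0.0 < self.incident_angle_deg < 90.0:
            raise StackError("incident angle must lie in (0, 90) degrees")

    def with_analyte(self, dispersion: DispersionModel) -> "LayerStack":
        """A copy with the final (analyte) half-space replaced."""
        analyte = OpticalLayer(self.layers[-1].name, SEMI_INFINITE, dispersion)
        return LayerStack(self.layers[:-1] + (analyte,), self.incident_angle_deg)

    def with_analyte_index(self, n: float, k: float = 0.0) -> "LayerStack":
        return self.with_analyte(Constant(n, k))


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Sampled p-reflectance: ascending wavelengths (nm) and Rp in [0, 1]."""

    wavelengths_nm: np.ndarray
    rp: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        rp = np.asarray(self.rp, dtype=float)
        if wl.shape != rp.shape or wl.ndim != 1:
            raise ValueError("wavelengths and rp must be 1-D and equal length")
        if wl.size > 1 and np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly ascending")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "rp", rp)

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    def save(self, path) -> None:
        """Write a 2-column delimited text file (wavelength_nm, reflectance)."""
        np.savetxt(
            path,
            np.column_stack([self.wavelengths_nm, self.rp]),
            fmt="%.6f\t%.8f",
            header="wavelength_nm\treflectance",
            comments="",
        )


def _kz(eps: np.ndarray, k0: np.ndarray, kx: np.ndarray) -> np.ndarray:
    """Normal wavevector component with the decaying branch Im(kz) >= 0."""
    kz = np.sqrt(eps * k0**2 - kx**2 + 0j)
    return np.where(kz.imag < 0, -kz, kz)


def rp_multilayer(stack: LayerStack, wavelength_nm, angle_deg: float | None = None):
    """p-polarized intensity reflectance |r_p|^2 of the full stack.

    Uses the 2x2 characteristic-matrix method with the TM admittance
    ``q = kz / (k0 eps)`` per layer. ``wavelength_nm`` may be a scalar or an
    array; the incidence angle defaults to the stack's own angle.

    For passive media the result lies in [0, 1].
    """
    theta = math.radians(
        stack.incident_angle_deg if angle_deg is None else float(angle_deg)
    )
    if not 0.0 < math.degrees(theta) < 90.0:
        raise StackError("incident angle must lie in (0, 90) degrees")
    lam = np.asarray(wavelength_nm, dtype=float)
    scalar = lam.ndim == 0
    lam = np.atleast_1d(lam)

    k0 = 2.0 * np.pi / lam
    eps = [permittivity(layer.dispersion, lam) for layer in stack.layers]
    eps = [np.broadcast_to(np.atleast_1d(e), lam.shape) for e in eps]
    if any(not np.all(np.isfinite(e)) for e in eps):
        raise StackError("non-finite permittivity at requested wavelength")
    kx = k0 * np.sqrt(eps[0]) * math.sin(theta)

    q = [_kz(e, k0, kx) / (k0 * e) for e in eps]

    m11 = np.ones_like(lam, dtype=complex)
    m12 = np.zeros_like(m11)
    m21 = np.zeros_like(m11)
    m22 = np.ones_like(m11)
    for j, layer in enumerate(stack.layers[1:-1], start=1):
        beta = _kz(eps[j], k0, kx) * layer.thickness_nm
        c, s = np.cos(beta), np.sin(beta)
        a11, a12 = c, -1j * s / q[j]
        a21, a22 = -1j * q[j] * s, c
        m11, m12, m21, m22 = (
            m11 * a11 + m12 * a21,
            m11 * a12 + m12 * a22,
            m21 * a11 + m22 * a21,
            m21 * a12 + m22 * a22,
        )

    q1, qn = q[0], q[-1]
    num = (m11 + m12 * qn) * q1 - (m21 + m22 * qn)
    den = (m11 + m12 * qn) * q1 + (m21 + m22 * qn)
    rp = np.abs(num / den) ** 2
    # absorb rounding overshoot just above 1 (lossless TIR); a genuinely
    # amplified reflection (lossy incidence medium) passes through untouched
    rp = np.where((rp > 1.0) & (rp <= 1.0 + 1e-9), 1.0, rp)
    return float(rp[0]) if scalar else rp


def spr_spectrum(
    stack: LayerStack, angle_deg: float | None, wavelengths_nm: Sequence[float]
) -> ReflectanceSpectrum:
    """Element-wise reflectance on an ascending wavelength grid."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    if wl.size == 0:
        return ReflectanceSpectrum(wl, np.empty(0))
    return ReflectanceSpectrum(wl, rp_multilayer(stack, wl, angle_deg))


def refine_minimum(wavelengths_nm: np.ndarray, values: np.ndarray, i: int) -> float:
    """3-point parabolic interpolation of a sampled minimum at index *i*.

    Returns the vertex abscissa of the parabola through points
    ``i-1, i, i+1``; falls back to the grid point for a degenerate (flat)
    triple. Assumes ``0 < i < len - 1``.
    """
    x0, x1, x2 = wavelengths_nm[i - 1 : i + 2]
    y0, y1, y2 = values[i - 1 : i + 2]
    denom = (y0 - 2.0 * y1 + y2)
    if denom <= 0:
        return float(x1)
    # uniform-grid vertex formula generalized to (possibly) uneven spacing
    a = ((y2 - y1) / (x2 - x1) - (y1 - y0) / (x1 - x0)) / (x2 - x0)
    if a <= 0:
        return float(x1)
    b = (y1 - y0) / (x1 - x0) - a * (x0 + x1)
    vertex = -b / (2.0 * a)
    return float(min(max(vertex, x0), x2))


def true_rw(
    target: Union[LayerStack, Callable],
    angle_deg: float | None = None,
    search_range_nm: tuple = (730.0, 805.0),
    grid_step_nm: float = 0.01,
) -> float:
    """Resonance wavelength: dense-grid argmin with parabolic refinement.

    *target* is either a :class:`LayerStack` (evaluated via
    :func:`rp_multilayer`) or any callable mapping a wavelength array to
    reflectances. Ties between equal grid minima resolve to the smaller
    wavelength. A minimum on the boundary of *search_range_nm* raises
    :class:`BoundaryMinimumError` — the dip lies outside the range.
    """
    lo, hi = float(search_range_nm[0]), float(search_range_nm[1])
    if not (hi > lo) or grid_step_nm <= 0:
        raise ValueError("need hi > lo and grid_step_nm > 0")
    n = int(round((hi - lo) / grid_step_nm)) + 1
    grid = np.linspace(lo, hi, max(n, 3))
    if isinstance(target, LayerStack):
        rp = rp_multilayer(target, grid, angle_deg)
    else:
        rp = np.asarray(target(grid), dtype=float)
    i = int(np.argmin(rp))
    if i == 0 or i == grid.size - 1:
        raise BoundaryMinimumError(
            f"reflectance minimum at the search boundary ({grid[i]:.2f} nm); "
            "the dip lies outside the search range"
        )
    return refine_minimum(grid, rp, i)


def resonance_residual(
    stack: LayerStack, wavelength_nm: float, angle_deg: float | None = None
) -> float:
    """|Re(k_SP) - k_x| in rad/nm, the phase-matching diagnostic.

    ``k_SP = (2 pi / lam) sqrt(eps_m eps_d / (eps_m + eps_d))`` for the metal
    (layer adjacent to the analyte) and the analyte half-space;
    ``k_x = (2 pi / lam) n_p sin(theta)`` for the prism. The SPR dip sits
    near the wavelength where this residual is smallest.
    """
    if len(stack.layers) < 3:
        raise StackError("need a metal layer between prism and analyte")
    lam = float(wavelength_nm)
    theta = math.radians(
        stack.incident_angle_deg if angle_deg is None else float(angle_deg)
    )
    eps_m = complex(np.asarray(permittivity(stack.layers[-2].dispersion, lam)))
    eps_d = complex(np.asarray(permittivity(stack.layers[-1].dispersion, lam)))
    denom = eps_m + eps_d
    if abs(denom) < 1e-9 * max(abs(eps_m), abs(eps_d), 1.0):
        raise SingularConfigurationError(
            "eps_metal + eps_dielectric ~ 0: surface-plasmon pole is singular"
        )
    k_sp = (2.0 * np.pi / lam) * np.sqrt(eps_m * eps_d / denom)
    n_p = complex(np.asarray(refractive_index(stack.layers[0].dispersion, lam))).real
    k_x = (2.0 * np.pi / lam) * n_p * math.sin(theta)
    return abs(k_sp.real - k_x)


def sf11_sellmeier_index() -> Tabulated:
    """SF11 glass index from its Sellmeier equation, tabulated 400-1100 nm."""
    b = (1.73759695, 0.313747346, 1.89878101)
    c = (0.013188707, 0.0623068142, 155.23629)  # um^2
    lam_um = np.linspace(0.4, 1.1, 141)
    l2 = lam_um**2
    n2 = 1.0 + sum(bi * l2 / (l2 - ci) for bi, ci in zip(b, c))
    return Tabulated(
        wavelengths_nm=tuple(lam_um * 1000.0),
        n=tuple(np.sqrt(n2)),
        k=tuple(np.zeros_like(lam_um)),
        label="sf11_sellmeier",
    )


def kretschmann_stack(
    analyte_n: float = 1.333,
    incident_angle_deg: float = 51.2,
    gold_nm: float = 48.0,
    chromium_nm: float | None = 2.0,
    prism: DispersionModel | str = "constant",
    gold: DispersionModel | None = None,
) -> LayerStack:
    """The default sensor: SF11 prism / 2 nm Cr / 48 nm Au / aqueous analyte.

    ``prism`` is either a dispersion model, ``"constant"`` (n = 1.785, the
    prism's quoted index) or ``"sf11"`` (Sellmeier dispersion).
    ``chromium_nm=None`` drops the adhesion layer; ``gold`` overrides the
    packaged tabulated gold constants.
    """
    if prism == "constant":
        prism_model: DispersionModel = Constant(1.785)
    elif prism == "sf11":
        prism_model = sf11_sellmeier_index()
    else:
        prism_model = prism  # type: ignore[assignment]
    layers = [OpticalLayer("prism", SEMI_INFINITE, prism_model)]
    if chromium_nm is not None:
        layers.append(
            OpticalLayer("chromium", chromium_nm, packaged_table("cr_nk_synthetic"))
        )
    layers.append(OpticalLayer("gold", gold_nm, gold or packaged_table("au_nk")))
    layers.append(OpticalLayer("analyte", SEMI_INFINITE, Constant(analyte_n)))
    return LayerStack(tuple(layers), incident_angle_deg)
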