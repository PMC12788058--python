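"""Independent reflectance oracle: recursive single-interface Fresnel cascade.

Deliberately implemented without the characteristic-matrix formalism used by
the package (Parratt-style recursion over interface coefficients), so the
two routes share only the physics, not the code path.
"""

import math

import numpy as np


def _kz(eps: complex, k0: float, kx: complex) -> complex:
    kz = np.sqrt(complex(eps) * k0**2 - kx**2)
    if kz.imag < 0:
        kz = -kz
    return kz


def rp_recursive(eps_list, thickness_list, wavelength_nm, angle_deg) -> float:
    """|r_p|^2 of a multilayer by bottom-up Fresnel recursion.

    ``eps_list`` holds complex permittivities, incidence medium first;
    ``thickness_list`` holds the interior thicknesses in nm (length =
    len(eps_list) - 2).
    """
    n_layers = len(eps_list)
    assert len(thickness_list) == n_layers - 2
    k0 = 2.0 * math.pi / wavelength_nm
    kx = k0 * np.sqrt(complex(eps_list[0])) * math.sin(math.radians(angle_deg))
    kz = [_kz(e, k0, kx) for e in eps_list]

    def fresnel_p(i: int, j: int) -> complex:
        return (eps_list[j] * kz[i] - eps_list[i] * kz[j]) / (
            eps_list[j] * kz[i] + eps_list[i] * kz[j]
        )

    r = fresnel_p(n_layers - 2, n_layers - 1)
    for i in range(n_layers - 3, -1, -1):
        phase = np.exp(2j * kz[i + 1] * thickness_list[i])
        r_i = fresnel_p(i, i + 1)
        r = (r_i + r * phase) / (1.0 + r_i * r * phase)
    return float(abs(r) ** 2)
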