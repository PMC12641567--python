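"""Rayleigh-limit conversions between droplet charge, diameter, and mass.

The Rayleigh limit is the maximum charge ``z_R`` a spherical liquid droplet
can carry before Coulomb fission.  For a water droplet of diameter ``d_R``,

    d_R = 2 * (z_R * e / (8*pi))**(2/3) * (eps0 * gamma)**(-1/3)

with ``e`` the elementary charge, ``eps0`` the permittivity of the medium and
``gamma`` the surface tension of water.  Because most globular particles
electrosprayed from aqueous solution charge close to this limit, the charge
axis of a CDMS histogram doubles as a particle-diameter axis, and the charge
of sub-capsid fragments tracks the "Rayleigh line" z_R(m) obtained by
converting droplet mass to a sphere diameter at unit density.

All charges are in elementary units, diameters in nm, masses in Da.  Charges
are real-valued throughout; integerization is presentation-only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DA_TO_KG",
    "RayleighConstants",
    "diameter_from_charge",
    "charge_from_diameter",
    "rayleigh_charge_for_mass",
    "sphere_diameter_for_mass",
]

#: 1 dalton in kilograms (CODATA).
DA_TO_KG = 1.66053906660e-27


@dataclass(frozen=True)
class RayleighConstants:
    """Physical constants entering the Rayleigh-limit expressions.

    Parameters
    ----------
    epsilon0 : float
        Permittivity of the surrounding medium, F/m.
    gamma : float
        Surface tension of water, N/m.  The default 0.0720 N/m reproduces
        the 165 e <-> 24.0 nm and 170 e <-> 24.5 nm pairings.
    e_charge : float
        Elementary charge, C.
    density : float
        Droplet density, kg/m^3; 1000 for the aqueous Rayleigh line.
    """

    epsilon0: float = 8.8542e-12
    gamma: float = 0.0720
    e_charge: float = 1.602177e-19
    density: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("epsilon0", "gamma", "e_charge", "density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"RayleighConstants.{name} must be strictly positive")


DEFAULT_CONSTANTS = RayleighConstants()


def _check_nonnegative(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr


def diameter_from_charge(z, consts: RayleighConstants = DEFAULT_CONSTANTS):
    """Diameter (nm) of a spherical water droplet whose Rayleigh limit is ``z``.

    Accepts scalars or arrays of charge in elementary units; z=0 maps to 0 nm.
    """
    zarr = _check_nonnegative(z, "charge")
    q = zarr * consts.e_charge
    d_m = 2.0 * (q / (8.0 * np.pi)) ** (2.0 / 3.0) * (consts.epsilon0 * consts.gamma) ** (-1.0 / 3.0)
    d_nm = d_m * 1e9
    return float(d_nm) if np.isscalar(z) or np.ndim(z) == 0 else d_nm


def charge_from_diameter(d_nm, consts: RayleighConstants = DEFAULT_CONSTANTS):
    """Rayleigh-limit charge (elementary units) of a droplet of diameter ``d_nm``.

    Exact algebraic inverse of :func:`diameter_from_charge`; returns real
    (unrounded) charge.
    """
    darr = _check_nonnegative(d_nm, "diameter")
    r = darr * 1e-9 / 2.0
    z = 8.0 * np.pi * np.sqrt(consts.epsilon0 * consts.gamma * r**3) / consts.e_charge
    return float(z) if np.isscalar(d_nm) or np.ndim(d_nm) == 0 else z


def sphere_diameter_for_mass(m_da, consts: RayleighConstants = DEFAULT_CONSTANTS):
    """Diameter (nm) of a sphere of mass ``m_da`` Da at the configured density."""
    marr = _check_nonnegative(m_da, "mass")
    m_kg = marr * DA_TO_KG
    r = (3.0 * m_kg / (4.0 * np.pi * consts.density)) ** (1.0 / 3.0)
    d_nm = 2.0 * r * 1e9
    return float(d_nm) if np.isscalar(m_da) or np.ndim(m_da) == 0 else d_nm


def rayleigh_charge_for_mass(m_da, consts: RayleighConstants = DEFAULT_CONSTANTS):
    """Rayleigh-limit charge of a spherical droplet of mass ``m_da`` Da.

    This is the "Rayleigh line" overlaid on 2D mass/charge histograms: the
    droplet radius follows from mass and density, then
    z_R = 8*pi*sqrt(eps0*gamma*r^3)/e.  Scales as sqrt(m).
    """
    marr = _check_nonnegative(m_da, "mass")
    m_kg = marr * DA_TO_KG
    r = (3.0 * m_kg / (4.0 * np.pi * consts.density)) ** (1.0 / 3.0)
    z = 8.0 * np.pi * np.sqrt(consts.epsilon0 * consts.gamma * r**3) / consts.e_charge
    return float(z) if np.isscalar(m_da) or np.ndim(m_da) == 0 else z
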