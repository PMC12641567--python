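"""Mechanistic population classification of measured ions.

Acid- and freeze-thaw-stressed AAV ensembles separate in the 2D mass/charge
plane into intact full capsids, empty capsids, a sub-capsid fragment
continuum whose charge tracks the Rayleigh line (capsid disassembly with
retained DNA), capsid dimers, and intact capsids carrying aggregated
constituent proteins.  The gates below turn that visual classification into
deterministic mass/charge windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .capsid import CapsidSpecies, VPMasses, DEFAULT_VP_MASSES, species_mass
from .rayleigh import RayleighConstants, DEFAULT_CONSTANTS, rayleigh_charge_for_mass

__all__ = [
    "LABELS",
    "PopulationGates",
    "ReferenceMasses",
    "classify_masses_charges",
    "classify_ions",
    "population_fractions",
    "estimate_bound_count",
    "estimate_bound_counts",
    "charge_vs_bound_slope",
]

LABELS = ("INTACT_FULL", "EMPTY", "FRAGMENT", "DIMER", "AGGREGATE", "UNASSIGNED")


@dataclass(frozen=True)
class PopulationGates:
    """Classification windows.

    Relative mass windows (+/- fractions of the reference mass) select the
    intact-full, empty and dimer species; FRAGMENT requires mass below
    ``fragment_mass_ceiling`` x full mass *and* charge within
    ``rayleigh_band`` of the Rayleigh-limit charge for that mass; AGGREGATE
    is any mass more than ``aggregate_min_excess_da`` above the full capsid
    that is not a dimer.  The 0.93 fragment ceiling excludes the intact
    distribution tail (intact mass SD ~1.5% at default noise).
    """

    full_mass_window: float = 0.05
    empty_mass_window: float = 0.02
    dimer_mass_window: float = 0.04
    rayleigh_band: tuple[float, float] = (0.80, 1.02)
    aggregate_min_excess_da: float = 2.5e5
    fragment_mass_ceiling: float = 0.93

    def __post_init__(self) -> None:
        if min(self.full_mass_window, self.empty_mass_window, self.dimer_mass_window) <= 0:
            raise ValueError("mass windows must be positive")
        lo, hi = self.rayleigh_band
        if not (0.0 < lo < hi <= 1.1):
            raise ValueError("rayleigh_band must satisfy 0 < lo < hi <= 1.1")
        if not 0.0 < self.fragment_mass_ceiling < 1.0:
            raise ValueError("fragment_mass_ceiling must be in (0, 1)")


DEFAULT_GATES = PopulationGates()


@dataclass(frozen=True)
class ReferenceMasses:
    """Expected masses (Da) of the gated species; empty/dimer optional."""

    full_da: float
    empty_da: float | None = None
    dimer_da: float | None = None


def _references_from_species(expected, vp_masses: VPMasses) -> ReferenceMasses:
    if isinstance(expected, ReferenceMasses):
        return expected
    full = empty = dimer = None
    for sp in expected:
        m = species_mass(sp, vp_masses)
        if sp.multiplicity >= 2:
            dimer = m
        elif sp.cargo_da == 0:
            empty = m
        else:
            full = m
    if full is None:
        raise ValueError("expected species set must contain a full (cargo-bearing) monomer")
    return ReferenceMasses(full_da=full, empty_da=empty, dimer_da=dimer)


def classify_masses_charges(
    mass_da,
    charge_e,
    refs: ReferenceMasses,
    gates: PopulationGates = DEFAULT_GATES,
    consts: RayleighConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Vectorized label assignment on (mass, charge) arrays.

    Precedence: DIMER > INTACT_FULL > EMPTY > AGGREGATE > FRAGMENT; anything
    left over is UNASSIGNED.  Deterministic and permutation-invariant.
    """
    m = np.asarray(mass_da, dtype=float)
    z = np.asarray(charge_e, dtype=float)
    if m.shape != z.shape:
        raise ValueError("mass and charge arrays must have equal length")
    labels = np.full(m.shape, "UNASSIGNED", dtype=object)
    unset = np.ones(m.shape, dtype=bool)

    if refs.dimer_da is not None:
        sel = unset & (np.abs(m - refs.dimer_da) <= gates.dimer_mass_window * refs.dimer_da)
        labels[sel] = "DIMER"
        unset &= ~sel
    sel = unset & (np.abs(m - refs.full_da) <= gates.full_mass_window * refs.full_da)
    labels[sel] = "INTACT_FULL"
    unset &= ~sel
    if refs.empty_da is not None:
        sel = unset & (np.abs(m - refs.empty_da) <= gates.empty_mass_window * refs.empty_da)
        labels[sel] = "EMPTY"
        unset &= ~sel
    sel = unset & (m > refs.full_da + gates.aggregate_min_excess_da)
    labels[sel] = "AGGREGATE"
    unset &= ~sel
    with np.errstate(invalid="ignore", divide="ignore"):
        zr = rayleigh_charge_for_mass(np.maximum(m, 0.0), consts)
        ratio = np.where(zr > 0, z / np.where(zr > 0, zr, 1.0), np.inf)
    lo, hi = gates.rayleigh_band
    sel = unset & (m < gates.fragment_mass_ceiling * refs.full_da) & (ratio >= lo) & (ratio <= hi)
    labels[sel] = "FRAGMENT"
    return labels.astype(str)


def classify_ions(
    measurements,
    expected,
    gates: PopulationGates = DEFAULT_GATES,
    consts: RayleighConstants = DEFAULT_CONSTANTS,
    vp_masses: VPMasses = DEFAULT_VP_MASSES,
) -> np.ndarray:
    """Classify measured ions against an expected species set.

    ``measurements`` may be a sequence of objects with ``mass_da`` /
    ``charge_e`` attributes or a DataFrame with those columns; ``expected``
    is a set of :class:`CapsidSpecies` (full required; a cargo-free monomer
    supplies the empty gate, a multiplicity-2 species the dimer gate) or a
    pre-computed :class:`ReferenceMasses`.  Returns one label per ion; an
    empty input yields an empty array.
    """
    refs = _references_from_species(expected, vp_masses)
    if hasattr(measurements, "columns"):
        m = measurements["mass_da"].to_numpy(dtype=float)
        z = measurements["charge_e"].to_numpy(dtype=float)
    else:
        m = np.array([x.mass_da for x in measurements], dtype=float)
        z = np.array([x.charge_e for x in measurements], dtype=float)
    return classify_masses_charges(m, z, refs, gates, consts)


def population_fractions(labels) -> dict[str, float]:
    """Fraction of ions per label; fractions sum to 1.  Empty input is an error."""
    arr = np.asarray(labels, dtype=str)
    if arr.size == 0:
        raise ValueError("labels must be nonempty")
    uniq, counts = np.unique(arr, return_counts=True)
    return {str(u): float(c) / arr.size for u, c in zip(uniq, counts)}


def estimate_bound_count(mass_da: float, base_mass_da: float, ligand_da: float) -> int:
    """Number of bound ligands from a mass increment, rounded to the nearest
    integer; negative estimates clamp to zero."""
    if ligand_da <= 0:
        raise ValueError("ligand_da must be strictly positive")
    n = int(round((mass_da - base_mass_da) / ligand_da))
    return max(n, 0)


def estimate_bound_counts(mass_da, base_mass_da: float, ligand_da: float) -> np.ndarray:
    """Vectorized :func:`estimate_bound_count`."""
    if ligand_da <= 0:
        raise ValueError("ligand_da must be strictly positive")
    n = np.rint((np.asarray(mass_da, dtype=float) - base_mass_da) / ligand_da).astype(int)
    return np.maximum(n, 0)


def charge_vs_bound_slope(measurements, base_mass_da: float, ligand_da: float):
    """OLS slope (e per bound ligand) and intercept of charge on bound count.

    The per-ion bound count is estimated from the mass increment over
    ``base_mass_da``.  Requires at least two distinct bound counts.
    """
    if hasattr(measurements, "columns"):
        m = measurements["mass_da"].to_numpy(dtype=float)
        z = measurements["charge_e"].to_numpy(dtype=float)
    else:
        m = np.array([x.mass_da for x in measurements], dtype=float)
        z = np.array([x.charge_e for x in measurements], dtype=float)
    n = estimate_bound_counts(m, base_mass_da, ligand_da)
    if np.unique(n).size < 2:
        raise ValueError("need at least two distinct bound counts for a slope")
    slope, intercept = np.polyfit(n.astype(float), z, 1)
    return float(slope), float(intercept)
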