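"""Deterministic mass accounting for AAV capsid species.

An AAV capsid is a 60-subunit shell of three viral proteins (VP1, VP2, VP3,
average stoichiometry ~1:1:10 with virion-to-virion variability) around a
single-stranded DNA cargo.  Species masses are additive:

    mass = multiplicity * (sum(vp_counts * vp_masses) + cargo) +
           adducts + n_ligand * ligand_mass

Nonvolatile-salt adduction is modelled as a single lump-sum mass offset
because only aggregate shifts are observable in the mass histograms; bound
ligands (e.g. a ~34 kDa nuclease) contribute integer multiples of their mass.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "VPMasses",
    "CapsidSpecies",
    "vp_counts_from_ratio",
    "sample_stoichiometry",
    "species_mass",
    "SPECIES_REGISTRY",
    "get_species",
]


@dataclass(frozen=True)
class VPMasses:
    """Masses of the three capsid proteins, in Da.

    Defaults are the rounded literature values for AAV9: VP1 83.5 kDa,
    VP2 68.6 kDa, VP3 62.0 kDa.
    """

    vp1_da: float = 83_500.0
    vp2_da: float = 68_600.0
    vp3_da: float = 62_000.0

    def __post_init__(self) -> None:
        for name in ("vp1_da", "vp2_da", "vp3_da"):
            if getattr(self, name) <= 0:
                raise ValueError(f"VPMasses.{name} must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.vp1_da, self.vp2_da, self.vp3_da])


DEFAULT_VP_MASSES = VPMasses()


@dataclass(frozen=True)
class CapsidSpecies:
    """One molecular species with a deterministic mass.

    ``vp_counts`` is the (n1, n2, n3) subunit triple; canonical capsids have
    n1+n2+n3 = 60 * multiplicity (fragments may violate this).  ``cargo_da``
    is the packaged DNA mass, ``adduct_da`` a lump-sum buffer-adduct offset,
    and ``n_ligand`` copies of a ``ligand_da`` ligand may be bound.
    ``multiplicity`` 2 denotes a capsid dimer.
    """

    vp_counts: tuple[int, int, int]
    cargo_da: float = 0.0
    adduct_da: float = 0.0
    n_ligand: int = 0
    ligand_da: float = 0.0
    multiplicity: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.vp_counts) != 3 or any(int(c) != c or c < 0 for c in self.vp_counts):
            raise ValueError("vp_counts must be a triple of non-negative integers")
        if self.cargo_da < 0 or self.adduct_da < 0 or self.ligand_da < 0:
            raise ValueError("mass fields must be non-negative")
        if self.n_ligand < 0:
            raise ValueError("n_ligand must be non-negative")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be a positive integer")

    def with_(self, **kwargs) -> "CapsidSpecies":
        return replace(self, **kwargs)


def vp_counts_from_ratio(total_subunits: int, ratio) -> tuple[int, int, int]:
    """Integer VP counts proportional to ``ratio`` summing to ``total_subunits``.

    Fractional parts are resolved by the largest-remainder method; remainder
    ties are broken toward VP3 (then VP2), which is the only scheme that maps
    every permutation of the 1:1:10 stoichiometry onto (5, 5, 50) at 60
    subunits.
    """
    if total_subunits <= 0:
        raise ValueError("total_subunits must be positive")
    r = np.asarray(ratio, dtype=float)
    if r.shape != (3,) or np.any(r < 0):
        raise ValueError("ratio must be a triple of non-negative weights")
    if not np.any(r > 0):
        raise ValueError("ratio must not be all zero")
    quota = total_subunits * r / r.sum()
    base = np.floor(quota).astype(int)
    remainder = int(total_subunits - base.sum())
    # sort by descending fractional part, ties toward the highest index (VP3)
    frac = quota - base
    order = sorted(range(3), key=lambda i: (-frac[i], -i))
    for i in order[:remainder]:
        base[i] += 1
    return tuple(int(c) for c in base)


def sample_stoichiometry(total_subunits: int, probs, seed: int) -> tuple[int, int, int]:
    """Multinomial draw of a VP stoichiometry; reproducible under ``seed``."""
    if total_subunits <= 0:
        raise ValueError("total_subunits must be positive")
    p = np.asarray(probs, dtype=float)
    if p.shape != (3,) or np.any(p < 0):
        raise ValueError("probs must be a triple of non-negative probabilities")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probs must sum to 1 within 1e-9")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(total_subunits, p / p.sum())
    return tuple(int(c) for c in counts)


def species_mass(species: CapsidSpecies, vp_masses: VPMasses = DEFAULT_VP_MASSES) -> float:
    """Total mass of ``species`` in Da.

    multiplicity * (sum(vp_counts * vp_masses) + cargo) + adducts +
    n_ligand * ligand_da.  Exactly additive in every field.
    """
    protein = float(np.dot(np.asarray(species.vp_counts, dtype=float), vp_masses.as_array()))
    return (
        species.multiplicity * (protein + species.cargo_da)
        + species.adduct_da
        + species.n_ligand * species.ligand_da
    )


#: Built-in species.  Masses with default VP masses:
#: AAV9_CMV_GFP 4.9105 MDa, VLP_CAG_GFP 4.560 MDa, AAV9_CAG_GFP 4.7005 MDa,
#: AAV9_empty 3.8605 MDa.
SPECIES_REGISTRY: dict[str, CapsidSpecies] = {
    "AAV9_CMV_GFP": CapsidSpecies(
        vp_counts=vp_counts_from_ratio(60, (1, 1, 10)), cargo_da=1.05e6, label="AAV9_CMV_GFP"
    ),
    "VLP_CAG_GFP": CapsidSpecies(vp_counts=(0, 0, 60), cargo_da=0.84e6, label="VLP_CAG_GFP"),
    "AAV9_CAG_GFP": CapsidSpecies(
        vp_counts=vp_counts_from_ratio(60, (1, 1, 10)), cargo_da=0.84e6, label="AAV9_CAG_GFP"
    ),
    "AAV9_empty": CapsidSpecies(
        vp_counts=vp_counts_from_ratio(60, (1, 1, 10)), cargo_da=0.0, label="AAV9_empty"
    ),
}


def get_species(name: str) -> CapsidSpecies:
    """Look up a registry species by name; raises with valid names listed."""
    try:
        return SPECIES_REGISTRY[name]
    except KeyError:
        valid = ", ".join(sorted(SPECIES_REGISTRY))
        raise KeyError(f"unknown species {name!r}; valid names: {valid}") from None
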