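"""System partitioning and QM/MM energy composition with electrostatic embedding.

The total potential is composed additively,

    V_potential = V_qm + V_qm/mm + V_mm,

where ``V_qm`` is the internal solute energy at the requested theory tier (its
gas-phase expression), ``V_mm`` the intermolecular water-water energy, and
``V_qm/mm`` the coupling term.  The coupling uses electrostatic embedding with
a distance cutoff around the QM region (default 15 Å): water molecules whose
oxygen lies strictly inside the cutoff of the nearest QM atom interact through
full Coulomb plus Lennard-Jones terms; molecules outside interact through
Coulomb only, against the solute's unscaled ESP charges.

The cutoff is group-based: each water is wholly inside or outside, judged by
its oxygen, so molecules are never split across the boundary.  The default
treatment is a non-periodic droplet (hard truncation, no Ewald).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calculators import (CalculatorError, SurrogateSolute, WaterModelParams,
                          lennard_jones, load_qm_lj_table, load_water_params,
                          water_water_energy)
from .constants import COULOMB_KCAL
from .geometry import GeometryError, Structure, element_of

__all__ = [
    "SimulationBox",
    "EmbeddingScheme",
    "EnergyDecomposition",
    "partition",
    "coupling_energy",
    "per_water_coupling",
    "compose_energy",
    "box_to_structure",
    "structure_to_waters",
    "solute_lj_params",
]


@dataclass
class SimulationBox:
    """A cubic box of rigid waters: ``waters`` has shape (n, 3, 3) = (O, H, H) × xyz."""

    length: float
    waters: np.ndarray
    periodic: bool = False
    water_params: WaterModelParams = field(default_factory=load_water_params)

    def __post_init__(self) -> None:
        self.waters = np.asarray(self.waters, dtype=float)
        if self.waters.ndim != 3 or self.waters.shape[1:] != (3, 3):
            raise CalculatorError("waters must have shape (n, 3, 3)")
        if self.periodic:
            if np.any(self.waters < 0) or np.any(self.waters >= self.length):
                raise CalculatorError("periodic box requires all sites in [0, L)^3")

    @property
    def n_waters(self) -> int:
        return self.waters.shape[0]

    def site_charges(self) -> np.ndarray:
        return np.tile(self.water_params.site_charges, self.n_waters)


@dataclass
class EmbeddingScheme:
    """Coupling rules: full (Coulomb+LJ) inside the cutoff, ESP-Coulomb outside.

    A water is inside iff its oxygen's distance to the *nearest* QM atom is
    strictly below ``cutoff`` (group-based membership; boundary tie-break is
    "outside").
    """

    cutoff: float = 15.0
    group_based: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise CalculatorError("cutoff must be positive")


@dataclass
class EnergyDecomposition:
    """The additive QM/MM energy decomposition, kcal·mol⁻¹."""

    v_qm: float
    v_qmmm: float
    v_mm: float
    v_potential: float

    @classmethod
    def compose(cls, v_qm: float, v_qmmm: float, v_mm: float) -> "EnergyDecomposition":
        return cls(v_qm, v_qmmm, v_mm, v_qm + v_qmmm + v_mm)


def partition(structure: Structure) -> tuple[Structure, Structure]:
    """Split a tagged structure into its (QM, MM) subsets.

    The subsets are disjoint and exhaustive; untagged atoms or an empty system
    are errors.
    """
    if len(structure) == 0:
        raise GeometryError("empty system cannot be partitioned")
    if structure.region is None:
        raise GeometryError("structure has no region tags")
    qm_idx = [i for i, r in enumerate(structure.region) if r == "QM"]
    mm_idx = [i for i, r in enumerate(structure.region) if r == "MM"]

    def subset(idx):
        return Structure(
            [structure.labels[i] for i in idx],
            structure.coords[idx].reshape(len(idx), 3),
            None if structure.charges is None else structure.charges[idx],
            np.array([structure.region[i] for i in idx], dtype=object)
            if idx else np.empty(0, dtype=object),
        )

    return subset(qm_idx), subset(mm_idx)


def solute_lj_params(labels: list[str],
                     table: dict[str, tuple[float, float]] | None = None) -> np.ndarray:
    """(σ, ε) per solute atom from the element-keyed parameter table."""
    table = table if table is not None else load_qm_lj_table()
    out = []
    for lb in labels:
        el = element_of(lb)
        if el not in table:
            raise CalculatorError(f"no Lennard-Jones parameters for QM atom {lb!r} "
                                  f"(element {el})")
        out.append(table[el])
    return np.array(out)


def per_water_coupling(solute_coords: np.ndarray,
                       esp_charges: np.ndarray,
                       lj: np.ndarray,
                       box: SimulationBox,
                       scheme: EmbeddingScheme):
    """Per-water coupling components against unscaled ESP charges.

    Returns ``(coul, lj_e, inside)``: for each water, its Coulomb energy with
    the solute's ESP charges (kcal/mol), its Lennard-Jones energy with the
    solute (zero when outside the cutoff), and its inside-cutoff flag.
    """
    solute_coords = np.asarray(solute_coords, dtype=float)
    waters = box.waters
    n = box.n_waters
    if n == 0:
        z = np.zeros(0)
        return z, z.copy(), np.zeros(0, dtype=bool)
    oxy = waters[:, 0, :]
    d_o_solute = np.linalg.norm(oxy[:, None, :] - solute_coords[None, :, :], axis=-1)
    inside = np.min(d_o_solute, axis=1) < scheme.cutoff

    # Coulomb: solute atoms x 3 water sites, per water
    sites = waters.reshape(n, 3, 1, 3)
    d = np.linalg.norm(sites - solute_coords[None, None, :, :], axis=-1)  # (n,3,m)
    if np.any(d < 0.1):
        raise CalculatorError("solute-water site overlap (r < 0.1 Å)")
    qw = box.water_params.site_charges  # (3,)
    coul = COULOMB_KCAL * np.einsum("s,m,nsm->n", qw, esp_charges, 1.0 / d)

    lj_e = np.zeros(n)
    if np.any(inside):
        sig = 0.5 * (lj[:, 0] + box.water_params.sigma_oo)   # (m,)
        eps = np.sqrt(lj[:, 1] * box.water_params.epsilon_oo)
        d_in = d_o_solute[inside]                             # (k, m)
        lj_e[inside] = np.sum(lennard_jones(d_in, sig[None, :], eps[None, :]),
                              axis=1)
    return coul, lj_e, inside


def coupling_energy(solute_coords: np.ndarray,
                    level_charges: np.ndarray,
                    esp_charges: np.ndarray,
                    lj: np.ndarray,
                    box: SimulationBox,
                    scheme: EmbeddingScheme) -> float:
    """The V_qm/mm coupling term, kcal·mol⁻¹.

    Inside the cutoff: Coulomb with the tier's (possibly polished) charges plus
    Lennard-Jones.  Outside: Coulomb only, against the unscaled ESP charges.
    """
    coul_esp, lj_e, inside = per_water_coupling(solute_coords, esp_charges, lj,
                                                box, scheme)
    if coul_esp.size == 0:
        return 0.0
    coul_lvl, _, _ = per_water_coupling(solute_coords, level_charges, lj, box,
                                        scheme)
    return float(np.sum(coul_lvl[inside]) + np.sum(coul_esp[~inside])
                 + np.sum(lj_e))


def compose_energy(solute: SurrogateSolute,
                   coords: np.ndarray,
                   level: str,
                   box: SimulationBox,
                   scheme: EmbeddingScheme,
                   lj_table: dict | None = None) -> EnergyDecomposition:
    """Full additive energy decomposition at a theory tier.

    ``V_potential = V_qm + V_qm/mm + V_mm`` holds exactly by construction.
    """
    coords = np.asarray(coords, dtype=float)
    try:
        v_qm = solute.internal_energy(coords, level)
    except Exception as exc:
        raise CalculatorError(f"V_qm evaluation failed: {exc}") from exc
    lj = solute_lj_params(solute.labels, lj_table)
    esp = solute.esp_charges(coords)
    lvl = solute.charges(coords, level)
    try:
        v_qmmm = coupling_energy(coords, lvl, esp, lj, box, scheme)
    except Exception as exc:
        raise CalculatorError(f"V_qm/mm evaluation failed: {exc}") from exc
    try:
        v_mm = water_water_energy(box.waters, box.water_params,
                                  cutoff=scheme.cutoff)
    except Exception as exc:
        raise CalculatorError(f"V_mm evaluation failed: {exc}") from exc
    return EnergyDecomposition.compose(v_qm, v_qmmm, v_mm)


# ---------------------------------------------------------------------------
# box <-> structure conversion (PDB plumbing)
# ---------------------------------------------------------------------------

def box_to_structure(box: SimulationBox) -> Structure:
    """Flatten a water box to a Structure (labels O/H1/H2, MM region tags)."""
    n = box.n_waters
    labels = []
    for _ in range(n):
        labels.extend(["O", "H1", "H2"])
    coords = box.waters.reshape(n * 3, 3)
    region = np.array(["MM"] * (n * 3), dtype=object)
    return Structure(labels, coords, charges=box.site_charges(), region=region)


def structure_to_waters(structure: Structure) -> np.ndarray:
    """Regroup a flat O,H,H,... site list into (n, 3, 3) water molecules."""
    if len(structure) % 3 != 0:
        raise CalculatorError("site count is not a multiple of 3")
    return structure.coords.reshape(-1, 3, 3)
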