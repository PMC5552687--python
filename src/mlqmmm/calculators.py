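"""Pluggable energy/force backends.

Three families of calculators stand behind the pipeline:

* analytic benchmark surfaces (Müller–Brown, used to validate the path
  optimizer against brute-force saddle searches);
* a rigid SPC/E-style explicit-water molecular-mechanics potential
  (Lennard-Jones on oxygens + Coulomb on all sites);
* a small reactive *surrogate solute* with one breakable bond, exposing three
  tiers of theory:

  - ``ESP``  — fixed-charge tier: conformation-dependent point charges only,
    internal energy frozen at a reference (0 by convention);
  - ``LOW``  — full internal force field (Morse + product well on the reactive
    pair, harmonic bonds/angles elsewhere);
  - ``HIGH`` — the LOW surface plus a bounded, differentiable Gaussian
    perturbation along the breakable-bond coordinate, emulating the shift from
    a cheap to an accurate electronic-structure description.

  The tiers also differ by a small multiplicative polish of the solute point
  charges (``level_scale``), so that level-shift free energies evaluated in a
  solvent ensemble are genuinely configuration dependent, as they are when an
  actual wavefunction polarizes in the solvent field.

Units: kcal·mol⁻¹, Å, e.  All analytic gradients are validated against central
finite differences in the test suite.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from .constants import COULOMB_KCAL
from .geometry import Structure

__all__ = [
    "CalculatorSpec",
    "EnergyResult",
    "WaterModelParams",
    "SurrogateSolute",
    "CalculatorError",
    "LEVELS",
    "lennard_jones",
    "coulomb",
    "morse",
    "MuellerBrown",
    "water_water_energy",
    "solute_energy",
    "evaluate",
    "load_water_params",
    "load_qm_lj_table",
    "finite_difference_gradient",
]

LEVELS = ("ESP", "LOW", "HIGH", "MM", "ANALYTIC")


class CalculatorError(ValueError):
    """Raised for invalid calculator configuration or non-finite energies."""


@dataclass(frozen=True)
class CalculatorSpec:
    """Which backend to evaluate and with which parameter table."""

    level: str
    parameters: dict = field(default_factory=dict)
    units: dict = field(default_factory=lambda: {
        "energy": "kcal/mol", "length": "angstrom", "charge": "e"})

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise CalculatorError(f"unknown level {self.level!r}; valid: {LEVELS}")


@dataclass
class EnergyResult:
    """Energy (kcal·mol⁻¹) and optional forces (kcal·mol⁻¹·Å⁻¹)."""

    energy: float
    forces: np.ndarray | None = None
    level: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.energy):
            raise CalculatorError(f"non-finite energy at level {self.level!r}")


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def lennard_jones(r, sigma: float, epsilon: float):
    """12-6 Lennard-Jones energy, zero exactly at r = σ."""
    sr6 = (sigma / np.asarray(r)) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6)


def coulomb(q1, q2, r):
    """Point-charge Coulomb energy with the fixed constant 332.0637."""
    return COULOMB_KCAL * np.asarray(q1) * np.asarray(q2) / np.asarray(r)


def morse(r, de: float, a: float, r0: float):
    """Morse potential with the minimum at −D_e and dissociation plateau 0−D_e→0."""
    x = 1.0 - np.exp(-a * (np.asarray(r) - r0))
    return de * x * x - de


def _morse_dVdr(r, de, a, r0):
    e = np.exp(-a * (r - r0))
    return 2.0 * de * a * (1.0 - e) * e


# ---------------------------------------------------------------------------
# water model
# ---------------------------------------------------------------------------

@dataclass
class WaterModelParams:
    """Rigid three-site water parameters (defaults: the standard SPC/E set)."""

    q_oxygen: float = -0.8476
    q_hydrogen: float = 0.4238
    sigma_oo: float = 3.166
    epsilon_oo: float = 0.1553
    r_oh: float = 1.0
    angle_hoh: float = 109.47

    def __post_init__(self) -> None:
        net = self.q_oxygen + 2.0 * self.q_hydrogen
        if abs(net) > 1e-10:
            raise CalculatorError(f"water molecule net charge {net} != 0")
        if self.sigma_oo <= 0 or self.epsilon_oo <= 0:
            raise CalculatorError("LJ sigma and epsilon must be positive")

    @property
    def site_charges(self) -> np.ndarray:
        return np.array([self.q_oxygen, self.q_hydrogen, self.q_hydrogen])


def _data_text(name: str) -> str:
    return (importlib.resources.files("mlqmmm") / "data" / name).read_text()


def load_water_params() -> WaterModelParams:
    """SPC/E constants from the versioned parameter file shipped with the package."""
    raw = yaml.safe_load(_data_text("spce.yaml"))
    raw.pop("version", None)
    return WaterModelParams(**raw)


def load_qm_lj_table() -> dict[str, tuple[float, float]]:
    """Element → (σ, ε) Lennard-Jones table for the solute coupling term."""
    raw = yaml.safe_load(_data_text("qm_lj.yaml"))
    return {el: (v["sigma"], v["epsilon"]) for el, v in raw["types"].items()}


def water_water_energy(waters: np.ndarray, params: WaterModelParams,
                       cutoff: float | None = None) -> float:
    """Total intermolecular energy of rigid waters, kcal·mol⁻¹.

    ``waters`` has shape (n, 3, 3): molecules × (O, H, H) × xyz.  Interactions
    are molecule-pairwise: O–O Lennard-Jones plus all-site Coulomb.  With a
    cutoff, a pair interacts fully iff its O–O distance is strictly below the
    cutoff (group-based hard truncation, no switching).
    """
    waters = np.asarray(waters, dtype=float)
    n = waters.shape[0]
    if n < 2:
        return 0.0
    oxy = waters[:, 0, :]
    doo = np.linalg.norm(oxy[:, None, :] - oxy[None, :, :], axis=-1)
    iu = np.triu_indices(n, k=1)
    pair_oo = doo[iu]
    include = np.ones(pair_oo.shape, dtype=bool) if cutoff is None else pair_oo < cutoff

    sites = waters.reshape(n * 3, 3)
    q = np.tile(params.site_charges, n)
    dss = np.linalg.norm(sites[:, None, :] - sites[None, :, :], axis=-1)
    mol = np.repeat(np.arange(n), 3)
    inter = mol[:, None] != mol[None, :]
    if np.any(dss[inter] < 0.1):
        raise CalculatorError("overlapping sites (r < 0.1 Å) between water molecules")

    # molecule-pair inclusion mask expanded to sites
    inc_mat = np.zeros((n, n), dtype=bool)
    inc_mat[iu] = include
    inc_mat |= inc_mat.T
    site_mask = inc_mat[mol[:, None], mol[None, :]] & inter
    siu = np.triu_indices(n * 3, k=1)
    mask_u = site_mask[siu]
    e_coul = float(np.sum(COULOMB_KCAL * (q[:, None] * q[None, :])[siu][mask_u]
                          / dss[siu][mask_u]))
    e_lj = float(np.sum(lennard_jones(pair_oo[include], params.sigma_oo,
                                      params.epsilon_oo)))
    return e_lj + e_coul


# ---------------------------------------------------------------------------
# Müller–Brown benchmark surface
# ---------------------------------------------------------------------------

class MuellerBrown:
    """The standard four-Gaussian Müller–Brown 2-D benchmark surface.

    Used only to validate the NEB optimizer and the finite-difference Hessian;
    its model units are arbitrary (not kcal/mol).
    """

    A = np.array([-200.0, -100.0, -170.0, 15.0])
    a = np.array([-1.0, -1.0, -6.5, 0.7])
    b = np.array([0.0, 0.0, 11.0, 0.6])
    c = np.array([-10.0, -10.0, -6.5, 0.7])
    x0 = np.array([1.0, 0.0, -0.5, -1.0])
    y0 = np.array([0.0, 0.5, 1.5, 1.0])

    def _terms(self, pt):
        x, y = pt
        dx, dy = x - self.x0, y - self.y0
        return self.A * np.exp(self.a * dx**2 + self.b * dx * dy + self.c * dy**2), dx, dy

    def energy(self, pt) -> float:
        t, _, _ = self._terms(np.asarray(pt, dtype=float))
        return float(np.sum(t))

    def gradient(self, pt) -> np.ndarray:
        t, dx, dy = self._terms(np.asarray(pt, dtype=float))
        gx = np.sum(t * (2.0 * self.a * dx + self.b * dy))
        gy = np.sum(t * (self.b * dx + 2.0 * self.c * dy))
        return np.array([gx, gy])

    def hessian(self, pt) -> np.ndarray:
        t, dx, dy = self._terms(np.asarray(pt, dtype=float))
        u = 2.0 * self.a * dx + self.b * dy
        v = self.b * dx + 2.0 * self.c * dy
        hxx = np.sum(t * (u * u + 2.0 * self.a))
        hyy = np.sum(t * (v * v + 2.0 * self.c))
        hxy = np.sum(t * (u * v + self.b))
        return np.array([[hxx, hxy], [hxy, hyy]])


def muller_brown(point) -> float:
    """Energy of the Müller–Brown surface at a 2-vector."""
    return MuellerBrown().energy(point)


# ---------------------------------------------------------------------------
# surrogate reactive solute
# ---------------------------------------------------------------------------

@dataclass
class SurrogateSolute:
    """A small reactive molecule with one breakable bond and three theory tiers.

    The reactive pair interacts through a Morse well (bound state) plus an
    attractive Gaussian "product well" at stretched separation, producing a
    double-well profile along the bond length r with a single barrier between
    the closed (reactant) and open (product) states.  The remaining skeleton is
    held by harmonic bonds and angles whose equilibria do not depend on r.

    ``HIGH`` adds a Gaussian bump (amplitude ``high_amp``) centred near the
    barrier top; ``ESP`` carries no internal energy (charges only).  Point
    charges interpolate linearly between the reactant-state and product-state
    ESP sets as a function of r, and each tier applies a small multiplicative
    ``level_scale`` polish to them.
    """

    labels: list[str]
    bonds: list[tuple[int, int, float, float]]            # (i, j, k, r0)
    angles: list[tuple[int, int, int, float, float]]      # (i, j, k, k_theta, theta0_deg)
    reactive_pair: tuple[int, int] = (1, 2)
    morse_de: float = 60.0
    morse_a: float = 2.0
    morse_r0: float = 1.47
    well_depth: float = 46.0
    well_center: float = 2.90
    well_width: float = 0.30
    high_amp: float = 2.5
    high_center: float = 2.30
    high_width: float = 0.25
    charges_reactant: np.ndarray = None
    charges_product: np.ndarray = None
    level_scale: dict = field(default_factory=lambda: {
        "ESP": 1.00, "LOW": 1.03, "HIGH": 1.05})

    def __post_init__(self) -> None:
        self.charges_reactant = np.asarray(self.charges_reactant, dtype=float)
        self.charges_product = np.asarray(self.charges_product, dtype=float)
        for q in (self.charges_reactant, self.charges_product):
            if q.shape != (len(self.labels),):
                raise CalculatorError("charge set length mismatch")

    # -- reactive-pair 1-D profile ------------------------------------------

    def reactive_distance(self, coords: np.ndarray) -> float:
        i, j = self.reactive_pair
        return float(np.linalg.norm(coords[j] - coords[i]))

    def bond_profile(self, r, level: str = "LOW"):
        """Internal energy contribution of the reactive pair at separation r."""
        r = np.asarray(r, dtype=float)
        e = morse(r, self.morse_de, self.morse_a, self.morse_r0)
        e = e - self.well_depth * np.exp(-((r - self.well_center) ** 2)
                                         / (2.0 * self.well_width ** 2))
        if level == "HIGH":
            e = e + self.high_perturbation(r)
        return e

    def high_perturbation(self, r):
        """The bounded, differentiable HIGH−LOW additive term along r."""
        r = np.asarray(r, dtype=float)
        return self.high_amp * np.exp(-((r - self.high_center) ** 2)
                                      / (2.0 * self.high_width ** 2))

    def _profile_dVdr(self, r: float, level: str) -> float:
        dv = _morse_dVdr(r, self.morse_de, self.morse_a, self.morse_r0)
        g = np.exp(-((r - self.well_center) ** 2) / (2.0 * self.well_width ** 2))
        dv += self.well_depth * (r - self.well_center) / self.well_width ** 2 * g
        if level == "HIGH":
            gb = np.exp(-((r - self.high_center) ** 2) / (2.0 * self.high_width ** 2))
            dv += -self.high_amp * (r - self.high_center) / self.high_width ** 2 * gb
        return float(dv)

    # -- full internal energy / gradient ------------------------------------

    def internal_energy(self, coords: np.ndarray, level: str = "LOW") -> float:
        """Internal (gas-phase) energy at a tier; ESP is frozen at 0."""
        self._check_level(level)
        if level == "ESP":
            return 0.0
        coords = np.asarray(coords, dtype=float)
        e = float(self.bond_profile(self.reactive_distance(coords), level))
        for i, j, k, r0 in self.bonds:
            d = np.linalg.norm(coords[j] - coords[i])
            e += k * (d - r0) ** 2
        for i, j, k, kt, t0 in self.angles:
            th = _angle_rad(coords[i], coords[j], coords[k])
            e += kt * (th - np.radians(t0)) ** 2
        return e

    def internal_gradient(self, coords: np.ndarray, level: str = "LOW") -> np.ndarray:
        self._check_level(level)
        coords = np.asarray(coords, dtype=float)
        g = np.zeros_like(coords)
        if level == "ESP":
            return g
        i, j = self.reactive_pair
        rij = coords[j] - coords[i]
        r = np.linalg.norm(rij)
        dv = self._profile_dVdr(r, level)
        u = rij / r
        g[j] += dv * u
        g[i] -= dv * u
        for bi, bj, k, r0 in self.bonds:
            rij = coords[bj] - coords[bi]
            d = np.linalg.norm(rij)
            dv = 2.0 * k * (d - r0)
            u = rij / d
            g[bj] += dv * u
            g[bi] -= dv * u
        for ai, aj, ak, kt, t0 in self.angles:
            th, (gi, gj, gk) = _angle_rad_grad(coords[ai], coords[aj], coords[ak])
            dv = 2.0 * kt * (th - np.radians(t0))
            g[ai] += dv * gi
            g[aj] += dv * gj
            g[ak] += dv * gk
        return g

    # -- charges -------------------------------------------------------------

    def esp_charges(self, coords: np.ndarray) -> np.ndarray:
        """Conformation-dependent ESP charges.

        Linear interpolation between the reactant and product charge sets as a
        function of the breakable-bond length, clamped outside the
        [morse_r0, well_center] range.
        """
        r = self.reactive_distance(np.asarray(coords, dtype=float))
        lam = np.clip((r - self.morse_r0) / (self.well_center - self.morse_r0),
                      0.0, 1.0)
        return (1.0 - lam) * self.charges_reactant + lam * self.charges_product

    def charges(self, coords: np.ndarray, level: str = "ESP") -> np.ndarray:
        self._check_level(level)
        return self.level_scale[level] * self.esp_charges(coords)

    @staticmethod
    def _check_level(level: str) -> None:
        if level not in ("ESP", "LOW", "HIGH"):
            raise CalculatorError(f"undefined solute level {level!r}")


def _angle_rad(p1, p2, p3) -> float:
    u, v = p1 - p2, p3 - p2
    c = np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0)
    return float(np.arccos(c))


def _angle_rad_grad(p1, p2, p3):
    """Angle at p2 (rad) and its Cartesian gradient w.r.t. the three atoms."""
    u, v = p1 - p2, p3 - p2
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    th = np.arccos(c)
    s = np.sqrt(max(1.0 - c * c, 1e-14))
    g1 = (c * u / nu - v / nv) / (nu * s)
    g3 = (c * v / nv - u / nu) / (nv * s)
    g2 = -(g1 + g3)
    return float(th), (g1, g2, g3)


def solute_energy(level: str, structure_or_coords, solute: SurrogateSolute,
                  forces: bool = False) -> EnergyResult:
    """Internal solute energy at a theory tier (gas-phase expression)."""
    coords = (structure_or_coords.coords
              if isinstance(structure_or_coords, Structure)
              else np.asarray(structure_or_coords, dtype=float))
    e = solute.internal_energy(coords, level)
    f = -solute.internal_gradient(coords, level) if forces else None
    return EnergyResult(energy=e, forces=f, level=level)


def evaluate(spec: CalculatorSpec, structure: Structure,
             forces: bool = False) -> EnergyResult:
    """Generic calculator dispatch for the closed level set.

    ``ESP``/``LOW``/``HIGH`` require ``spec.parameters["solute"]`` (a
    :class:`SurrogateSolute`); ``MM`` treats the structure's coordinates as
    rigid waters reshaped (n, 3, 3); ``ANALYTIC`` evaluates the Müller–Brown
    surface at the first atom's (x, y).
    """
    if spec.level in ("ESP", "LOW", "HIGH"):
        solute = spec.parameters.get("solute")
        if solute is None:
            raise CalculatorError("solute levels require parameters['solute']")
        if len(structure) != len(solute.labels):
            raise CalculatorError(
                f"atom count {len(structure)} does not match solute "
                f"({len(solute.labels)})")
        return solute_energy(spec.level, structure, solute, forces=forces)
    if spec.level == "MM":
        params = spec.parameters.get("water", load_water_params())
        waters = structure.coords.reshape(-1, 3, 3)
        e = water_water_energy(waters, params, spec.parameters.get("cutoff"))
        return EnergyResult(energy=e, level="MM")
    mb = MuellerBrown()
    pt = structure.coords[0, :2]
    f = None
    if forces:
        f = np.zeros_like(structure.coords)
        f[0, :2] = -mb.gradient(pt)
    return EnergyResult(energy=mb.energy(pt), forces=f, level="ANALYTIC")


def finite_difference_gradient(energy_fn, coords: np.ndarray,
                               h: float = 1e-5) -> np.ndarray:
    """Central-difference gradient, the independent check for analytic forces."""
    coords = np.asarray(coords, dtype=float)
    g = np.zeros_like(coords)
    flat = coords.ravel()
    gf = g.ravel()
    for k in range(flat.size):
        x0 = flat[k]
        flat[k] = x0 + h
        ep = energy_fn(coords)
        flat[k] = x0 - h
        em = energy_fn(coords)
        flat[k] = x0
        gf[k] = (ep - em) / (2.0 * h)
    return g
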