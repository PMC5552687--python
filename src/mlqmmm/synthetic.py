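"""Synthetic study systems: seeded water boxes, the surrogate reactive solute,
perturbed-geometry fixtures, and the shipped reference-value tables.

The generators define the study conditions of the pipeline:

* :func:`generate_box` places rigid waters uniformly in a cube under a minimum
  O–O distance constraint (rejection sampling), at the reference density of
  1752 molecules in a 37.5 Å cube (0.994 g·cm⁻³).  The desk-scale default used
  throughout the tests and the demo pipeline is 64 waters in a 12.4 Å cube —
  the same density, small enough that the full multi-level PMF runs in
  minutes.

* :func:`generate_solute` builds the surrogate ring-opening solute: a
  seven-atom model of the five-membered-ring fragment whose C8–N9 bond breaks,
  with a closed (reactant) minimum near r(C8–N9) = 1.47 Å and an open
  (product) minimum near 2.9 Å — echoing the 1.466 → 2.812 Å evolution of the
  real lesion — plus reactant/product ESP charge sets.

* :func:`reference_tables` loads the shipped tables of printed worked-example
  values (transition-state internal coordinates at two basis sets, energy
  decompositions, solvation free energies, rate orders); every entry carries a
  non-empty source note.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .calculators import SurrogateSolute, WaterModelParams, load_water_params
from .constants import AVOGADRO, WATER_MOLAR_MASS
from .geometry import Structure
from .qmmm import SimulationBox

__all__ = [
    "BoxSpec",
    "generate_box",
    "generate_solute",
    "perturb",
    "reference_tables",
    "water_template",
    "box_density",
]


@dataclass
class BoxSpec:
    """Specification of a cubic rigid-water box.

    The reference conditions are 1752 waters in a 37.5 Å cube.  The default
    minimum O–O placement distance of 2.4 Å avoids catastrophic Lennard-Jones
    overlaps while remaining feasible for random sequential placement at
    liquid density (the first peak of the liquid O–O distribution sits near
    2.8 Å; random placement cannot jam-pack spheres that large at 0.033 Å⁻³).
    """

    length: float = 37.5        # Å
    n_waters: int = 1752
    min_oo: float = 2.4         # Å
    seed: int = 0
    margin: float = 0.75        # Å, keeps H sites inside the box


def water_template(params: WaterModelParams | None = None) -> np.ndarray:
    """One rigid water (O at origin), shape (3, 3)."""
    p = params or load_water_params()
    half = np.radians(p.angle_hoh / 2.0)
    h1 = p.r_oh * np.array([np.sin(half), 0.0, np.cos(half)])
    h2 = p.r_oh * np.array([-np.sin(half), 0.0, np.cos(half)])
    return np.array([[0.0, 0.0, 0.0], h1, h2])


def box_density(n_waters: int, length: float) -> float:
    """Mass density in g·cm⁻³ of n waters in a cube of the given edge (Å)."""
    return n_waters * WATER_MOLAR_MASS / (AVOGADRO * (length * 1e-8) ** 3)


def _random_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform random rotation matrices (n, 3, 3) via normalized quaternions."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack([
        np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)], -1),
        np.stack([2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)], -1),
        np.stack([2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)], -1),
    ], axis=1)


def generate_box(spec: BoxSpec | None = None,
                 exclude: np.ndarray | None = None,
                 exclude_radius: float = 2.6,
                 params: WaterModelParams | None = None,
                 max_attempts_factor: int = 400) -> SimulationBox:
    """Rejection-sample a rigid-water box; deterministic given the seed.

    Oxygen positions are drawn uniformly inside the cube (respecting a wall
    margin) and accepted if at least ``spec.min_oo`` from every accepted
    oxygen and at least ``exclude_radius`` from every site in ``exclude``
    (e.g. a solute).  Orientations are uniform random rotations of the rigid
    template.  Placement failure raises with advice to reduce the count.
    """
    spec = spec or BoxSpec()
    params = params or load_water_params()
    rng = np.random.default_rng(spec.seed)
    rho = box_density(spec.n_waters, spec.length)
    if not 0.8 <= rho <= 1.2:
        warnings.warn(f"box density {rho:.3f} g/cm^3 outside [0.8, 1.2]",
                      stacklevel=2)
    lo, hi = spec.margin, spec.length - spec.margin
    accepted = np.empty((0, 3))
    attempts = 0
    max_attempts = max_attempts_factor * spec.n_waters
    exclude = None if exclude is None else np.asarray(exclude, dtype=float)
    while accepted.shape[0] < spec.n_waters:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"placed only {accepted.shape[0]}/{spec.n_waters} waters after "
                f"{attempts} attempts; reduce n_waters or min_oo")
        cand = rng.uniform(lo, hi, size=3)
        attempts += 1
        if accepted.size and np.min(
                np.linalg.norm(accepted - cand, axis=1)) < spec.min_oo:
            continue
        if exclude is not None and np.min(
                np.linalg.norm(exclude - cand, axis=1)) < exclude_radius:
            continue
        accepted = np.vstack([accepted, cand])
    tmpl = water_template(params)
    rots = _random_rotations(rng, spec.n_waters)
    waters = accepted[:, None, :] + np.einsum("nij,sj->nsi", rots, tmpl)
    waters = np.clip(waters, 0.0, np.nextafter(spec.length, 0.0))
    return SimulationBox(length=spec.length, waters=waters, periodic=False,
                         water_params=params)


# ---------------------------------------------------------------------------
# surrogate solute
# ---------------------------------------------------------------------------

_SOLUTE_LABELS = ["N7", "C8", "N9", "C4", "O10", "H8", "H10"]
# harmonic skeleton: (i, j, k [kcal/mol/Å²], r0 [Å])
_SOLUTE_BONDS = [
    (0, 1, 300.0, 1.38),   # N7-C8
    (2, 3, 300.0, 1.32),   # N9-C4
    (3, 0, 300.0, 1.36),   # C4-N7
    (1, 4, 300.0, 1.40),   # C8-O10
    (4, 6, 400.0, 0.97),   # O10-H10
    (1, 5, 350.0, 1.09),   # C8-H8
    (1, 3, 30.0, 2.20),    # soft C8···C4 1-3 restraint
]
# harmonic angles: (i, j, k, k_theta [kcal/mol/rad²], theta0 [deg])
_SOLUTE_ANGLES = [
    (0, 1, 4, 80.0, 118.0),   # N7-C8-O10
    (0, 1, 5, 60.0, 112.0),   # N7-C8-H8
    (4, 1, 5, 60.0, 108.0),   # O10-C8-H8
    (1, 4, 6, 70.0, 106.0),   # C8-O10-H10
]
_CHARGES_REACTANT = np.array([-0.40, 0.45, -0.50, 0.30, -0.55, 0.25, 0.45])
_CHARGES_PRODUCT = np.array([-0.45, 0.55, -0.60, 0.35, -0.50, 0.25, 0.40])

_REACTANT_GUESS = np.array([
    [0.55, 1.27, 0.00],    # N7
    [0.00, 0.00, 0.00],    # C8
    [1.47, 0.00, 0.00],    # N9
    [1.90, 1.25, 0.00],    # C4
    [-0.70, -1.17, 0.00],  # O10
    [-0.80, 0.65, 0.55],   # H8
    [-1.62, -1.25, 0.30],  # H10
])


def generate_solute(seed: int = 0, jitter: float = 0.0, **level_params):
    """Build the surrogate solute and its minimized endpoint structures.

    Returns ``(reactant, product, solute)`` where the endpoints are
    :class:`~mlqmmm.geometry.Structure` objects minimized on the LOW-tier
    internal surface (reactant in the closed basin, product in the open one)
    and ``solute`` carries the potential parameters and charge sets.
    ``level_params`` override any :class:`SurrogateSolute` field (e.g.
    ``high_amp``).  A nonzero ``jitter`` Gaussian-perturbs the starting guess
    before minimization (seeded), for basin-robustness studies.
    """
    solute = SurrogateSolute(
        labels=list(_SOLUTE_LABELS),
        bonds=list(_SOLUTE_BONDS),
        angles=list(_SOLUTE_ANGLES),
        reactive_pair=(1, 2),
        charges_reactant=_CHARGES_REACTANT.copy(),
        charges_product=_CHARGES_PRODUCT.copy(),
        **level_params,
    )
    rng = np.random.default_rng(seed)
    guess_r = _REACTANT_GUESS + (jitter * rng.normal(size=_REACTANT_GUESS.shape)
                                 if jitter > 0 else 0.0)
    reactant = _minimize(solute, guess_r)

    # open-basin guess: swing N9 away from C8 around C4 to r(C8-N9) ~ 2.9 Å
    guess_p = reactant.copy()
    c4, c8 = guess_p[3], guess_p[1]
    away = (c4 - c8) / np.linalg.norm(c4 - c8)
    guess_p[2] = c4 + 1.32 * away
    product = _minimize(solute, guess_p)
    template = Structure(list(_SOLUTE_LABELS), reactant)
    return (template.with_coords(reactant), template.with_coords(product),
            solute)


def _minimize(solute: SurrogateSolute, guess: np.ndarray) -> np.ndarray:
    res = minimize(
        lambda x: solute.internal_energy(x.reshape(-1, 3), "LOW"),
        guess.ravel(),
        jac=lambda x: solute.internal_gradient(x.reshape(-1, 3), "LOW").ravel(),
        method="L-BFGS-B",
        options={"maxiter": 5000, "gtol": 1e-9, "ftol": 1e-15})
    return res.x.reshape(-1, 3)


def perturb(structure: Structure, magnitude: float, seed: int = 0) -> Structure:
    """Add seeded isotropic Gaussian noise of the given σ (Å) per coordinate."""
    if magnitude < 0:
        raise ValueError("magnitude must be non-negative")
    if magnitude == 0:
        return structure.copy()
    rng = np.random.default_rng(seed)
    return structure.with_coords(
        structure.coords + rng.normal(0.0, magnitude, structure.coords.shape))


# ---------------------------------------------------------------------------
# reference tables
# ---------------------------------------------------------------------------

def reference_tables() -> dict:
    """The shipped worked-example reference tables (parsed JSON)."""
    import importlib.resources

    text = (importlib.resources.files("mlqmmm") / "data"
            / "reference_values.json").read_text()
    return json.loads(text)
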