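"""Nudged-elastic-band path optimization and transition-state verification.

A reaction path is a sequence of *beads* (replicas of the system) connecting a
fixed reactant endpoint to a fixed product endpoint.  Interior beads are
relaxed so that the force perpendicular to the local path tangent vanishes;
elastic springs between neighbours keep the beads spread out along the path.
The tangent is the energy-weighted "improved tangent" (upwinding between
neighbours), which suppresses kinks on steep surfaces.  After a warm-up the
highest-energy bead is switched to *climbing* mode — its spring force is
dropped and the parallel component of the true force is inverted — so it
converges onto the saddle point itself.

Relaxation uses FIRE-style projected-velocity damped dynamics with a step cap,
which is robust on coupled surfaces without a line search.

Transition states are verified by a central-difference Hessian: after mass
weighting and (optionally) projecting out rigid-body translations/rotations, a
first-order saddle must show exactly one imaginary vibrational mode.

Potentials are any objects exposing ``energy(x)`` and ``gradient(x)`` on flat
coordinate vectors.  The solution-phase convention of the pipeline is a
minimum-energy path with the solvent frozen: path optimization never samples
solvent degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import HESSIAN_EIGVAL_TO_OMEGA_SQ, SPEED_OF_LIGHT_CM

__all__ = [
    "Path",
    "NEBConfig",
    "FrequencyResult",
    "GasSolutePotential",
    "interpolate",
    "neb_relax",
    "frequencies",
]


class GasSolutePotential:
    """Adapter: gas-phase surrogate-solute internal surface at a theory tier."""

    def __init__(self, solute, level: str = "LOW"):
        self.solute = solute
        self.level = level

    def energy(self, x: np.ndarray) -> float:
        return self.solute.internal_energy(np.asarray(x).reshape(-1, 3), self.level)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return self.solute.internal_gradient(
            np.asarray(x).reshape(-1, 3), self.level).ravel()


@dataclass
class Path:
    """An ordered sequence of beads from reactant to product.

    ``beads`` is (N, d) with flat per-bead coordinates; ``energies`` and the
    cumulative Cartesian ``arc_lengths`` are filled by :func:`neb_relax`.
    """

    beads: np.ndarray
    energies: np.ndarray | None = None
    converged: bool = True
    n_iterations: int = 0

    def __post_init__(self) -> None:
        self.beads = np.asarray(self.beads, dtype=float)
        if self.beads.ndim != 2 or self.beads.shape[0] < 2:
            raise ValueError("a path needs at least 2 beads of equal dimension")

    @property
    def n_beads(self) -> int:
        return self.beads.shape[0]

    @property
    def arc_lengths(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.beads, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def highest_bead(self) -> int:
        if self.energies is None:
            raise ValueError("path has no energies; relax it first")
        return int(np.argmax(self.energies))


@dataclass
class NEBConfig:
    """Knobs of the band optimization (defaults suit the shipped surfaces)."""

    spring_k: float = 1.0          # kcal·mol⁻¹·Å⁻²
    climbing: bool = True
    climb_after: int = 50          # iterations before the top bead climbs
    max_iterations: int = 4000
    fmax: float = 0.05             # kcal·mol⁻¹·Å⁻¹, per-bead max-norm
    dt: float = 0.01               # FIRE initial time step
    max_step: float = 0.1          # Å, per-component displacement cap
    seed: int = 0                  # recorded for provenance

    def __post_init__(self) -> None:
        if self.fmax <= 0:
            raise ValueError("force threshold must be positive")


def interpolate(reactant, product, n_beads: int = 10) -> Path:
    """Linear Cartesian interpolation between two endpoints, inclusive."""
    r = np.asarray(getattr(reactant, "coords", reactant), dtype=float).ravel()
    p = np.asarray(getattr(product, "coords", product), dtype=float).ravel()
    if r.shape != p.shape:
        raise ValueError(f"endpoint size mismatch: {r.shape} vs {p.shape}")
    if n_beads < 2:
        raise ValueError("need at least 2 beads")
    if np.allclose(r, p):
        warnings.warn("identical endpoints: all beads coincide", stacklevel=2)
    t = np.linspace(0.0, 1.0, n_beads)[:, None]
    return Path((1.0 - t) * r[None, :] + t * p[None, :])


def _tangents(beads: np.ndarray, energies: np.ndarray) -> np.ndarray:
    """Energy-weighted improved tangents for interior beads (unit vectors)."""
    n = beads.shape[0]
    tau = np.zeros_like(beads)
    for i in range(1, n - 1):
        dplus = beads[i + 1] - beads[i]
        dminus = beads[i] - beads[i - 1]
        e0, ep, em = energies[i], energies[i + 1], energies[i - 1]
        if ep > e0 > em:
            t = dplus
        elif ep < e0 < em:
            t = dminus
        else:
            dmax = max(abs(ep - e0), abs(em - e0))
            dmin = min(abs(ep - e0), abs(em - e0))
            if ep > em:
                t = dplus * dmax + dminus * dmin
            else:
                t = dplus * dmin + dminus * dmax
        nrm = np.linalg.norm(t)
        tau[i] = t / nrm if nrm > 1e-12 else t
    return tau


def neb_relax(path: Path, potential, config: NEBConfig | None = None) -> Path:
    """Relax a band on a potential; endpoints stay bitwise fixed.

    Returns a new :class:`Path` with per-bead energies.  Non-convergence within
    ``max_iterations`` yields the partial result with ``converged=False`` plus
    a warning, never a silent failure.
    """
    config = config or NEBConfig()
    beads = path.beads.copy()
    n, d = beads.shape
    if n < 3:
        energies = np.array([potential.energy(b) for b in beads])
        return Path(beads, energies, converged=True, n_iterations=0)

    # FIRE state over all interior beads
    v = np.zeros((n - 2, d))
    dt = config.dt
    alpha = 0.1
    n_pos = 0
    climb_idx = -1
    converged = False
    it = 0

    energies = np.array([potential.energy(b) for b in beads])
    grads = np.array([potential.gradient(b) for b in beads])

    for it in range(1, config.max_iterations + 1):
        if config.climbing and it > config.climb_after:
            climb_idx = int(np.argmax(energies[1:-1])) + 1
        tau = _tangents(beads, energies)

        forces = np.zeros((n - 2, d))
        resid = np.zeros(n - 2)
        for k, i in enumerate(range(1, n - 1)):
            g = grads[i]
            t = tau[i]
            g_par = np.dot(g, t) * t
            f_perp = -(g - g_par)
            if i == climb_idx:
                f = -g + 2.0 * g_par
            else:
                spring = config.spring_k * (
                    np.linalg.norm(beads[i + 1] - beads[i])
                    - np.linalg.norm(beads[i] - beads[i - 1]))
                f = f_perp + spring * t
            # residual includes the spring component so the band both relaxes
            # perpendicular forces and equalizes bead spacing
            resid[k] = np.max(np.abs(f))
            forces[k] = f

        if np.max(resid) <= config.fmax:
            converged = True
            break

        # FIRE update
        p = float(np.sum(forces * v))
        fnorm = np.linalg.norm(forces)
        if p > 0:
            vnorm = np.linalg.norm(v)
            v = (1.0 - alpha) * v + alpha * vnorm * forces / max(fnorm, 1e-12)
            n_pos += 1
            if n_pos > 5:
                dt = min(dt * 1.1, 10.0 * config.dt)
                alpha *= 0.99
        else:
            v[:] = 0.0
            dt *= 0.5
            alpha = 0.1
            n_pos = 0
        v = v + dt * forces
        step = np.clip(dt * v, -config.max_step, config.max_step)
        beads[1:-1] += step

        for i in range(1, n - 1):
            energies[i] = potential.energy(beads[i])
            grads[i] = potential.gradient(beads[i])

    if not converged:
        warnings.warn(
            f"NEB did not converge in {config.max_iterations} iterations "
            f"(residual {np.max(resid):.3g} > {config.fmax}); returning partial "
            "result", stacklevel=2)
    return Path(beads, energies, converged=converged, n_iterations=it)


# ---------------------------------------------------------------------------
# frequency analysis
# ---------------------------------------------------------------------------

@dataclass
class FrequencyResult:
    """Mass-weighted Hessian eigenvalues and vibrational frequencies.

    ``frequencies_cm`` are in cm⁻¹ with imaginary modes reported as negative
    numbers; ``eigenvalues`` are in kcal·mol⁻¹·Å⁻²·amu⁻¹ (or model units for
    unit masses).  Rigid-body modes, when projected out, are excluded from the
    imaginary count.
    """

    eigenvalues: np.ndarray
    frequencies_cm: np.ndarray
    n_imaginary: int
    warning: str | None = None


def _numerical_hessian(potential, x: np.ndarray, step: float) -> np.ndarray:
    d = x.size
    h = np.zeros((d, d))
    for k in range(d):
        xp = x.copy(); xp[k] += step
        xm = x.copy(); xm[k] -= step
        h[:, k] = (potential.gradient(xp) - potential.gradient(xm)) / (2.0 * step)
    return 0.5 * (h + h.T)  # enforce symmetry


def _rigid_body_modes(coords: np.ndarray, sqrt_m: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted translation/rotation vectors, shape (k, 3n)."""
    n = coords.shape[0]
    modes = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        modes.append((t * sqrt_m[:, None]).ravel())
    com = np.sum(coords * (sqrt_m**2)[:, None], axis=0) / np.sum(sqrt_m**2)
    rel = coords - com
    for ax in range(3):
        e = np.zeros(3); e[ax] = 1.0
        r = np.cross(rel, e) * sqrt_m[:, None]
        modes.append(r.ravel())
    q, r = np.linalg.qr(np.array(modes).T)
    keep = np.abs(np.diag(r)) > 1e-8
    return q[:, keep].T


def frequencies(potential, x: np.ndarray, masses: np.ndarray | None = None,
                step: float = 0.005, project_rigid: bool = False,
                force_tolerance: float = 0.5) -> FrequencyResult:
    """Finite-difference normal-mode analysis at a (near-)stationary point.

    ``masses`` is per-atom (amu) for 3n Cartesian coordinates or omitted for
    unit masses (analytic model surfaces).  A non-stationary input (force norm
    above ``force_tolerance``) annotates the result with a warning rather than
    failing.
    """
    x = np.asarray(x, dtype=float).ravel()
    warning = None
    gnorm = float(np.linalg.norm(potential.gradient(x)))
    if gnorm > force_tolerance:
        warning = (f"input is not stationary (|grad| = {gnorm:.3g}); "
                   "frequencies are unreliable")
        warnings.warn(warning, stacklevel=2)

    hess = _numerical_hessian(potential, x, step)
    if masses is not None:
        masses = np.asarray(masses, dtype=float)
        if x.size != 3 * masses.size:
            raise ValueError("masses must be per-atom for 3n coordinates")
        sqrt_m = np.sqrt(masses)
        mw = np.repeat(sqrt_m, 3)
        hess = hess / np.outer(mw, mw)
    else:
        sqrt_m = None

    n_rigid = 0
    if project_rigid:
        if masses is None or x.size % 3 != 0:
            raise ValueError("rigid-body projection needs per-atom masses and "
                             "3n coordinates")
        modes = _rigid_body_modes(x.reshape(-1, 3), sqrt_m)
        n_rigid = modes.shape[0]
        proj = np.eye(x.size) - modes.T @ modes
        hess = proj @ hess @ proj

    eigvals = np.linalg.eigvalsh(hess)
    scale = max(1.0, float(np.max(np.abs(eigvals))))
    tol = 1e-6 * scale
    if project_rigid:
        # drop the projected-out (near-zero) rigid modes
        order = np.argsort(np.abs(eigvals))
        drop = set(order[:n_rigid])
        eigvals = np.array([ev for k, ev in enumerate(eigvals) if k not in drop])

    freqs = np.empty_like(eigvals)
    if masses is not None:
        omega = np.sqrt(np.abs(eigvals) * HESSIAN_EIGVAL_TO_OMEGA_SQ)
        freqs = np.sign(eigvals) * omega / (2.0 * np.pi * SPEED_OF_LIGHT_CM)
    else:
        freqs = np.sign(eigvals) * np.sqrt(np.abs(eigvals))
    n_imag = int(np.sum(eigvals < -tol))
    return FrequencyResult(eigenvalues=eigvals, frequencies_cm=freqs,
                           n_imaginary=n_imag, warning=warning)
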