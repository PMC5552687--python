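"""Potential-of-mean-force machinery: solvent sampling, free-energy
perturbation level shifts, multi-level composition, and solvent decomposition.

The free-energy profile along the reaction path is built in three tiers:

1.  ``ESP`` PMF.  With the solute frozen at each path bead and carrying its
    cheap fixed (ESP) charges, rigid-water Metropolis Monte Carlo generates a
    canonical solvent ensemble.  The profile increment between adjacent beads
    A→B is the Zwanzig exponential average of perturbing the frozen solute from
    A to B inside A's ensemble, plus the solute's gas-phase ESP energy change
    (zero for a charges-only tier), so the zero-coupling limit reduces exactly
    to the gas profile.

2.  Level shifts.  At every bead the free energy of switching the solute tier
    at *fixed* solute configuration — ESP→LOW sampled in the ESP ensemble,
    LOW→HIGH sampled in the LOW ensemble — is estimated with the one-sided
    Zwanzig formula ΔW = −kT·ln⟨exp(−ΔU/kT)⟩.

3.  Composition.  The high-tier profile is the ESP profile plus the per-bead
    level-shift *differences* relative to the reactant bead,

        W^HIGH(B) = W^ESP(B) + [ΔW^{LOW←ESP}_BB − ΔW^{LOW←ESP}_AA]
                             + [ΔW^{HIGH←LOW}_BB − ΔW^{HIGH←LOW}_AA],

    with A fixed at the reactant bead.  The identity is exact in the
    infinite-sampling limit, which is verified against a directly sampled
    high-tier PMF (:func:`direct_pmf`) in the acceptance tests.

Every ensemble is sampled as several independent chains; free-energy standard
errors are estimated *between* chains, which captures slow solvent
correlations that within-chain block averaging cannot see.  A variance-based
overlap guard rejects perturbations too large for one-sided exponential
averaging.  All randomness fans out deterministically from one master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .calculators import SurrogateSolute, lennard_jones, water_water_energy
from .constants import COULOMB_KCAL, DEFAULT_TEMPERATURE, kT as thermal_energy
from .qmmm import EmbeddingScheme, SimulationBox, solute_lj_params

__all__ = [
    "SamplerConfig",
    "Ensemble",
    "FEPResult",
    "MultiLevelPMF",
    "SolventDecomposition",
    "OverlapError",
    "sample_solvent",
    "sample_solvent_chains",
    "sample_path_ensembles",
    "equilibrate_box",
    "path_boxes",
    "metropolis_sample",
    "zwanzig",
    "zwanzig_chains",
    "pmf_esp",
    "level_shift",
    "compose",
    "direct_pmf",
    "multi_level_pmf",
    "decompose_solvent",
    "bead_seed",
]

_LEVEL_ID = {"ESP": 1, "LOW": 2, "HIGH": 3}


class OverlapError(RuntimeError):
    """Perturbation too large for one-sided exponential averaging."""


@dataclass
class SamplerConfig:
    """Canonical rigid-water Monte Carlo settings.

    Move set: single-molecule rigid translations (uniform in a cube of half
    width ``max_translation``) plus rotation about the oxygen by a uniform
    angle up to ``max_rotation`` about a random axis.
    """

    temperature: float = DEFAULT_TEMPERATURE  # K
    n_equilibration: int = 600                # sweeps (1 sweep = n_water moves)
    n_production: int = 1500
    stride: int = 10                          # sweeps between stored samples
    max_translation: float = 0.18             # Å
    max_rotation: float = 22.0                # degrees
    teleport_fraction: float = 0.0            # fraction of relocation moves
                                              # (useful only below liquid density)
    n_chains: int = 3                         # independent chains per ensemble
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_production < 1:
            raise ValueError("need at least one production sweep")
        if not 0.0 <= self.teleport_fraction < 1.0:
            raise ValueError("teleport fraction must be in [0, 1)")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @property
    def kT(self) -> float:
        return thermal_energy(self.temperature)


@dataclass
class Ensemble:
    """Stored solvent configurations around one frozen solute bead.

    ``coul_in``/``coul_out`` are the ESP-charge Coulomb coupling sums over
    inside-/outside-cutoff waters and ``lj`` the Lennard-Jones coupling, all
    per stored configuration and evaluated at the ensemble's own bead geometry.
    """

    bead_coords: np.ndarray
    level: str
    configs: np.ndarray           # (m, n, 3, 3)
    coul_in: np.ndarray           # (m,)
    coul_out: np.ndarray          # (m,)
    lj: np.ndarray                # (m,)
    e_ww: np.ndarray              # (m,)
    acceptance_rate: float = 0.0
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.configs.shape[0]


@dataclass
class FEPResult:
    """A free-energy estimate with its block-averaged standard error."""

    value: float
    se: float


def bead_seed(master_seed: int, bead: int, level: str,
              window: int = 0) -> np.random.Generator:
    """Deterministic per-(bead, level, window) RNG from one master seed."""
    ss = np.random.SeedSequence([int(master_seed) % (2**31), int(bead),
                                 _LEVEL_ID.get(level, 0), int(window)])
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def zwanzig(delta_u: np.ndarray, kt: float, n_blocks: int = 10,
            check_overlap: bool = True) -> FEPResult:
    """One-sided exponential (Zwanzig) free-energy estimator.

    ΔW = −kT·ln⟨exp(−ΔU/kT)⟩ with the standard error from ``n_blocks`` block
    means.  When the variance of ΔU/kT exceeds 25, phase-space overlap is too
    poor for a one-sided estimate and :class:`OverlapError` is raised (the cure
    is more intermediate states, i.e. more beads).
    """
    du = np.asarray(delta_u, dtype=float)
    if du.size == 0:
        raise ValueError("no samples")
    x = du / kt
    if check_overlap and du.size > 1 and float(np.var(x)) > 25.0:
        raise OverlapError(
            f"exponent variance {np.var(x):.1f} kT² exceeds 25; insert more "
            "beads (smaller perturbation steps)")
    # factor out the minimum for numerical stability of the exponential mean
    x0 = float(np.min(x))
    w = np.exp(-(x - x0))
    mean_w = float(np.mean(w))
    value = kt * (x0 - np.log(mean_w))
    if du.size >= n_blocks and n_blocks > 1:
        m = (du.size // n_blocks) * n_blocks
        blocks = w[:m].reshape(n_blocks, -1).mean(axis=1)
        se = kt * float(np.std(blocks, ddof=1)) / (mean_w * np.sqrt(n_blocks))
    else:
        se = kt * float(np.std(w, ddof=1) / max(np.sqrt(du.size), 1.0)) / mean_w
    return FEPResult(value=float(value), se=float(se))


def metropolis_sample(energy_fn, x0: np.ndarray, step: float, n_samples: int,
                      kt: float, seed: int = 0, n_burn: int = 100,
                      stride: int = 1):
    """Generic single-particle Metropolis sampler (calibration utility).

    Samples a vector state with isotropic uniform proposal steps; returns the
    array of stored states.  Used to validate the sampling kernel against
    closed-form ensemble moments on analytic potentials.
    """
    rng = np.random.default_rng(seed)
    x = np.array(x0, dtype=float)
    e = float(energy_fn(x))
    out = []
    n_total = n_burn + n_samples * stride
    for it in range(n_total):
        prop = x + rng.uniform(-step, step, size=x.shape)
        ep = float(energy_fn(prop))
        if ep <= e or rng.random() < np.exp(-(ep - e) / kt):
            x, e = prop, ep
        if it >= n_burn and (it - n_burn) % stride == 0:
            out.append(x.copy())
    return np.array(out)


# ---------------------------------------------------------------------------
# rigid-water Metropolis sampling around a frozen solute
# ---------------------------------------------------------------------------

try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba ships with the environment
    def _njit(*a, **k):
        def deco(fn):
            return fn
        return deco if not (a and callable(a[0])) else a[0]


@_njit(cache=False)
def _sweep_kernel(waters, coul, lj, inside, idx, disp, axes, angles, u_acc,
                  teleport, targets, sol_xyz, esp_q, sig, eps, qw, sigma_oo,
                  eps_oo, cutoff, ww_cutoff, scale, length, kt):
    """One Monte-Carlo sweep over rigid waters; updates state in place.

    Two proposal kinds: local rigid translation+rotation, and (with the
    configured probability) a *teleport* — relocation of the whole molecule to
    a uniform random position with a fresh orientation, which accelerates
    solvent-shell exchange enormously at a small acceptance cost.  Returns the
    number of accepted moves.  All randomness is pre-drawn by the caller so
    the trajectory is fully determined by the generator seed.
    """
    n = waters.shape[0]
    m = sol_xyz.shape[0]
    accepted = 0
    new = np.empty((3, 3))
    for k in range(idx.shape[0]):
        i = idx[k]
        # propose: translate, then rotate H sites about the O
        ax = axes[k]
        nrm = np.sqrt(ax[0]**2 + ax[1]**2 + ax[2]**2)
        ux, uy, uz = ax[0] / nrm, ax[1] / nrm, ax[2] / nrm
        c = np.cos(angles[k])
        s = np.sin(angles[k])
        oc = 1.0 - c
        r00 = c + ux * ux * oc
        r01 = ux * uy * oc - uz * s
        r02 = ux * uz * oc + uy * s
        r10 = uy * ux * oc + uz * s
        r11 = c + uy * uy * oc
        r12 = uy * uz * oc - ux * s
        r20 = uz * ux * oc - uy * s
        r21 = uz * uy * oc + ux * s
        r22 = c + uz * uz * oc
        if teleport[k]:
            for a in range(3):
                for x in range(3):
                    new[a, x] = targets[k, x] + (waters[i, a, x]
                                                 - waters[i, 0, x])
        else:
            for a in range(3):
                for x in range(3):
                    new[a, x] = waters[i, a, x] + disp[k, x]
        for a in range(1, 3):
            vx = new[a, 0] - new[0, 0]
            vy = new[a, 1] - new[0, 1]
            vz = new[a, 2] - new[0, 2]
            new[a, 0] = new[0, 0] + r00 * vx + r01 * vy + r02 * vz
            new[a, 1] = new[0, 1] + r10 * vx + r11 * vy + r12 * vz
            new[a, 2] = new[0, 2] + r20 * vx + r21 * vy + r22 * vz
        ok = True
        for a in range(3):
            for x in range(3):
                if new[a, x] < 0.0 or new[a, x] >= length:
                    ok = False
        if not ok:
            continue
        # water-water energy of molecule i, old and new
        e_old = 0.0
        e_new = 0.0
        for j in range(n):
            if j == i:
                continue
            do_old = 0.0
            do_new = 0.0
            for x in range(3):
                do_old += (waters[j, 0, x] - waters[i, 0, x])**2
                do_new += (waters[j, 0, x] - new[0, x])**2
            do_old = np.sqrt(do_old)
            do_new = np.sqrt(do_new)
            if ww_cutoff <= 0.0 or do_old < ww_cutoff:
                sr6 = (sigma_oo / do_old)**6
                e_old += 4.0 * eps_oo * (sr6 * sr6 - sr6)
                for a in range(3):
                    for b in range(3):
                        d2 = 0.0
                        for x in range(3):
                            d2 += (waters[j, b, x] - waters[i, a, x])**2
                        e_old += 332.0637 * qw[a] * qw[b] / np.sqrt(d2)
            if ww_cutoff <= 0.0 or do_new < ww_cutoff:
                sr6 = (sigma_oo / do_new)**6
                e_new += 4.0 * eps_oo * (sr6 * sr6 - sr6)
                for a in range(3):
                    for b in range(3):
                        d2 = 0.0
                        for x in range(3):
                            d2 += (waters[j, b, x] - new[a, x])**2
                        e_new += 332.0637 * qw[a] * qw[b] / np.sqrt(d2)
        # solute coupling of the proposed position
        c_new = 0.0
        dmin = 1e30
        for a in range(m):
            d2o = 0.0
            for x in range(3):
                d2o += (sol_xyz[a, x] - new[0, x])**2
            do = np.sqrt(d2o)
            if do < dmin:
                dmin = do
            for b in range(3):
                d2 = 0.0
                for x in range(3):
                    d2 += (sol_xyz[a, x] - new[b, x])**2
                c_new += 332.0637 * qw[b] * esp_q[a] / np.sqrt(d2)
        in_new = dmin < cutoff
        l_new = 0.0
        if in_new:
            for a in range(m):
                d2o = 0.0
                for x in range(3):
                    d2o += (sol_xyz[a, x] - new[0, x])**2
                do = np.sqrt(d2o)
                sr6 = (sig[a] / do)**6
                l_new += 4.0 * eps[a] * (sr6 * sr6 - sr6)
        c_old_lvl = (scale * coul[i] if inside[i] else coul[i]) + lj[i]
        c_new_lvl = (scale * c_new if in_new else c_new) + l_new
        de = (e_new - e_old) + (c_new_lvl - c_old_lvl)
        if de <= 0.0 or u_acc[k] < np.exp(-de / kt):
            for a in range(3):
                for x in range(3):
                    waters[i, a, x] = new[a, x]
            coul[i] = c_new
            lj[i] = l_new
            inside[i] = in_new
            accepted += 1
    return accepted


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) * c + s * K + (1 - c) * np.outer(axis, axis)


def _mol_env_energy(sites_flat, q_flat, oxy, i, mol_sites, params, cutoff):
    """Interaction energy of molecule i (at ``mol_sites``) with all others."""
    d = np.linalg.norm(mol_sites[:, None, :] - sites_flat[None, :, :], axis=-1)
    d[:, 3 * i:3 * i + 3] = np.inf
    d_oo = np.linalg.norm(oxy - mol_sites[0], axis=1)
    d_oo[i] = np.inf
    if cutoff is not None:
        inc = np.repeat(d_oo < cutoff, 3)
        d = np.where(inc[None, :], d, np.inf)
        d_oo = np.where(d_oo < cutoff, d_oo, np.inf)
    e_c = COULOMB_KCAL * float(
        np.sum(params.site_charges[:, None] * q_flat[None, :] / d))
    sr6 = (params.sigma_oo / d_oo) ** 6
    e_lj = float(np.sum(4.0 * params.epsilon_oo * (sr6 * sr6 - sr6)))
    return e_c + e_lj


def _solute_coupling_one(mol_sites, solute_coords, esp_q, sig, eps, qw, cutoff):
    """(coul, lj, inside) of one water against the frozen solute."""
    d = np.linalg.norm(mol_sites[:, None, :] - solute_coords[None, :, :], axis=-1)
    coul = COULOMB_KCAL * float(np.sum(qw[:, None] * esp_q[None, :] / d))
    d_o = np.linalg.norm(solute_coords - mol_sites[0], axis=1)
    inside = bool(np.min(d_o) < cutoff)
    lj = float(np.sum(lennard_jones(d_o, sig, eps))) if inside else 0.0
    return coul, lj, inside


def batch_coupling(configs: np.ndarray, solute_coords: np.ndarray,
                   esp_charges: np.ndarray, lj_params: np.ndarray,
                   box: SimulationBox, scheme: EmbeddingScheme):
    """Coupling sums for a batch of stored configs at a given solute geometry.

    Returns ``(coul_in, coul_out, lj)`` arrays of length m, using unscaled ESP
    charges for the Coulomb part (tier polish is applied by the callers).
    """
    configs = np.asarray(configs, dtype=float)
    m, n = configs.shape[0], configs.shape[1]
    solute_coords = np.asarray(solute_coords, dtype=float)
    qw = box.water_params.site_charges
    sites = configs.reshape(m, n * 3, 3)
    d = np.linalg.norm(sites[:, :, None, :] - solute_coords[None, None, :, :],
                       axis=-1)  # (m, 3n, a)
    q2 = np.tile(qw, n)
    coul_site = COULOMB_KCAL * np.einsum("s,a,msa->ms", q2, esp_charges, 1.0 / d)
    coul_mol = coul_site.reshape(m, n, 3).sum(axis=2)
    d_o = np.linalg.norm(configs[:, :, 0, None, :]
                         - solute_coords[None, None, :, :], axis=-1)  # (m,n,a)
    inside = np.min(d_o, axis=2) < scheme.cutoff
    sig = 0.5 * (lj_params[:, 0] + box.water_params.sigma_oo)
    eps = np.sqrt(lj_params[:, 1] * box.water_params.epsilon_oo)
    lj_mol = np.sum(lennard_jones(d_o, sig[None, None, :], eps[None, None, :]),
                    axis=2) * inside
    coul_in = np.sum(coul_mol * inside, axis=1)
    coul_out = np.sum(coul_mol * ~inside, axis=1)
    lj = np.sum(lj_mol, axis=1)
    return coul_in, coul_out, lj


def coupling_at_level(coul_in, coul_out, lj, solute: SurrogateSolute, level: str):
    """Total coupling energy at a tier from the stored ESP-charge components."""
    s = solute.level_scale[level]
    return s * np.asarray(coul_in) + np.asarray(coul_out) + np.asarray(lj)


def sample_solvent(bead_coords: np.ndarray, solute: SurrogateSolute,
                   box: SimulationBox, cfg: SamplerConfig,
                   scheme: EmbeddingScheme | None = None,
                   level: str = "ESP",
                   lj_table: dict | None = None) -> Ensemble:
    """Canonical Metropolis ensemble of rigid waters around a frozen solute.

    The solute is frozen at ``bead_coords`` and couples at the given tier
    (tier charge polish times ESP Coulomb, plus Lennard-Jones inside the
    cutoff).  The trajectory is fully determined by ``cfg.seed``.  Moves that
    would take any water site outside the box are rejected (hard-wall droplet
    container).
    """
    scheme = scheme or EmbeddingScheme()
    rng = np.random.default_rng(cfg.seed)
    kt = cfg.kT
    waters = box.waters.copy()
    n = waters.shape[0]
    if n == 0:
        raise ValueError("empty box")
    bead_coords = np.asarray(bead_coords, dtype=float)
    esp_q = solute.esp_charges(bead_coords)
    scale = solute.level_scale[level]
    lj_p = solute_lj_params(solute.labels, lj_table)
    sig = 0.5 * (lj_p[:, 0] + box.water_params.sigma_oo)
    eps = np.sqrt(lj_p[:, 1] * box.water_params.epsilon_oo)
    qw = box.water_params.site_charges
    cutoff = scheme.cutoff
    ww_cutoff = scheme.cutoff if scheme.cutoff < box.length * np.sqrt(3) else None

    coul = np.zeros(n)
    lj = np.zeros(n)
    inside = np.zeros(n, dtype=bool)
    for i in range(n):
        coul[i], lj[i], inside[i] = _solute_coupling_one(
            waters[i], bead_coords, esp_q, sig, eps, qw, cutoff)

    rot_max = np.radians(cfg.max_rotation)
    n_sweeps = cfg.n_equilibration + cfg.n_production
    accepted = attempted = 0
    samples, s_ci, s_co, s_lj, s_ww = [], [], [], [], []
    ww_cut = -1.0 if ww_cutoff is None else float(ww_cutoff)

    for sweep in range(n_sweeps):
        idx = rng.integers(n, size=n)
        disp = rng.uniform(-cfg.max_translation, cfg.max_translation, (n, 3))
        axes = rng.normal(size=(n, 3))
        angles = rng.uniform(-rot_max, rot_max, n)
        u_acc = rng.random(n)
        teleport = rng.random(n) < cfg.teleport_fraction
        targets = rng.uniform(0.0, box.length, (n, 3))
        big = rng.uniform(-np.pi, np.pi, n)
        angles = np.where(teleport, big, angles)
        attempted += n
        accepted += int(_sweep_kernel(
            waters, coul, lj, inside, idx, disp, axes, angles, u_acc,
            teleport, targets, bead_coords, esp_q, sig, eps, qw,
            box.water_params.sigma_oo, box.water_params.epsilon_oo, cutoff,
            ww_cut, scale, float(box.length), kt))
        if (sweep >= cfg.n_equilibration
                and (sweep - cfg.n_equilibration) % cfg.stride == 0):
            e_ww_running = water_water_energy(waters, box.water_params,
                                              cutoff=ww_cutoff)
            samples.append(waters.copy())
            s_ci.append(float(np.sum(coul[inside])))
            s_co.append(float(np.sum(coul[~inside])))
            s_lj.append(float(np.sum(lj)))
            s_ww.append(float(e_ww_running))

    if not samples:
        raise ValueError("zero production samples stored; increase "
                         "n_production or reduce stride")
    rate = accepted / max(attempted, 1)
    if not 0.1 <= rate <= 0.9:
        warnings.warn(f"MC acceptance rate {rate:.2f} outside [0.1, 0.9]; "
                      "adjust step sizes", stacklevel=2)
    return Ensemble(bead_coords=bead_coords, level=level,
                    configs=np.array(samples), coul_in=np.array(s_ci),
                    coul_out=np.array(s_co), lj=np.array(s_lj),
                    e_ww=np.array(s_ww), acceptance_rate=rate, seed=cfg.seed)


# ---------------------------------------------------------------------------
# PMF along the path
# ---------------------------------------------------------------------------

def _replace(cfg: SamplerConfig, seed: int) -> SamplerConfig:
    import dataclasses
    return dataclasses.replace(cfg, seed=seed)


def equilibrate_box(box: SimulationBox, solute: SurrogateSolute,
                    bead_coords: np.ndarray, cfg: SamplerConfig,
                    n_sweeps: int = 2000, scheme: EmbeddingScheme | None = None,
                    level: str = "ESP", seed: int = 0,
                    lj_table=None) -> SimulationBox:
    """Relax a freshly placed box by Monte Carlo before production sampling.

    Rejection-sampled boxes start far from the liquid equilibrium; running all
    production ensembles from one pre-relaxed configuration removes the slow
    common drift that would otherwise bias bead-to-bead free-energy
    differences.  Returns a new box holding the final configuration.
    """
    sub = SamplerConfig(temperature=cfg.temperature, n_equilibration=n_sweeps,
                        n_production=1, stride=1,
                        max_translation=cfg.max_translation,
                        max_rotation=cfg.max_rotation, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ens = sample_solvent(np.asarray(bead_coords).reshape(-1, 3), solute,
                             box, sub, scheme or EmbeddingScheme(),
                             level=level, lj_table=lj_table)
    return SimulationBox(length=box.length, waters=ens.configs[-1],
                         periodic=box.periodic, water_params=box.water_params)


def path_boxes(path_beads, solute, box: SimulationBox, cfg: SamplerConfig,
               scheme=None, level: str = "ESP", master_seed: int = 0,
               n_sweeps: int = 600, chain: int = 0,
               lj_table=None) -> list[SimulationBox]:
    """Sequentially relaxed starting configurations along the path.

    Walks the path bead by bead, relaxing the solvent at each bead (at the
    requested tier's coupling) starting from the previous bead's relaxed
    configuration.  Production chains launched from these boxes start close
    to the local solvent equilibrium everywhere along the path, which removes
    the systematic under-relaxation that a single reactant-relaxed start
    would impose on product-like beads.
    """
    scheme = scheme or EmbeddingScheme()
    out = []
    cur = box
    for b, coords in enumerate(path_beads):
        rng = bead_seed(master_seed, b, level, window=9700 + chain)
        cur = equilibrate_box(cur, solute, coords, cfg, n_sweeps=n_sweeps,
                              scheme=scheme, level=level,
                              seed=int(rng.integers(2**31)),
                              lj_table=lj_table)
        out.append(cur)
    return out


def _chain_boxes(boxes, n_chains: int) -> list[SimulationBox]:
    """Normalize one box or a per-chain list to a per-chain list."""
    if isinstance(boxes, SimulationBox):
        return [boxes] * n_chains
    if len(boxes) != n_chains:
        raise ValueError(f"expected {n_chains} per-chain boxes, got {len(boxes)}")
    return list(boxes)


def _boxes_at_bead(walks, bead: int, n_chains: int):
    """Per-chain starting boxes for one bead.

    ``walks`` is a single box, a per-bead list, or a per-chain list of
    per-bead lists (the fully independent-chain layout of
    :func:`multi_level_pmf`).
    """
    if isinstance(walks, SimulationBox):
        return walks
    first = walks[0]
    if isinstance(first, SimulationBox):
        return walks[bead]
    return [walks[c][bead] for c in range(n_chains)]


def sample_path_ensembles(path_beads, solute, walks, cfg, scheme=None,
                          level="ESP", master_seed=0, lj_table=None):
    """Independent chains per bead at a tier, deterministic per-bead seeds.

    ``walks`` is one box, a per-bead list, or per-chain per-bead lists (see
    :func:`path_boxes`).  Returns a list (per bead) of lists of
    :class:`Ensemble` (``cfg.n_chains`` each).
    """
    scheme = scheme or EmbeddingScheme()
    out = []
    for b, coords in enumerate(path_beads):
        rng = bead_seed(master_seed, b, level)
        out.append(sample_solvent_chains(
            coords, solute, _boxes_at_bead(walks, b, cfg.n_chains), cfg,
            scheme, level=level, rng=rng, lj_table=lj_table))
    return out


def _as_chains(x) -> list[Ensemble]:
    return list(x) if isinstance(x, (list, tuple)) else [x]


def zwanzig_chains(du_chains, kt: float, check_overlap: bool = True) -> FEPResult:
    """Zwanzig estimate pooled over independent chains.

    The value is the exponential average over all pooled samples; the standard
    error is computed *between* the chains' exponential means, so slow
    within-chain correlations that block averaging cannot see are reflected in
    the error bar.  With one chain this reduces to block averaging.
    """
    du_chains = [np.asarray(d, dtype=float) for d in du_chains]
    if len(du_chains) == 1:
        return zwanzig(du_chains[0], kt, check_overlap=check_overlap)
    pooled = np.concatenate(du_chains)
    x = pooled / kt
    if check_overlap and pooled.size > 1 and float(np.var(x)) > 25.0:
        raise OverlapError(
            f"exponent variance {np.var(x):.1f} kT² exceeds 25; insert more "
            "beads (smaller perturbation steps)")
    x0 = float(np.min(x))
    chain_means = np.array([np.mean(np.exp(-(d / kt - x0)))
                            for d in du_chains])
    mean_w = float(np.mean(np.exp(-(x - x0))))
    value = kt * (x0 - np.log(mean_w))
    r = len(du_chains)
    se = kt * float(np.std(chain_means, ddof=1)) / (mean_w * np.sqrt(r))
    return FEPResult(value=float(value), se=float(se))


def sample_solvent_chains(bead_coords, solute, boxes, cfg: SamplerConfig,
                          scheme=None, level: str = "ESP",
                          rng: np.random.Generator | None = None,
                          lj_table=None) -> list[Ensemble]:
    """``cfg.n_chains`` independent ensembles at one bead (distinct seeds).

    ``boxes`` is one box or one starting box per chain; per-chain starts keep
    the chains' entire histories independent, so between-chain errors include
    starting-configuration variability.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    out = []
    for box in _chain_boxes(boxes, cfg.n_chains):
        sub = _replace(cfg, int(rng.integers(2**31)))
        out.append(sample_solvent(np.asarray(bead_coords).reshape(-1, 3),
                                  solute, box, sub, scheme, level=level,
                                  lj_table=lj_table))
    return out


def _segment_increment(chains_a, a: np.ndarray, b: np.ndarray,
                       solute: SurrogateSolute, boxes_a,
                       scheme: EmbeddingScheme, cfg: SamplerConfig,
                       level: str, master_seed: int, bead_index: int,
                       n_windows: int, lj_p: np.ndarray):
    """Stratified FEP free energy of swapping the frozen solute A→B.

    The geometric perturbation is split into ``n_windows`` sub-windows along
    the linear A→B interpolation, each estimated one-sidedly in independent
    chains sampled at the window's own start geometry (window 0 reuses the
    bead chains).  The solute's configuration-independent internal energy
    change telescopes out of the exponential averages and is added
    analytically.  Returns (value, se).
    """
    geoms = [(1.0 - t) * a + t * b
             for t in np.linspace(0.0, 1.0, n_windows + 1)]
    eval_box = (boxes_a if isinstance(boxes_a, SimulationBox)
                else _as_chains(boxes_a)[0])
    total = 0.0
    var = 0.0
    for w in range(n_windows):
        if w == 0:
            chains = _as_chains(chains_a)
        else:
            rng = bead_seed(master_seed, bead_index, level, window=w)
            chains = sample_solvent_chains(geoms[w], solute, boxes_a, cfg,
                                           scheme, level=level, rng=rng)
        g = geoms[w + 1]
        du = []
        for ens in chains:
            u_from = coupling_at_level(ens.coul_in, ens.coul_out, ens.lj,
                                       solute, level)
            ci, co, lj = batch_coupling(ens.configs, g, solute.esp_charges(g),
                                        lj_p, eval_box, scheme)
            du.append(coupling_at_level(ci, co, lj, solute, level) - u_from)
        r = zwanzig_chains(du, cfg.kT)
        total += r.value
        var += r.se ** 2
    gas = (solute.internal_energy(b, level) - solute.internal_energy(a, level))
    return gas + total, float(np.sqrt(var))


def pmf_esp(ensembles, path_beads, solute: SurrogateSolute,
            boxes, scheme: EmbeddingScheme, cfg: SamplerConfig,
            master_seed: int = 0, n_windows: int = 4,
            lj_table: dict | None = None):
    """Adjacent-bead ESP-tier PMF increments ΔW^ESP(A→B).

    ``ensembles[i]`` (one :class:`Ensemble` or a list of independent chains)
    must be sampled at bead i with ESP coupling.  Each increment is the
    stratified Zwanzig average of the coupling change when the frozen solute
    is swapped A→B starting from A's chains, plus the solute's internal
    ESP-tier gas energy difference (identically zero for a charges-only
    tier).  Returns (increments, standard errors), length N−1.
    """
    lj_p = solute_lj_params(solute.labels, lj_table)
    beads = [np.asarray(b).reshape(-1, 3) for b in path_beads]
    n = len(beads)
    inc = np.zeros(n - 1)
    se = np.zeros(n - 1)
    for i in range(n - 1):
        chains = _as_chains(ensembles[i])
        if any(e.level != "ESP" for e in chains):
            raise ValueError("pmf_esp requires ESP-sampled bead ensembles")
        inc[i], se[i] = _segment_increment(
            chains, beads[i], beads[i + 1], solute,
            _boxes_at_bead(boxes, i, cfg.n_chains), scheme, cfg,
            "ESP", master_seed, i, n_windows, lj_p)
    return inc, se


def level_shift(ensemble, solute: SurrogateSolute,
                from_level: str, to_level: str, kt: float) -> FEPResult:
    """Zwanzig free energy of switching the solute tier at fixed configuration.

    ΔU per stored configuration is the internal-energy change of the frozen
    solute plus the coupling change due to the tier charge polish; the
    Lennard-Jones and outside-cutoff terms are tier-independent and cancel.
    ``ensemble`` may be a single :class:`Ensemble` or a list of independent
    chains (errors are then estimated between chains).
    """
    chains = _as_chains(ensemble)
    bad = [e.level for e in chains if e.level != from_level]
    if bad:
        raise ValueError(f"ensemble was sampled at {bad[0]!r}, not "
                         f"{from_level!r}")
    bead = chains[0].bead_coords
    d_int = (solute.internal_energy(bead, to_level)
             - solute.internal_energy(bead, from_level))
    ds = solute.level_scale[to_level] - solute.level_scale[from_level]
    du = [d_int + ds * e.coul_in for e in chains]
    return zwanzig_chains(du, kt)


@dataclass
class MultiLevelPMF:
    """Per-bead PMF profiles at the three tiers plus their components.

    All profiles are cumulative free energies relative to the reactant bead
    (bead 0), kcal·mol⁻¹.  ``shifts_low``/``shifts_high`` are the per-bead
    fixed-configuration level-shift free energies (ESP→LOW, LOW→HIGH).
    """

    w_esp: np.ndarray
    shifts_low: np.ndarray
    shifts_high: np.ndarray
    w_low: np.ndarray
    w_high: np.ndarray
    se_esp: np.ndarray
    se_low: np.ndarray
    se_high: np.ndarray

    def barrier(self, level: str = "HIGH"):
        """(barrier, se, bead index): max bead free energy minus reactant."""
        w, se = self._profile(level)
        i = int(np.argmax(w))
        return float(w[i]), float(se[i]), i

    def reaction_free_energy(self, level: str = "HIGH"):
        w, se = self._profile(level)
        return float(w[-1]), float(se[-1])

    def _profile(self, level: str):
        try:
            return {"ESP": (self.w_esp, self.se_esp),
                    "LOW": (self.w_low, self.se_low),
                    "HIGH": (self.w_high, self.se_high)}[level]
        except KeyError:
            raise ValueError(f"unknown level {level!r}") from None

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "bead": np.arange(self.w_esp.size),
            "dW_esp": self.w_esp, "shift_low": self.shifts_low,
            "shift_high": self.shifts_high, "dW_low": self.w_low,
            "dW_high": self.w_high, "se_esp": self.se_esp,
            "se_low": self.se_low, "se_high": self.se_high,
        })


def compose(esp_increments, esp_se, shifts_low, shifts_high) -> MultiLevelPMF:
    """Compose the multi-level PMF from ESP increments and per-bead shifts.

    ``shifts_low``/``shifts_high`` are sequences of :class:`FEPResult` (or
    (value, se) pairs), one per bead; a missing/NaN bead is an error.
    """
    def unpack(seq, name):
        vals, ses = [], []
        for k, r in enumerate(seq):
            v, s = (r.value, r.se) if isinstance(r, FEPResult) else r
            vals.append(v)
            ses.append(s)
        vals, ses = np.asarray(vals, float), np.asarray(ses, float)
        gaps = np.where(~np.isfinite(vals))[0].tolist()
        if gaps:
            raise ValueError(f"missing {name} shifts at beads {gaps}")
        return vals, ses

    inc = np.asarray(esp_increments, dtype=float)
    inc_se = np.asarray(esp_se, dtype=float)
    sl, sl_se = unpack(shifts_low, "LOW")
    sh, sh_se = unpack(shifts_high, "HIGH")
    n = sl.size
    if sh.size != n or inc.size != n - 1:
        raise ValueError("inconsistent bead counts between increments and shifts")

    w_esp = np.concatenate([[0.0], np.cumsum(inc)])
    se_esp = np.sqrt(np.concatenate([[0.0], np.cumsum(inc_se**2)]))
    w_low = w_esp + (sl - sl[0])
    se_low = np.sqrt(se_esp**2 + sl_se**2 + sl_se[0]**2)
    se_low[0] = 0.0
    w_high = w_low + (sh - sh[0])
    se_high = np.sqrt(se_low**2 + sh_se**2 + sh_se[0]**2)
    se_high[0] = 0.0
    return MultiLevelPMF(w_esp=w_esp, shifts_low=sl, shifts_high=sh,
                         w_low=w_low, w_high=w_high, se_esp=se_esp,
                         se_low=se_low, se_high=se_high)


def multi_level_pmf(path_beads, solute, box, cfg: SamplerConfig,
                    scheme: EmbeddingScheme | None = None, master_seed: int = 0,
                    n_windows: int = 4, walk_sweeps: int = 600,
                    lj_table: dict | None = None):
    """Full three-tier PMF: ESP sampling, shifts, and composition.

    Starting configurations come from a sequential path walk
    (:func:`path_boxes`) so every bead's chains launch near the local solvent
    equilibrium.  Returns ``(MultiLevelPMF, esp_ensembles, low_ensembles)``.
    """
    scheme = scheme or EmbeddingScheme()
    kt = cfg.kT
    beads = [np.asarray(b).reshape(-1, 3) for b in path_beads]
    esp_walks = [path_boxes(beads, solute, box, cfg, scheme, level="ESP",
                            master_seed=master_seed, n_sweeps=walk_sweeps,
                            chain=c, lj_table=lj_table)
                 for c in range(cfg.n_chains)]
    low_walks = [path_boxes(beads, solute, box, cfg, scheme, level="LOW",
                            master_seed=master_seed, n_sweeps=walk_sweeps,
                            chain=c, lj_table=lj_table)
                 for c in range(cfg.n_chains)]
    esp_ens = sample_path_ensembles(beads, solute, esp_walks, cfg, scheme,
                                    level="ESP", master_seed=master_seed,
                                    lj_table=lj_table)
    low_ens = sample_path_ensembles(beads, solute, low_walks, cfg, scheme,
                                    level="LOW", master_seed=master_seed,
                                    lj_table=lj_table)
    inc, inc_se = pmf_esp(esp_ens, beads, solute, esp_walks, scheme, cfg,
                          master_seed=master_seed, n_windows=n_windows,
                          lj_table=lj_table)
    shifts_low = [level_shift(e, solute, "ESP", "LOW", kt) for e in esp_ens]
    shifts_high = [level_shift(e, solute, "LOW", "HIGH", kt) for e in low_ens]
    pmf = compose(inc, inc_se, shifts_low, shifts_high)
    return pmf, esp_ens, low_ens


def direct_pmf(level: str, path_beads, solute, box, cfg: SamplerConfig,
               scheme: EmbeddingScheme | None = None, master_seed: int = 0,
               n_windows: int = 4, walk_sweeps: int = 600,
               lj_table: dict | None = None):
    """Single-tier PMF sampled directly at ``level`` (the cross-check route).

    Samples every bead with the tier's own coupling and accumulates Zwanzig
    increments of the *full* tier potential difference between adjacent beads.
    Returns (profile, se) arrays of length N.
    """
    scheme = scheme or EmbeddingScheme()
    lj_p = solute_lj_params(solute.labels, lj_table)
    beads = [np.asarray(b).reshape(-1, 3) for b in path_beads]
    walks = [path_boxes(beads, solute, box, cfg, scheme, level=level,
                        master_seed=master_seed, n_sweeps=walk_sweeps,
                        chain=c, lj_table=lj_table)
             for c in range(cfg.n_chains)]
    ens = sample_path_ensembles(beads, solute, walks, cfg, scheme, level=level,
                                master_seed=master_seed, lj_table=lj_table)
    n = len(beads)
    inc = np.zeros(n - 1)
    se = np.zeros(n - 1)
    for i in range(n - 1):
        inc[i], se[i] = _segment_increment(
            ens[i], beads[i], beads[i + 1], solute,
            _boxes_at_bead(walks, i, cfg.n_chains), scheme, cfg,
            level, master_seed, i, n_windows, lj_p)
    w = np.concatenate([[0.0], np.cumsum(inc)])
    w_se = np.sqrt(np.concatenate([[0.0], np.cumsum(se**2)]))
    return w, w_se


# ---------------------------------------------------------------------------
# solvent / polarization decomposition
# ---------------------------------------------------------------------------

@dataclass
class SolventDecomposition:
    """Bookkeeping split of the aqueous PMF into solvent and polarization parts.

    All per-state numbers are kcal·mol⁻¹.  ``polarization_*`` are internal
    QM/MM minus gas-phase energies (absolute per state); the nets subtract the
    reactant value.  The additivity identity

        aqueous contribution = solvent-energy contribution + net polarization

    holds exactly by construction and is asserted in the test suite.
    """

    solvent_barrier: float
    solvent_reaction: float
    polarization_reactant: float
    polarization_ts: float
    polarization_product: float
    net_polarization_ts: float = field(init=False)
    net_polarization_product: float = field(init=False)
    aqueous_barrier_contribution: float = field(init=False)
    aqueous_reaction_contribution: float = field(init=False)

    def __post_init__(self) -> None:
        self.net_polarization_ts = self.polarization_ts - self.polarization_reactant
        self.net_polarization_product = (self.polarization_product
                                         - self.polarization_reactant)
        self.aqueous_barrier_contribution = (self.solvent_barrier
                                             + self.net_polarization_ts)
        self.aqueous_reaction_contribution = (self.solvent_reaction
                                              + self.net_polarization_product)


def decompose_solvent(path_beads, solute: SurrogateSolute,
                      esp_profile: np.ndarray, ensembles: list[Ensemble],
                      ts_index: int, level: str = "HIGH",
                      product_index: int = -1):
    """Solvent/polarization decomposition along a sampled path.

    The gas-phase profile is the solute's internal tier energy at the same
    beads without any solvent terms; the internal QM/MM energy additionally
    includes the ensemble-averaged coupling (everything except the MM-MM
    energy); polarization is their difference.  The solvent-energy
    contribution to the PMF is the ESP-tier profile.  Returns the per-state
    :class:`SolventDecomposition` plus the three per-bead profiles.
    """
    beads = [np.asarray(b).reshape(-1, 3) for b in path_beads]
    gas = np.array([solute.internal_energy(b, level) for b in beads])
    coup = np.array([
        float(np.mean(np.concatenate([
            coupling_at_level(e.coul_in, e.coul_out, e.lj, solute, level)
            for e in _as_chains(chains)])))
        for chains in ensembles])
    internal = gas + coup
    pol = internal - gas
    prod = product_index if product_index >= 0 else len(beads) - 1
    esp_profile = np.asarray(esp_profile, dtype=float)
    deco = SolventDecomposition(
        solvent_barrier=float(esp_profile[ts_index]),
        solvent_reaction=float(esp_profile[prod]),
        polarization_reactant=float(pol[0]),
        polarization_ts=float(pol[ts_index]),
        polarization_product=float(pol[prod]),
    )
    return deco, gas - gas[0], internal - internal[0], pol
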