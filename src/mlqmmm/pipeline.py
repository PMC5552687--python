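"""End-to-end pipeline orchestration: NEB → PMF → decomposition → cycle → rate.

A :class:`RunConfig` (YAML-loadable) fixes every knob and one master seed; the
pipeline is idempotent given the config, and the written summary records the
provenance (seed, config hash, package version) needed to reproduce it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path as FsPath

import numpy as np
import yaml

from . import __version__
from .freeenergy import (SamplerConfig, decompose_solvent, equilibrate_box,
                         multi_level_pmf)
from .geometry import write_xyz_frames
from .pathopt import GasSolutePotential, NEBConfig, interpolate, neb_relax
from .qmmm import EmbeddingScheme
from .synthetic import BoxSpec, generate_box, generate_solute, reference_tables
from .thermo import RateInput, cycle_compose, rate_ratio_orders, tst_rate

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

log = logging.getLogger("mlqmmm")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """All pipeline settings; every source of randomness flows from ``seed``."""

    seed: int = 1
    n_beads: int = 10
    n_waters: int = 64
    box_length: float = 12.4
    min_oo: float = 2.4
    cutoff: float = 15.0
    temperature: float = 298.15
    n_windows: int = 4            # FEP sub-windows per path segment
    equilibration_sweeps: int = 4000  # shared box pre-relaxation
    neb: dict = field(default_factory=dict)       # NEBConfig overrides
    sampler: dict = field(default_factory=dict)   # SamplerConfig overrides
    solvation: dict = field(default_factory=dict) # {reactant, ts, product} kcal/mol
    lj_table_file: str | None = None
    output_dir: str = "mlqmmm_run"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        if cfg.lj_table_file and not FsPath(cfg.lj_table_file).exists():
            raise FileNotFoundError(
                f"referenced parameter file does not exist: {cfg.lj_table_file}")
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Assembled pipeline outputs with units and provenance."""

    summary: dict

    def write(self, outdir) -> None:
        out = FsPath(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)


def _default_solvation() -> dict:
    ref = reference_tables()["solvation"]
    return {"reactant": ref["reactant"]["v"], "ts": ref["ts"]["v"],
            "product": ref["product"]["v"]}


def run_pipeline(config: RunConfig, outdir=None) -> RunReport:
    """Execute the full pipeline on the surrogate system.

    Stages: gas-phase NEB on the LOW tier, solvent-box generation, three-tier
    PMF with level shifting, solvent/polarization decomposition, thermodynamic
    cycle from the configured solvation free energies, and TST rates.  A stage
    failure raises :class:`PipelineError` naming the stage; artifacts written
    before the failure are preserved.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    outdir = FsPath(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("run: seed=%d config_hash=%s", config.seed, config.config_hash())

    stage = "setup"
    try:
        reactant, product, solute = generate_solute(seed=config.seed)
        lj_table = None
        if config.lj_table_file:
            lj_table = yaml.safe_load(open(config.lj_table_file))
            lj_table = {el: (v["sigma"], v["epsilon"])
                        for el, v in lj_table["types"].items()}

        stage = "neb"
        neb_cfg = NEBConfig(seed=config.seed, **config.neb)
        pot_low = GasSolutePotential(solute, "LOW")
        path = neb_relax(interpolate(reactant, product, config.n_beads),
                         pot_low, neb_cfg)
        if not path.converged:
            raise PipelineError("neb: band did not converge")
        beads = [b.reshape(-1, 3) for b in path.beads]
        frames = [reactant.with_coords(b) for b in beads]
        write_xyz_frames(frames, outdir / "path.xyz",
                         comments=[f"bead {i} E_low={e:.6f} kcal/mol"
                                   for i, e in enumerate(path.energies)])
        gas_high = np.array([solute.internal_energy(b, "HIGH") for b in beads])
        gas_high -= gas_high[0]
        gas_low = path.energies - path.energies[0]

        stage = "box"
        center = np.full(3, config.box_length / 2.0)
        shift = center - reactant.coords.mean(axis=0)
        beads = [b + shift for b in beads]
        box = generate_box(
            BoxSpec(length=config.box_length, n_waters=config.n_waters,
                    min_oo=config.min_oo, seed=config.seed),
            exclude=beads[0])

        stage = "pmf"
        scheme = EmbeddingScheme(cutoff=config.cutoff)
        sampler = SamplerConfig(temperature=config.temperature,
                                **config.sampler)
        box = equilibrate_box(box, solute, beads[0], sampler,
                              n_sweeps=config.equilibration_sweeps,
                              scheme=scheme, seed=config.seed + 100)
        pmf, esp_ens, low_ens = multi_level_pmf(
            beads, solute, box, sampler, scheme, master_seed=config.seed,
            n_windows=config.n_windows, lj_table=lj_table)
        pmf.to_frame().assign(arc_length=path.arc_lengths).to_csv(
            outdir / "pmf.csv", index=False)
        barrier_high, barrier_se, ts_index = pmf.barrier("HIGH")
        dg_high, dg_se = pmf.reaction_free_energy("HIGH")

        stage = "decompose"
        deco, gas_prof, internal_prof, pol = decompose_solvent(
            beads, solute, pmf.w_esp, esp_ens, ts_index)

        stage = "cycle"
        solv = {**_default_solvation(), **config.solvation}
        gas_barrier = float(np.max(gas_high))
        gas_reaction = float(gas_high[-1])
        cycle = cycle_compose(gas_barrier, gas_reaction, solv["reactant"],
                              solv["ts"], solv["product"])

        stage = "rate"
        rate_gas = tst_rate(RateInput(gas_barrier, config.temperature))
        rate_soln = tst_rate(RateInput(barrier_high, config.temperature))
        orders, orders_int = rate_ratio_orders(gas_barrier, barrier_high,
                                               config.temperature)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"{stage}: {exc}") from exc

    summary = {
        "provenance": {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "version": __version__,
        },
        "units": {"energy": "kcal/mol", "length": "angstrom",
                  "rate": "cm^3/molecule/s", "temperature": "K"},
        "neb": {
            "n_beads": config.n_beads,
            "iterations": path.n_iterations,
            "gas_barrier_low": float(np.max(gas_low)),
            "gas_barrier_high": gas_barrier,
            "gas_reaction_high": gas_reaction,
            "ts_bond_length": float(np.linalg.norm(
                beads[ts_index][2] - beads[ts_index][1])),
        },
        "pmf": {
            "barrier_esp": pmf.barrier("ESP")[0],
            "barrier_low": pmf.barrier("LOW")[0],
            "barrier_high": barrier_high,
            "barrier_high_se": barrier_se,
            "reaction_high": dg_high,
            "reaction_high_se": dg_se,
            "ts_bead": ts_index,
        },
        "decomposition": {
            "solvent_barrier": deco.solvent_barrier,
            "solvent_reaction": deco.solvent_reaction,
            "net_polarization_ts": deco.net_polarization_ts,
            "net_polarization_product": deco.net_polarization_product,
            "aqueous_barrier_contribution": deco.aqueous_barrier_contribution,
            "aqueous_reaction_contribution": deco.aqueous_reaction_contribution,
        },
        "cycle": {
            "inputs": {"gas_barrier": gas_barrier,
                       "gas_reaction_energy": gas_reaction, **solv},
            "solution_barrier": cycle.solution_barrier,
            "solution_reaction_energy": cycle.solution_reaction_energy,
        },
        "rates": {
            "gas": {"rate": rate_gas.rate, "log10": rate_gas.log10_rate,
                    "power_of_ten": rate_gas.nearest_power_of_ten},
            "solution": {"rate": rate_soln.rate, "log10": rate_soln.log10_rate,
                         "power_of_ten": rate_soln.nearest_power_of_ten},
            "orders_slower_in_solution": orders_int,
        },
    }
    report = RunReport(summary=summary)
    report.write(outdir)
    return report
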