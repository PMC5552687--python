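"""Thermodynamic-cycle composition and transition-state-theory rate constants.

Solution-phase free energies are composed from a gas-phase reaction profile
plus continuum solvation free energies of the three stationary states:

    ΔW‡(soln) = ΔE‡(gas) + ΔG_solv(TS) − ΔG_solv(RC)
    ΔW(soln)  = ΔE(gas)  + ΔG_solv(PC) − ΔG_solv(RC)

Rate constants use the thermodynamic formulation of transition-state theory,

    k = A·exp(−ΔW_a‡ / RT),   A = (k_B·T/h)·(RT/P),

with the prefactor carrying the bimolecular standard-state volume factor
(RT/P per molecule), so k is reported in cm³·molecule⁻¹·s⁻¹ — the same
convention and units in which such barrier-derived estimates are customarily
printed, even when the elementary step is unimolecular.  Order-of-magnitude
statements use round(log₁₀ k).  Constants are pinned CODATA-2018 values;
defaults are T = 298.15 K and P = 1 atm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (ATM_TO_PA, BOLTZMANN_SI, DEFAULT_PRESSURE_ATM,
                        DEFAULT_TEMPERATURE, GAS_CONSTANT_KCAL, PLANCK_SI)

__all__ = [
    "SolvationCycle",
    "RateInput",
    "RateResult",
    "cycle_compose",
    "tst_rate",
    "rate_ratio_orders",
]


@dataclass
class SolvationCycle:
    """Gas-phase energies + solvation free energies → solution-phase values.

    All fields in kcal·mol⁻¹.  The derived fields satisfy the cycle identities
    exactly (plain arithmetic, no fitting).
    """

    gas_barrier: float
    gas_reaction_energy: float
    solvation_reactant: float
    solvation_ts: float
    solvation_product: float
    solution_barrier: float = field(init=False)
    solution_reaction_energy: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("gas_barrier", "gas_reaction_energy", "solvation_reactant",
                     "solvation_ts", "solvation_product"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ValueError(f"missing or non-finite cycle input {name!r}")
        self.solution_barrier = (self.gas_barrier + self.solvation_ts
                                 - self.solvation_reactant)
        self.solution_reaction_energy = (self.gas_reaction_energy
                                         + self.solvation_product
                                         - self.solvation_reactant)


def cycle_compose(gas_barrier: float, gas_reaction_energy: float,
                  solvation_reactant: float, solvation_ts: float,
                  solvation_product: float) -> SolvationCycle:
    """Compose solution-phase barrier and reaction energy via the cycle."""
    return SolvationCycle(gas_barrier, gas_reaction_energy, solvation_reactant,
                          solvation_ts, solvation_product)


@dataclass
class RateInput:
    """Inputs of the TST rate expression."""

    barrier: float                                  # ΔW_a‡, kcal·mol⁻¹
    temperature: float = DEFAULT_TEMPERATURE        # K
    pressure_atm: float = DEFAULT_PRESSURE_ATM      # standard state, atm

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.pressure_atm <= 0:
            raise ValueError("pressure must be positive")


@dataclass
class RateResult:
    """TST prefactor and rate in cm³·molecule⁻¹·s⁻¹."""

    prefactor: float
    rate: float
    log10_rate: float
    nearest_power_of_ten: int


def tst_rate(inp: RateInput) -> RateResult:
    """k = A·exp(−ΔW‡/RT) with A = (k_B·T/h)·(RT/P) per molecule."""
    t = inp.temperature
    p_pa = inp.pressure_atm * ATM_TO_PA
    volume_m3 = BOLTZMANN_SI * t / p_pa      # RT/P per molecule
    prefactor = (BOLTZMANN_SI * t / PLANCK_SI) * volume_m3 * 1.0e6  # cm³/s
    rate = prefactor * np.exp(-inp.barrier / (GAS_CONSTANT_KCAL * t))
    log10 = float(np.log10(rate))
    return RateResult(prefactor=float(prefactor), rate=float(rate),
                      log10_rate=log10,
                      nearest_power_of_ten=int(np.round(log10)))


def rate_ratio_orders(barrier_a: float, barrier_b: float,
                      temperature: float = DEFAULT_TEMPERATURE):
    """Orders of magnitude by which barrier_b slows the rate versus barrier_a.

    The prefactor cancels analytically:
    log₁₀(k_a/k_b) = (ΔW_b − ΔW_a)/(RT·ln 10).  Returns (exact, rounded).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    orders = (barrier_b - barrier_a) / (GAS_CONSTANT_KCAL * temperature
                                        * np.log(10.0))
    return float(orders), int(np.round(orders))
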