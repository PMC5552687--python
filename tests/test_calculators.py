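"""Energy backends: primitives, water MM, Müller-Brown, surrogate solute."""

import numpy as np
import pytest

from mlqmmm.calculators import (CalculatorError, CalculatorSpec, MuellerBrown,
                                WaterModelParams, coulomb, evaluate,
                                finite_difference_gradient, lennard_jones,
                                load_qm_lj_table, load_water_params, morse,
                                muller_brown, solute_energy,
                                water_water_energy)
from mlqmmm.constants import COULOMB_KCAL
from mlqmmm.geometry import Structure
from mlqmmm.synthetic import water_template


class TestPrimitives:
    def test_lj_zero_at_sigma(self):
        assert lennard_jones(3.166, 3.166, 0.1553) == pytest.approx(0.0)

    def test_lj_minimum_depth(self):
        rmin = 2 ** (1 / 6) * 3.0
        assert lennard_jones(rmin, 3.0, 0.2) == pytest.approx(-0.2)

    def test_coulomb_unit_charges_at_1A(self):
        assert coulomb(1.0, 1.0, 1.0) == pytest.approx(COULOMB_KCAL)

    def test_morse_minimum_is_minus_de(self):
        assert morse(1.47, 60.0, 2.0, 1.47) == pytest.approx(-60.0)

    def test_morse_dissociation_plateau(self):
        assert morse(60.0, 60.0, 2.0, 1.47) == pytest.approx(0.0, abs=1e-6)


class TestWaterMM:
    def test_single_water_is_zero(self):
        params = load_water_params()
        assert water_water_energy(water_template(params)[None], params) == 0.0

    def test_beyond_cutoff_is_zero(self):
        params = load_water_params()
        w = np.stack([water_template(params),
                      water_template(params) + [50.0, 0, 0]])
        assert water_water_energy(w, params, cutoff=15.0) == 0.0

    def test_cluster_matches_brute_force_oracle(self, rng):
        """Vectorized energy equals an explicit O(N²) double loop."""
        params = load_water_params()
        centers = rng.uniform(0, 12, size=(10, 3))
        w = centers[:, None, :] + water_template(params)[None]

        def oracle():
            q = params.site_charges
            e = 0.0
            for i in range(10):
                for j in range(i + 1, 10):
                    doo = np.linalg.norm(w[i, 0] - w[j, 0])
                    sr6 = (params.sigma_oo / doo) ** 6
                    e += 4 * params.epsilon_oo * (sr6**2 - sr6)
                    for a in range(3):
                        for b in range(3):
                            r = np.linalg.norm(w[i, a] - w[j, b])
                            e += COULOMB_KCAL * q[a] * q[b] / r
            return e

        assert water_water_energy(w, params) == pytest.approx(oracle(), abs=1e-8)

    def test_overlapping_sites_error(self):
        params = load_water_params()
        w = np.stack([water_template(params), water_template(params) + 0.01])
        with pytest.raises(CalculatorError, match="overlap"):
            water_water_energy(w, params)

    def test_spce_net_charge_zero(self):
        assert load_water_params().site_charges.sum() == pytest.approx(0.0)

    def test_unbalanced_charges_rejected(self):
        with pytest.raises(CalculatorError, match="net charge"):
            WaterModelParams(q_oxygen=-0.8, q_hydrogen=0.41)


class TestMuellerBrown:
    # the three literature minima and the saddle between the deepest two,
    # frozen from a dense-grid scan + Newton refinement oracle (see
    # test_acceptance for the live oracle)
    MINIMA = [(-0.5582236346, 1.4417258418),
              (-0.0500108230, 0.4666941049),
              (0.6234994049, 0.0280377585)]

    def test_minima_ordering(self):
        mb = MuellerBrown()
        energies = sorted(mb.energy(m) for m in self.MINIMA)
        assert energies[0] == pytest.approx(-146.6995, abs=1e-3)
        assert energies[0] < energies[1] < energies[2]

    def test_gradient_vanishes_at_minima(self):
        mb = MuellerBrown()
        for m in self.MINIMA:
            assert np.linalg.norm(mb.gradient(m)) < 1e-6

    def test_gradient_matches_finite_difference(self, rng):
        mb = MuellerBrown()
        for _ in range(5):
            pt = rng.uniform([-1.5, -0.5], [1.0, 2.0])
            fd = finite_difference_gradient(lambda c: mb.energy(c[0]),
                                            pt[None, :].copy())[0]
            np.testing.assert_allclose(mb.gradient(pt), fd, rtol=1e-4, atol=1e-5)

    def test_hessian_matches_finite_difference(self):
        mb = MuellerBrown()
        pt = np.array([-0.7, 0.6])
        h = 1e-5
        num = np.zeros((2, 2))
        for k in range(2):
            e = np.zeros(2)
            e[k] = h
            num[:, k] = (mb.gradient(pt + e) - mb.gradient(pt - e)) / (2 * h)
        np.testing.assert_allclose(mb.hessian(pt), num, rtol=1e-5, atol=1e-4)

    def test_module_level_helper(self):
        assert muller_brown((0.0, 0.0)) == pytest.approx(
            MuellerBrown().energy((0.0, 0.0)))


class TestSurrogateSolute:
    def test_high_minus_low_at_center_is_amplitude(self, solute_system):
        _, _, sol = solute_system
        r = sol.high_center
        assert (sol.bond_profile(r, "HIGH") - sol.bond_profile(r, "LOW")
                == pytest.approx(sol.high_amp))

    def test_levels_coincide_far_from_perturbation(self, solute_system):
        _, _, sol = solute_system
        assert sol.high_perturbation(10.0) < 1e-10

    def test_stretched_bond_reaches_dissociation_plateau(self, solute_system):
        _, _, sol = solute_system
        assert sol.bond_profile(60.0, "LOW") == pytest.approx(0.0, abs=1e-6)

    def test_profile_barrier_matches_scan_oracle(self, solute_system):
        """NEB-relevant 1-D barrier equals a fine-scan maximum."""
        _, _, sol = solute_system
        r = np.linspace(1.47, 2.9, 20001)
        prof = sol.bond_profile(r, "LOW")
        barrier = prof.max() - sol.bond_profile(1.47, "LOW")
        # oracle is the scan itself; the surface must have one interior max
        imax = int(np.argmax(prof))
        assert 0 < imax < r.size - 1
        assert barrier > 10.0

    def test_internal_forces_match_finite_difference(self, solute_system):
        reactant, _, sol = solute_system
        coords = reactant.coords + 0.05  # off-minimum
        for level in ("LOW", "HIGH"):
            an = sol.internal_gradient(coords, level)
            fd = finite_difference_gradient(
                lambda c: sol.internal_energy(c, level), coords.copy())
            scale = max(1.0, np.max(np.abs(fd)))
            assert np.max(np.abs(an - fd)) / scale < 1e-4

    def test_energy_rigid_motion_invariant(self, solute_system, rng):
        reactant, _, sol = solute_system
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array([
            [1 - 2 * (y*y + z*z), 2 * (x*y - z*w), 2 * (x*z + y*w)],
            [2 * (x*y + z*w), 1 - 2 * (x*x + z*z), 2 * (y*z - x*w)],
            [2 * (x*z - y*w), 2 * (y*z + x*w), 1 - 2 * (x*x + y*y)]])
        moved = reactant.coords @ rot.T + np.array([3.0, -2.0, 1.0])
        for level in ("LOW", "HIGH"):
            assert sol.internal_energy(moved, level) == pytest.approx(
                sol.internal_energy(reactant.coords, level), abs=1e-9)

    def test_esp_level_has_no_internal_energy(self, solute_system):
        reactant, product, sol = solute_system
        assert sol.internal_energy(reactant.coords, "ESP") == 0.0
        assert sol.internal_energy(product.coords, "ESP") == 0.0

    def test_charges_interpolate_and_conserve(self, solute_system):
        reactant, product, sol = solute_system
        qr = sol.esp_charges(reactant.coords)
        qp = sol.esp_charges(product.coords)
        np.testing.assert_allclose(qr, sol.charges_reactant, atol=5e-3)
        assert qr.sum() == pytest.approx(0.0, abs=1e-12)
        assert qp.sum() == pytest.approx(0.0, abs=1e-10)

    def test_undefined_level_rejected(self, solute_system):
        reactant, _, sol = solute_system
        with pytest.raises(CalculatorError, match="undefined"):
            sol.internal_energy(reactant.coords, "CCSD")


class TestEvaluateDispatch:
    def test_solute_dispatch_and_forces(self, solute_system):
        reactant, _, sol = solute_system
        spec = CalculatorSpec("LOW", {"solute": sol})
        res = evaluate(spec, reactant, forces=True)
        assert res.level == "LOW"
        assert res.forces.shape == reactant.coords.shape

    def test_atom_mismatch_rejected(self, solute_system):
        _, _, sol = solute_system
        spec = CalculatorSpec("LOW", {"solute": sol})
        s = Structure(["C1"], np.zeros((1, 3)))
        with pytest.raises(CalculatorError, match="atom count"):
            evaluate(spec, s)

    def test_unknown_level_rejected(self):
        with pytest.raises(CalculatorError, match="unknown level"):
            CalculatorSpec("DFT")

    def test_solute_energy_determinism(self, solute_system):
        reactant, _, sol = solute_system
        a = solute_energy("HIGH", reactant, sol).energy
        b = solute_energy("HIGH", reactant, sol).energy
        assert a == b


def test_lj_table_covers_solute_elements(solute_system):
    table = load_qm_lj_table()
    _, _, sol = solute_system
    from mlqmmm.geometry import element_of
    assert {element_of(lb) for lb in sol.labels} <= set(table)
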