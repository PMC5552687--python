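"""Sampler calibration, Zwanzig estimator, PMF machinery and decomposition."""

import numpy as np
import pytest
from scipy import stats

from mlqmmm.constants import kT
from mlqmmm.freeenergy import (FEPResult, OverlapError, SamplerConfig,
                               SolventDecomposition, batch_coupling, compose,
                               coupling_at_level, equilibrate_box, level_shift,
                               metropolis_sample, pmf_esp, sample_solvent,
                               zwanzig)
from mlqmmm.qmmm import EmbeddingScheme, SimulationBox, solute_lj_params

KT = kT(298.15)


class TestZwanzig:
    def test_zero_perturbation_is_exactly_zero(self, rng):
        du = np.zeros(500)
        assert zwanzig(du, KT).value == 0.0

    def test_constant_offset_recovered_exactly(self, rng):
        c = 1.2345
        r = zwanzig(np.full(400, c), KT)
        assert r.value == pytest.approx(c, abs=1e-12)
        assert r.se == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_closed_form(self, rng):
        """For ΔU ~ N(μ, σ²): ΔW = μ − σ²/(2kT)."""
        mu, sigma = 0.8, 0.5
        du = rng.normal(mu, sigma, 200_000)
        r = zwanzig(du, KT)
        expected = mu - sigma**2 / (2 * KT)
        assert r.value == pytest.approx(expected, abs=4 * r.se + 0.01)

    def test_overlap_guard_raises(self, rng):
        du = rng.normal(0.0, 10 * KT, 1000)
        with pytest.raises(OverlapError, match="more beads"):
            zwanzig(du, KT)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            zwanzig(np.array([]), KT)


class TestMetropolisCalibration:
    def test_harmonic_variance_matches_kT_over_k(self):
        """Tethered particle in ½kx²: Var(x) = kT/k within 3 s.e."""
        k = 50.0
        samples = metropolis_sample(lambda x: 0.5 * k * x[0] ** 2,
                                    np.zeros(1), step=0.35, n_samples=20_000,
                                    kt=KT, seed=12, n_burn=500, stride=3)
        var = np.var(samples[:, 0], ddof=1)
        expected = KT / k
        se = expected * np.sqrt(2.0 / 2000)  # conservative n_eff
        assert abs(var - expected) < 3 * se

    def test_harmonic_zwanzig_closed_form(self):
        """ΔW for k1→k2 on a sampled harmonic ensemble equals (kT/2)ln(k2/k1)."""
        k1, k2 = 40.0, 60.0
        samples = metropolis_sample(lambda x: 0.5 * k1 * x[0] ** 2,
                                    np.zeros(1), step=0.4, n_samples=10_000,
                                    kt=KT, seed=7, n_burn=500, stride=3)
        du = 0.5 * (k2 - k1) * samples[:, 0] ** 2
        r = zwanzig(du, KT)
        expected = 0.5 * KT * np.log(k2 / k1)
        assert abs(r.value - expected) < 3 * max(r.se, 0.002)


@pytest.fixture(scope="module")
def sampled(centered_system):
    """One short ESP ensemble on the 64-water system (shared by tests)."""
    rc, pc, solute, box = centered_system
    scheme = EmbeddingScheme()
    cfg = SamplerConfig(n_equilibration=150, n_production=400, stride=4,
                        seed=21)
    box = equilibrate_box(box, solute, rc, cfg, n_sweeps=800, scheme=scheme,
                          seed=5)
    ens = sample_solvent(rc, solute, box, cfg, scheme, level="ESP")
    return rc, pc, solute, box, scheme, cfg, ens


class TestSampler:
    def test_identical_seeds_bitwise_identical(self, sampled):
        rc, _, solute, box, scheme, cfg, ens = sampled
        again = sample_solvent(rc, solute, box, cfg, scheme, level="ESP")
        np.testing.assert_array_equal(ens.configs, again.configs)
        np.testing.assert_array_equal(ens.e_ww, again.e_ww)

    def test_acceptance_rate_reasonable(self, sampled):
        assert 0.1 <= sampled[-1].acceptance_rate <= 0.9

    def test_incremental_coupling_matches_from_scratch(self, sampled):
        """The O(1)-updated coupling bookkeeping agrees with a full
        recomputation on every stored configuration."""
        rc, _, solute, box, scheme, cfg, ens = sampled
        lj_p = solute_lj_params(solute.labels)
        ci, co, lj = batch_coupling(ens.configs, rc, solute.esp_charges(rc),
                                    lj_p, box, scheme)
        np.testing.assert_allclose(ci + co, ens.coul_in + ens.coul_out,
                                   atol=1e-10)
        np.testing.assert_allclose(lj, ens.lj, atol=1e-10)

    def test_zero_production_rejected(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_production=0)

    def test_sweep_kernel_matches_pure_python_replay(self, centered_system):
        """Replaying one sweep move-by-move with the reference numpy energy
        functions reproduces the compiled kernel's trajectory."""
        from mlqmmm.freeenergy import (_mol_env_energy, _rotation_matrix,
                                       _solute_coupling_one, _sweep_kernel)
        rc, _, solute, box = centered_system
        scheme = EmbeddingScheme()
        rng = np.random.default_rng(123)
        n = box.n_waters
        waters = box.waters.copy()
        esp_q = solute.esp_charges(rc)
        lj_p = solute_lj_params(solute.labels)
        sig = 0.5 * (lj_p[:, 0] + box.water_params.sigma_oo)
        eps = np.sqrt(lj_p[:, 1] * box.water_params.epsilon_oo)
        qw = box.water_params.site_charges
        coul = np.zeros(n)
        lj = np.zeros(n)
        inside = np.zeros(n, dtype=bool)
        for i in range(n):
            coul[i], lj[i], inside[i] = _solute_coupling_one(
                waters[i], rc, esp_q, sig, eps, qw, scheme.cutoff)
        idx = rng.integers(n, size=n)
        disp = rng.uniform(-0.18, 0.18, (n, 3))
        axes = rng.normal(size=(n, 3))
        angles = rng.uniform(-0.4, 0.4, n)
        u_acc = rng.random(n)
        teleport = rng.random(n) < 0.2
        targets = rng.uniform(0.0, box.length, (n, 3))
        kt = 0.592486
        ww_cut = scheme.cutoff

        ref = waters.copy()
        ref_coul, ref_lj, ref_in = coul.copy(), lj.copy(), inside.copy()
        for k in range(n):
            i = int(idx[k])
            old = ref[i].copy()
            if teleport[k]:
                new = old - old[0] + targets[k]
            else:
                new = old + disp[k]
            R = _rotation_matrix(axes[k], angles[k])
            new[1:] = new[0] + (new[1:] - new[0]) @ R.T
            if np.any(new < 0.0) or np.any(new >= box.length):
                continue
            sites = ref.reshape(n * 3, 3)
            q_flat = np.tile(qw, n)
            oxy = ref[:, 0, :]
            e_old = _mol_env_energy(sites, q_flat, oxy, i, old,
                                    box.water_params, ww_cut)
            e_new = _mol_env_energy(sites, q_flat, oxy, i, new,
                                    box.water_params, ww_cut)
            c_new, l_new, in_new = _solute_coupling_one(
                new, rc, esp_q, sig, eps, qw, scheme.cutoff)
            scale = solute.level_scale["ESP"]
            c_old_lvl = (scale * ref_coul[i] if ref_in[i] else ref_coul[i]) + ref_lj[i]
            c_new_lvl = (scale * c_new if in_new else c_new) + l_new
            de = (e_new - e_old) + (c_new_lvl - c_old_lvl)
            if de <= 0 or u_acc[k] < np.exp(-de / kt):
                ref[i] = new
                ref_coul[i], ref_lj[i], ref_in[i] = c_new, l_new, in_new

        _sweep_kernel(waters, coul, lj, inside, idx, disp, axes, angles,
                      u_acc, teleport, targets, rc, esp_q, sig, eps, qw,
                      box.water_params.sigma_oo, box.water_params.epsilon_oo,
                      scheme.cutoff, ww_cut, 1.0, float(box.length), kt)
        np.testing.assert_allclose(waters, ref, atol=1e-12)
        np.testing.assert_allclose(coul, ref_coul, atol=1e-9)
        np.testing.assert_allclose(lj, ref_lj, atol=1e-9)

    def test_decoupled_chains_agree_in_distribution(self, solute_system):
        """With zero solute charges and LJ, independent chains sample the same
        pure-water energy distribution (two-sample KS test)."""
        from mlqmmm.synthetic import BoxSpec, generate_box, generate_solute
        _, _, base = solute_system
        _, _, solute = generate_solute(seed=1)
        solute.charges_reactant *= 0.0
        solute.charges_product *= 0.0
        reactant, _, _ = solute_system
        rc = reactant.coords + (3.95 - reactant.coords.mean(axis=0))
        box = generate_box(BoxSpec(length=7.9, n_waters=16, seed=8),
                           exclude=rc)
        scheme = EmbeddingScheme()
        zero_lj = {el: (3.0, 0.0) for el in "CNOH"}
        runs = []
        for seed in (101, 202):
            c = SamplerConfig(n_equilibration=10_000, n_production=15_000,
                              stride=150, seed=seed)
            ens = sample_solvent(rc, solute, box, c, scheme, level="ESP",
                                 lj_table=zero_lj)
            assert np.all(ens.coul_in + ens.coul_out == 0.0)
            assert np.all(ens.lj == 0.0)
            runs.append(ens.e_ww)
        ks = stats.ks_2samp(runs[0], runs[1])
        assert ks.pvalue > 0.01


class TestLevelShift:
    def test_identity_perturbation_exactly_zero(self, sampled):
        _, _, solute, _, _, cfg, ens = sampled
        r = level_shift(ens, solute, "ESP", "ESP", cfg.kT)
        assert r.value == 0.0

    def test_wrong_ensemble_level_rejected(self, sampled):
        _, _, solute, _, _, cfg, ens = sampled
        with pytest.raises(ValueError, match="sampled at"):
            level_shift(ens, solute, "LOW", "HIGH", cfg.kT)

    def test_constant_offset_recovered_exactly(self, sampled):
        """When the tiers differ only by a configuration-independent internal
        term, the shift equals that constant."""
        rc, _, solute, _, _, cfg, ens = sampled
        import copy
        iso = copy.deepcopy(solute)
        iso.level_scale = {"ESP": 1.0, "LOW": 1.0, "HIGH": 1.0}
        r = level_shift(ens, iso, "ESP", "LOW", cfg.kT)
        expected = iso.internal_energy(rc, "LOW")
        assert r.value == pytest.approx(expected, abs=1e-9)
        assert r.se == pytest.approx(0.0, abs=1e-9)


class TestPMF:
    def test_decoupled_limit_reduces_to_gas_profile(self, solute_system):
        """Zero charges and zero LJ: every sampled increment equals the gas
        energy difference exactly (the exponential average collapses)."""
        from mlqmmm.freeenergy import direct_pmf
        from mlqmmm.synthetic import BoxSpec, generate_box, generate_solute
        reactant, product, _ = solute_system
        _, _, solute = generate_solute(seed=1)
        solute.charges_reactant *= 0.0
        solute.charges_product *= 0.0
        rc = reactant.coords + (3.95 - reactant.coords.mean(axis=0))
        pc = product.coords + (3.95 - product.coords.mean(axis=0))
        box = generate_box(BoxSpec(length=7.9, n_waters=16, seed=4),
                           exclude=np.vstack([rc, pc]))
        beads = [(1 - t) * rc + t * pc for t in np.linspace(0, 1, 4)]
        zero_lj = {el: (3.0, 0.0) for el in "CNOH"}
        cfg = SamplerConfig(n_equilibration=30, n_production=60, stride=6,
                            n_chains=2)
        w, se = direct_pmf("LOW", beads, solute, box, cfg, EmbeddingScheme(),
                           master_seed=3, n_windows=1, lj_table=zero_lj)
        gas = np.array([solute.internal_energy(b, "LOW") for b in beads])
        np.testing.assert_allclose(w, gas - gas[0], atol=1e-9)
        np.testing.assert_allclose(se, 0.0, atol=1e-9)

    def test_reversed_path_negates_profile(self, sampled):
        """ΔW(A→B) ≈ −ΔW(B→A) within combined errors (antisymmetry)."""
        rc, pc, solute, box, scheme, _, _ = sampled
        end = rc + 0.25 * (pc - rc)
        beads_f = [rc, 0.5 * (rc + end), end]
        beads_r = beads_f[::-1]
        cfg = SamplerConfig(n_equilibration=400, n_production=1200, stride=8,
                            n_chains=2, seed=0)
        from mlqmmm.freeenergy import direct_pmf
        wf, sef = direct_pmf("ESP", beads_f, solute, box, cfg, scheme,
                             master_seed=11, n_windows=2)
        wr, ser = direct_pmf("ESP", beads_r, solute, box, cfg, scheme,
                             master_seed=12, n_windows=2)
        comb = np.hypot(sef[-1], ser[-1])
        assert abs(wf[-1] + wr[-1]) < 3.5 * comb + 0.05

    def test_pmf_esp_requires_esp_ensembles(self, sampled):
        rc, pc, solute, box, scheme, cfg, ens = sampled
        low_ens = sample_solvent(rc, solute, box, cfg, scheme, level="LOW")
        with pytest.raises(ValueError, match="ESP"):
            pmf_esp([low_ens, low_ens], [rc, pc], solute, box, scheme, cfg)

    def test_profile_invariant_under_water_relabeling(self, sampled):
        """Coupling sums, hence increments, are exactly permutation-invariant."""
        rc, pc, solute, box, scheme, cfg, ens = sampled
        lj_p = solute_lj_params(solute.labels)
        perm = np.random.default_rng(0).permutation(box.n_waters)
        ci0, co0, lj0 = batch_coupling(ens.configs, pc,
                                       solute.esp_charges(pc), lj_p, box,
                                       scheme)
        ci1, co1, lj1 = batch_coupling(ens.configs[:, perm], pc,
                                       solute.esp_charges(pc), lj_p, box,
                                       scheme)
        np.testing.assert_allclose(ci0, ci1, atol=1e-10)
        np.testing.assert_allclose(lj0, lj1, atol=1e-10)


class TestCompose:
    def _zero(self, n):
        return [FEPResult(0.0, 0.0) for _ in range(n)]

    def test_all_shifts_zero_gives_esp_profile(self):
        inc = np.array([1.0, 2.0, -0.5])
        pmf = compose(inc, np.zeros(3), self._zero(4), self._zero(4))
        np.testing.assert_allclose(pmf.w_high, pmf.w_esp)
        np.testing.assert_allclose(pmf.w_esp, [0.0, 1.0, 3.0, 2.5])

    def test_constant_shifts_cancel(self):
        inc = np.array([1.0, 2.0, -0.5])
        const = [FEPResult(4.2, 0.1) for _ in range(4)]
        pmf = compose(inc, np.zeros(3), const, const)
        assert pmf.barrier("HIGH")[0] == pytest.approx(pmf.barrier("ESP")[0])
        np.testing.assert_allclose(pmf.w_high, pmf.w_esp)

    def test_missing_bead_errors_with_gap_list(self):
        inc = np.array([1.0, 2.0, -0.5])
        bad = self._zero(4)
        bad[2] = FEPResult(np.nan, 0.0)
        with pytest.raises(ValueError, match=r"beads \[2\]"):
            compose(inc, np.zeros(3), bad, self._zero(4))

    def test_se_propagation_monotone_along_profile(self):
        inc = np.array([1.0, 1.0, 1.0])
        se = np.array([0.1, 0.2, 0.3])
        pmf = compose(inc, se, self._zero(4), self._zero(4))
        assert np.all(np.diff(pmf.se_esp) >= 0)
        assert pmf.se_esp[-1] == pytest.approx(np.sqrt(0.01 + 0.04 + 0.09))


class TestSolventDecomposition:
    def test_worked_example_bookkeeping(self):
        """Solvent 6.0/27.9 plus polarization 9.4/8.7/8.6 nets to 5.3 barrier
        and 27.1 reaction contributions with −0.7/−0.8 net polarization."""
        d = SolventDecomposition(solvent_barrier=6.0, solvent_reaction=27.9,
                                 polarization_reactant=9.4,
                                 polarization_ts=8.7,
                                 polarization_product=8.6)
        assert d.net_polarization_ts == pytest.approx(-0.7)
        assert d.net_polarization_product == pytest.approx(-0.8)
        assert d.aqueous_barrier_contribution == pytest.approx(5.3)
        assert d.aqueous_reaction_contribution == pytest.approx(27.1)

    def test_additivity_identity_random(self, rng):
        for _ in range(200):
            sb, sr, p0, p1, p2 = rng.normal(0, 10, 5)
            d = SolventDecomposition(sb, sr, p0, p1, p2)
            assert d.aqueous_barrier_contribution == pytest.approx(
                d.solvent_barrier + d.net_polarization_ts, abs=1e-10)
            assert d.aqueous_reaction_contribution == pytest.approx(
                d.solvent_reaction + d.net_polarization_product, abs=1e-10)
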