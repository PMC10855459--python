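import numpy as np
import pytest
from scipy.optimize import brentq

from plugmd import alchemy, fixtures
from plugmd.alchemy import (AlchemicalHamiltonian, LambdaSchedule,
                            MBARConvergenceError, ReducedEnergyMatrix,
                            alchemical_energy, convergence_series,
                            hydration_free_energy, mbar_solve,
                            overlap_matrix, run_lambda_ladder)
from plugmd.constants import KB
from plugmd.plugin import RegionTerm
from plugmd.potentials import HarmonicWellPotential, PotentialModel, ZeroPotential

T = 300.0
KT = KB * T
BETA = 1.0 / KT


class ConstantPotential(PotentialModel):
    def __init__(self, value):
        self.value = float(value)

    def _compute(self, pos, box):
        return self.value, np.zeros_like(pos)


def two_particle_hamiltonian(lam, k_coupled=400.0, k_solo=100.0):
    return AlchemicalHamiltonian(
        lam, HarmonicWellPotential(k_coupled),
        RegionTerm(HarmonicWellPotential(k_solo), [0], 2),
        RegionTerm(HarmonicWellPotential(k_solo), [1], 2),
        group_i=[1], group_j=[0], n_total=2)


def harmonic_reduced_matrix(k1, k2, n, seed):
    """Exact canonical samples of two 1-D harmonic states."""
    rng = np.random.default_rng(seed)
    x = np.concatenate([rng.normal(0, np.sqrt(KT / k1), n),
                        rng.normal(0, np.sqrt(KT / k2), n)])
    u = np.vstack([BETA * 0.5 * k1 * x**2, BETA * 0.5 * k2 * x**2])
    return ReducedEnergyMatrix(u, np.array([n, n]), T)


def bar_oracle(u, n0, n1, lo=-50.0, hi=50.0):
    """Independent BAR estimate of f1 - f0 (implicit-equation root)."""
    w_f = u[1, :n0] - u[0, :n0]          # forward work from state 0
    w_r = u[0, n0:] - u[1, n0:]          # reverse work from state 1
    m = np.log(n1 / n0)

    def g(df):
        a = np.sum(1.0 / (1.0 + np.exp(m + w_f - df)))
        b = np.sum(1.0 / (1.0 + np.exp(-m + w_r + df)))
        return a - b

    return brentq(g, lo, hi, xtol=1e-12)


class TestAlchemicalHamiltonian:
    def test_endpoints_exact(self):
        pos = np.array([[0.1, 0.2, -0.1], [0.05, 0.0, 0.3]])
        full = HarmonicWellPotential(400.0)
        h1 = two_particle_hamiltonian(1.0)
        e, f = alchemical_energy(h1, pos)
        e_ref, f_ref = full.evaluate(pos)
        assert e == e_ref
        np.testing.assert_array_equal(f, f_ref)

        h0 = two_particle_hamiltonian(0.0)
        e0, _ = alchemical_energy(h0, pos)
        solo = HarmonicWellPotential(100.0)
        assert e0 == pytest.approx(solo.evaluate(pos)[0], rel=1e-14)

    def test_midpoint_arithmetic(self):
        """U(0.5) with U_A = 10, U_B1 = 3, U_B2 = 4 is 8.5 kJ/mol."""
        h = AlchemicalHamiltonian(0.5, ConstantPotential(10.0),
                                  ConstantPotential(3.0),
                                  ConstantPotential(4.0),
                                  group_i=[1], group_j=[0], n_total=2)
        e, _ = alchemical_energy(h, np.zeros((2, 3)))
        assert e == pytest.approx(8.5, abs=1e-14)

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            AlchemicalHamiltonian(0.5, ConstantPotential(0),
                                  ConstantPotential(0), ConstantPotential(0),
                                  group_i=[0, 1], group_j=[1], n_total=2)

    def test_groups_must_cover_system(self):
        with pytest.raises(ValueError, match="cover"):
            AlchemicalHamiltonian(0.5, ConstantPotential(0),
                                  ConstantPotential(0), ConstantPotential(0),
                                  group_i=[0], group_j=[1], n_total=3)


class TestLambdaSchedule:
    def test_default_is_ten_states_dense_near_zero(self):
        s = LambdaSchedule()
        assert len(s) == 10
        assert s.values[0] == 0.0 and s.values[-1] == 1.0

    def test_rejects_unsorted_or_open_schedules(self):
        with pytest.raises(ValueError):
            LambdaSchedule((0.0, 0.5, 0.4, 1.0))
        with pytest.raises(ValueError):
            LambdaSchedule((0.1, 0.5, 1.0))


class TestMBAR:
    def test_identical_states_give_zero(self):
        m = harmonic_reduced_matrix(100.0, 100.0, 2000, seed=1)
        res = mbar_solve(m)
        dg, se = res.delta_G(0, 1)
        assert dg == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(res.overlap, 0.5, atol=1e-12)

    def test_harmonic_free_energy_matches_partition_function(self):
        """Delta A = (kT/2) ln(k2/k1) ~ 1.729 kJ/mol for k 100 -> 400."""
        m = harmonic_reduced_matrix(100.0, 400.0, 4000, seed=0)
        res = mbar_solve(m)
        dg, se = res.delta_G(0, 1)
        exact = 0.5 * KT * np.log(4.0)
        assert exact == pytest.approx(1.729, abs=5e-4)  # printed-value anchor
        assert abs(dg - exact) < 3 * se

    def test_mbar_reduces_to_bar_for_two_states(self):
        m = harmonic_reduced_matrix(100.0, 400.0, 3000, seed=5)
        res = mbar_solve(m)
        df_mbar = res.delta_f(0, 1)[0]
        df_bar = bar_oracle(m.u, 3000, 3000)
        assert df_mbar == pytest.approx(df_bar, abs=1e-6)

    def test_antisymmetry(self):
        m = harmonic_reduced_matrix(100.0, 400.0, 1000, seed=6)
        res = mbar_solve(m)
        assert res.delta_G(0, 1)[0] == pytest.approx(-res.delta_G(1, 0)[0])

    def test_invariant_to_per_sample_shift(self):
        m = harmonic_reduced_matrix(100.0, 400.0, 1000, seed=7)
        shifted = ReducedEnergyMatrix(m.u + np.linspace(0, 5, m.u.shape[1]),
                                      m.n_k, m.temperature)
        a = mbar_solve(m).delta_f(0, 1)[0]
        b = mbar_solve(shifted).delta_f(0, 1)[0]
        assert b == pytest.approx(a, abs=1e-9)

    def test_overlap_rows_sum_to_one(self):
        for seed in range(3):
            m = harmonic_reduced_matrix(100.0, 250.0, 500, seed=seed)
            o = overlap_matrix(mbar_solve(m))
            np.testing.assert_allclose(o.sum(axis=1), 1.0, atol=1e-8)
            assert np.all(o >= 0)

    def test_disjoint_supports_give_identity_overlap(self):
        # disjoint energy supports: cross-state energies are enormous
        rng = np.random.default_rng(8)
        n = 400
        u = np.zeros((2, 2 * n))
        u[0, :n] = rng.normal(0, 1, n)
        u[1, :n] = 1e4
        u[1, n:] = rng.normal(0, 1, n)
        u[0, n:] = 1e4
        o = overlap_matrix(mbar_solve(u, np.array([n, n])))
        np.testing.assert_allclose(o, np.eye(2), atol=1e-6)

    def test_convergence_error_reported(self):
        m = harmonic_reduced_matrix(100.0, 400.0, 200, seed=9)
        with pytest.raises(MBARConvergenceError):
            mbar_solve(m, tol=1e-15, max_iter=1)

    def test_requires_two_states_and_samples(self):
        with pytest.raises(ValueError):
            mbar_solve(np.zeros((1, 10)), np.array([10]))
        with pytest.raises(ValueError):
            mbar_solve(np.zeros((2, 10)), np.array([10, 0]))


class TestLambdaLadder:
    def test_identical_states_have_identical_reduced_energies(self):
        system = fixtures.harmonic_toy_system(2, T=T, seed=1)

        def factory(lam):
            return two_particle_hamiltonian(0.5)  # same H at every lambda

        _, mat = run_lambda_ladder(system, factory,
                                   LambdaSchedule((0.0, 1.0)),
                                   steps_per_state=500, save_every=50,
                                   seed=2)
        np.testing.assert_allclose(mat.u[0], mat.u[1], atol=1e-12)

    def test_default_schedule_matrix_shape(self):
        system = fixtures.harmonic_toy_system(2, T=T, seed=3)
        _, mat = run_lambda_ladder(system, two_particle_hamiltonian,
                                   steps_per_state=200, save_every=50,
                                   seed=4)
        assert mat.u.shape[0] == 10
        assert mat.u.shape[1] == int(mat.n_k.sum())

    def test_single_solute_reduced_energies_closed_form(self):
        """One harmonic particle with an empty environment: u[k][n] must be
        beta * 0.5 * k_lambda * |x_n|^2 exactly."""
        system = fixtures.harmonic_toy_system(1, T=T, seed=5)
        k_a, k_b = 300.0, 100.0

        def factory(lam):
            return AlchemicalHamiltonian(
                lam, HarmonicWellPotential(k_a), ZeroPotential(),
                HarmonicWellPotential(k_b), group_i=[0], group_j=[],
                n_total=1)

        trajs, mat = run_lambda_ladder(system, factory,
                                       LambdaSchedule((0.0, 0.5, 1.0)),
                                       steps_per_state=300, save_every=50,
                                       seed=6, burn_in_fraction=0.0)
        frames = np.concatenate([t.positions_array() for t in trajs])
        lambdas = (0.0, 0.5, 1.0)
        for k, lam in enumerate(lambdas):
            k_eff = lam * k_a + (1 - lam) * k_b
            expected = BETA * 0.5 * k_eff * np.sum(frames[:, 0, :]**2, axis=1)
            np.testing.assert_allclose(mat.u[k], expected, rtol=1e-10)

    def test_ladder_recovers_analytic_free_energy(self):
        """Two 3-D particles switched 100 -> 400 kJ/(mol nm^2):
        Delta A = 2 * (3/2) kT ln 4."""
        system = fixtures.harmonic_toy_system(2, T=T, seed=3)
        _, mat = run_lambda_ladder(
            system, two_particle_hamiltonian,
            LambdaSchedule((0.0, 0.25, 0.5, 0.75, 1.0)),
            steps_per_state=30000, save_every=250, seed=7, dt=0.002,
            coupling=5.0)
        res = mbar_solve(mat)
        dg, se = res.delta_G(0, -1)
        exact = 2 * 1.5 * KT * np.log(4.0)
        assert abs(dg - exact) < 3 * se

    def test_path_independence_five_vs_ten_states(self):
        system = fixtures.harmonic_toy_system(2, T=T, seed=8)
        results = []
        for schedule in (LambdaSchedule(tuple(np.linspace(0, 1, 5))),
                         LambdaSchedule(tuple(np.linspace(0, 1, 10)))):
            _, mat = run_lambda_ladder(system, two_particle_hamiltonian,
                                       schedule, steps_per_state=30000,
                                       save_every=250, seed=9, dt=0.002,
                                       coupling=5.0)
            results.append(mbar_solve(mat).delta_G(0, -1))
        (dg5, se5), (dg10, se10) = results
        assert abs(dg5 - dg10) < 3 * np.hypot(se5, se10)

    def test_hydration_sign_convention(self):
        m = harmonic_reduced_matrix(100.0, 400.0, 1000, seed=10)
        res = mbar_solve(m)
        # schedule (0, 1): state 0 decoupled, state 1 coupled
        dg_decouple = res.delta_G(1, 0)[0]
        hyd, _ = hydration_free_energy(res, (0.0, 1.0))
        assert hyd == pytest.approx(-dg_decouple)

    def test_convergence_series_final_point_equals_full_solve(self):
        system = fixtures.harmonic_toy_system(2, T=T, seed=11)
        _, mat = run_lambda_ladder(system, two_particle_hamiltonian,
                                   LambdaSchedule((0.0, 0.5, 1.0)),
                                   steps_per_state=2000, save_every=20,
                                   seed=12, dt=0.002)
        series = convergence_series(mat, fractions=(0.5, 1.0))
        full_dg = mbar_solve(mat).delta_G(0, -1)[0]
        assert series.iloc[-1]["delta_G_kjmol"] == pytest.approx(full_dg)
        assert series.iloc[-1]["se_kjmol"] < series.iloc[0]["se_kjmol"]
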