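"""Optimal control solver: state builders, augmented system, trajectories."""

import numpy as np
import pytest
from scipy.linalg import expm

from ctrlenergy.control import (
    BrainState,
    ControlTask,
    build_augmented_system,
    build_state,
    cohort_energy,
    solve_optimal_control,
    summarize_trajectory,
)
from ctrlenergy.errors import ParameterError, ValidationError
from ctrlenergy.network import NormalizedMatrix, normalize_adjacency

from conftest import random_connectome

SYSTEMS5 = np.array(["x", "fp", "x", "fp", "x"])


class TestBuildState:
    def test_baseline_zero(self):
        s = build_state(SYSTEMS5, "baseline")
        np.testing.assert_array_equal(s.values, np.zeros(5))

    def test_system_indicator(self):
        s = build_state(np.array(["x", "fp", "x", "fp"]), "system_indicator", system="fp")
        np.testing.assert_array_equal(s.values, [0, 1, 0, 1])

    def test_unknown_system(self):
        with pytest.raises(ValidationError):
            build_state(SYSTEMS5, "system_indicator", system="nope")

    def test_noisy_targets_monte_carlo(self):
        states = build_state(
            SYSTEMS5, "noisy", system="fp", noise_sd=0.1, count=100, seed=5
        )
        arr = np.array([s.values for s in states])
        on = arr[:, SYSTEMS5 == "fp"]
        off = arr[:, SYSTEMS5 != "fp"]
        # se = 0.1/sqrt(100) = 0.01, so means stay within 1 +/- 0.04
        assert np.all(np.abs(on.mean(axis=0) - 1.0) < 0.04)
        assert np.all(off == 0.0)

    def test_continuous_from_file(self, tmp_path):
        vec = np.array([0.2, -1.0, 3.5, 0.0, 1.0])
        path = tmp_path / "target.txt"
        np.savetxt(path, vec)
        s = build_state(SYSTEMS5, "continuous_from_file", path=path)
        np.testing.assert_allclose(s.values, vec)
        with pytest.raises(ValidationError):
            build_state(np.array(["x"] * 4), "continuous_from_file", path=path)


def _simple_task(n=2, rho=1.0, xt=None, a=None, **kw):
    a = -np.eye(n) if a is None else a
    norm = NormalizedMatrix(a, "control", 1.0)
    xt = np.ones(n) if xt is None else xt
    return ControlTask(
        normalized_A=norm, x0=BrainState(np.zeros(n)), xT=BrainState(xt), rho=rho, **kw
    )


class TestAugmentedSystem:
    def test_two_node_substitution(self):
        """Atilde blocks and btilde for A=-I, B=S=I, rho=1, xT=(1,1)."""
        aug = build_augmented_system(_simple_task())
        expected = np.block(
            [[-np.eye(2), -0.5 * np.eye(2)], [-2.0 * np.eye(2), np.eye(2)]]
        )
        np.testing.assert_allclose(aug.a_tilde, expected, atol=1e-15)
        np.testing.assert_allclose(aug.b_tilde, [0, 0, 2, 2], atol=1e-15)

    def test_shapes(self, rng):
        conn = random_connectome(rng, n=6)
        norm = normalize_adjacency(conn, "control")
        task = ControlTask(norm, BrainState(np.zeros(6)), BrainState(rng.standard_normal(6)))
        aug = build_augmented_system(task)
        assert aug.a_tilde.shape == (12, 12)
        assert aug.b_tilde.shape == (12,)
        assert aug.e12.shape == (6, 6)

    def test_c_solve_residual(self, rng):
        """c satisfies Atilde c = (e^{Atilde T} - I) btilde on random tasks."""
        for _ in range(5):
            conn = random_connectome(rng, n=8)
            norm = normalize_adjacency(conn, "control")
            task = ControlTask(
                norm,
                BrainState(np.zeros(8)),
                BrainState(rng.standard_normal(8)),
                constrained_set=np.arange(4),
            )
            aug = build_augmented_system(task)
            c = np.concatenate([aug.c1, aug.c2])
            e_t = expm(aug.a_tilde * task.horizon_T)
            rhs = (e_t - np.eye(16)) @ aug.b_tilde
            resid = np.linalg.norm(aug.a_tilde @ c - rhs)
            assert resid < 1e-8 * np.linalg.norm(aug.b_tilde)


class TestTaskValidation:
    def test_rho_positive(self):
        with pytest.raises(ParameterError, match="rho"):
            _simple_task(rho=-1.0)

    def test_dt_divides_horizon(self):
        with pytest.raises(ParameterError):
            _simple_task(dt=0.0003)

    def test_step_count_bookkeeping(self):
        task = _simple_task(horizon_T=1.0, dt=0.001)
        assert task.n_steps == 1000
        sol = solve_optimal_control(task)
        assert sol.states.shape[0] == 1001  # 1,000 steps after t=0


class TestSolver:
    def test_null_transition_zero_energy(self):
        task = _simple_task(xt=np.zeros(2))
        sol = solve_optimal_control(task)
        assert sol.total_energy < 1e-10
        assert np.max(np.abs(sol.inputs)) < 1e-8

    def test_terminal_accuracy(self, rng):
        conn = random_connectome(rng, n=8)
        norm = normalize_adjacency(conn, "control")
        xt = rng.standard_normal(8)
        task = ControlTask(norm, BrainState(np.zeros(8)), BrainState(xt))
        sol = solve_optimal_control(task)
        assert sol.terminal_error <= 1e-6 * max(1.0, np.linalg.norm(xt))
        assert sol.distance_series[-1] <= 1e-6 * max(1.0, np.linalg.norm(xt))

    def test_quadratic_scaling(self, rng):
        """Energy scales as c^2 when the target is scaled by c (x0 = 0)."""
        conn = random_connectome(rng, n=6)
        norm = normalize_adjacency(conn, "control")
        xt = rng.standard_normal(6)
        base = solve_optimal_control(
            ControlTask(norm, BrainState(np.zeros(6)), BrainState(xt))
        ).total_energy
        for c in (2.0, 3.0):
            scaled = solve_optimal_control(
                ControlTask(norm, BrainState(np.zeros(6)), BrainState(c * xt))
            ).total_energy
            assert abs(scaled / base - c**2) / c**2 < 1e-8

    def test_matches_direct_transcription_oracle(self, rng):
        """Total energy within 1% of an independent QP solution."""
        from oracles import qp_direct_transcription_energy

        for trial in range(4):
            n = int(rng.integers(3, 8))
            conn = random_connectome(rng, n=n)
            norm = normalize_adjacency(conn, "control")
            x0 = rng.standard_normal(n) * 0.3
            xt = rng.standard_normal(n)
            constrained = np.arange(n) if trial % 2 == 0 else np.arange(max(1, n // 2))
            task = ControlTask(
                norm, BrainState(x0), BrainState(xt), constrained_set=constrained
            )
            sol = solve_optimal_control(task)
            s_diag = np.zeros(n)
            s_diag[constrained] = 1.0
            e_qp = qp_direct_transcription_energy(
                norm.matrix, s_diag, x0, xt, steps=300
            )
            assert abs(sol.total_energy - e_qp) / e_qp < 0.01

    def test_energy_decomposition(self, rng):
        conn = random_connectome(rng, n=6)
        norm = normalize_adjacency(conn, "control")
        sol = solve_optimal_control(
            ControlTask(norm, BrainState(np.zeros(6)), BrainState(rng.standard_normal(6)))
        )
        assert sol.total_energy == pytest.approx(sol.nodal_energy.sum(), rel=1e-12)
        assert np.all(sol.nodal_energy >= 0)

    def test_restricted_control_set_inputs_zero(self, rng):
        conn = random_connectome(rng, n=6)
        norm = normalize_adjacency(conn, "control")
        task = ControlTask(
            norm,
            BrainState(np.zeros(6)),
            BrainState(rng.standard_normal(6)),
            control_set=np.array([0, 1, 2, 3]),
        )
        sol = solve_optimal_control(task)
        assert np.max(np.abs(sol.inputs[:, 4:])) == 0.0
        assert np.all(sol.nodal_energy[4:] == 0.0)


class TestSummaries:
    def test_system_means_consistent(self, rng):
        conn = random_connectome(rng, n=6)
        norm = normalize_adjacency(conn, "control")
        systems = np.array(["a", "a", "a", "b", "b", "b"])
        sol = solve_optimal_control(
            ControlTask(norm, BrainState(np.zeros(6)), BrainState(rng.standard_normal(6)))
        )
        summ = summarize_trajectory(sol, systems)
        assert summ["system_energy"]["a"] == pytest.approx(sol.nodal_energy[:3].mean())
        assert summ["whole_brain_energy"] == pytest.approx(sol.nodal_energy.mean())
        assert summ["total_distance"] == pytest.approx(sol.distance_series.sum())

    def test_quadrature_closed_forms(self):
        """Trapezoid on the stored grid: exact for u=1, ~1e-5 close for u=t."""
        dt = 0.001
        grid = np.arange(0, 1 + dt / 2, dt)
        const = np.trapezoid(np.ones_like(grid) ** 2, dx=dt)
        assert const == pytest.approx(1.0, abs=1e-12)
        ramp = np.trapezoid(grid**2, dx=dt)
        assert ramp == pytest.approx(1.0 / 3.0, abs=1e-5)


class TestCohortLevelProperties:
    def test_distance_energy_coupling(self, small_energy):
        """Subjects with longer transition trajectories need more energy."""
        r = np.corrcoef(
            small_energy.summaries["total_distance"],
            small_energy.summaries["total_energy"],
        )[0, 1]
        assert r > 0.9

    def test_terminal_errors_across_cohort(self, small_energy):
        assert small_energy.summaries["terminal_error"].max() <= 1e-6

    def test_constraint_set_robustness(self, small_cohort, small_energy):
        """Whole-brain energy with S=FP-only vs S=all nodes correlates highly."""
        res_all = cohort_energy(
            small_cohort.connectomes,
            small_cohort.phenotypes["subject_id"],
            small_cohort.systems,
            constrain="all",
        )
        r = np.corrcoef(
            small_energy.summaries["whole_brain_energy"],
            res_all.summaries["whole_brain_energy"],
        )[0, 1]
        assert r > 0.8
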