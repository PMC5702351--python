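"""Circuit construction, dynamics, perturbations and metrics.

Steady states are cross-checked against two independent oracles implemented
here: a damped Picard iteration on the rectified fixed-point equations and,
when every unit is strictly positive at the fixed point, a direct linear
solve with the rectifiers removed.
"""

import numpy as np
import pytest

from tectumds import circuit
from tectumds.angles import circ_dist_deg, vm_pdf_deg
from tectumds.circuit import (CircuitSpec, PerturbationSpec, SimulationConfig,
                              TuningCurve, UnitSpec, apply_perturbation, build_weights,
                              calibrate_kappa, default_circuit, perturbed_weights,
                              rgc_drive, solve_fixed_point, steady_state, tuning_curves,
                              tuning_metrics)


def picard_oracle(weights, f, damping=0.3, tol=1e-14, iters=200_000):
    """Independent fixed-point solver for the rectified rate equations."""
    s = np.zeros(weights.w_ss.shape[0])
    for _ in range(iters):
        s_new = np.maximum(weights.w_sr @ f - weights.w_ss @ s, 0.0)
        if np.abs(s_new - s).max() < tol:
            s = s_new
            break
        s = (1 - damping) * s + damping * s_new
    p = np.maximum(weights.w_pr @ f - weights.w_ps @ s, 0.0)
    return f, s, p


def linear_oracle(weights, f):
    """Fixed point with rectifiers assumed inactive: (I + w_ss) s = w_sr f."""
    s = np.linalg.solve(np.eye(weights.w_ss.shape[0]) + weights.w_ss, weights.w_sr @ f)
    p = weights.w_pr @ f - weights.w_ps @ s
    return f, s, p


class TestConstruction:
    def test_default_circuit_shape(self):
        spec = default_circuit()
        assert len(spec.units) == 10
        r = spec.by_layer("RGC")
        assert [u.theta_deg for u in r] == [24.0, 124.0, 256.0]
        p2_exc = [e for e in spec.excitatory_edges if e[1] == "P2"]
        p2_inh = [e for e in spec.inhibitory_edges if e[1] == "P2"]
        assert sorted(e[0] for e in p2_exc) == ["R1", "R2"]
        assert sorted(e[0] for e in p2_inh) == ["S1", "S2", "S3"]

    def test_invalid_edges_rejected(self):
        units = (UnitSpec("R1", "RGC", 0.0, 1.0), UnitSpec("S1", "SIN"),
                 UnitSpec("P1", "PVN"))
        with pytest.raises(ValueError):  # inhibition from a non-SIN source
            CircuitSpec(units, frozenset(), frozenset({("P1", "S1")}))
        with pytest.raises(ValueError):  # excitation from a non-RGC source
            CircuitSpec(units, frozenset({("S1", "P1")}), frozenset())
        with pytest.raises(ValueError):  # self edge
            CircuitSpec(units, frozenset(), frozenset({("S1", "S1")}))

    def test_divisive_normalization(self):
        w = build_weights(default_circuit())
        assert w.w_pr.sum() == pytest.approx(1.0)
        assert np.all(w.w_pr[w.w_pr > 0] == pytest.approx(1 / 5))  # 5 RGC->PVN edges
        assert np.all(w.w_ss[w.w_ss > 0] == pytest.approx(1 / 6))  # 6 SIN<->SIN edges
        assert np.all(w.w_sr[w.w_sr > 0] == pytest.approx(1 / 3))
        assert np.all(w.w_ps[w.w_ps > 0] == pytest.approx(1 / 3))

    def test_edgeless_matrix_stays_zero(self):
        units = (UnitSpec("R1", "RGC", 0.0, 1.0), UnitSpec("S1", "SIN"),
                 UnitSpec("P1", "PVN"))
        spec = CircuitSpec(units, frozenset({("R1", "P1")}), frozenset())
        w = build_weights(spec)
        assert np.all(w.w_ss == 0.0) and np.all(w.w_sr == 0.0)


class TestKappaCalibration:
    def test_closed_form_at_180(self):
        assert calibrate_kappa(180.0) == pytest.approx(np.log(2.0))

    def test_round_trip_with_dense_grid_oracle(self):
        from tectumds.angles import vm_shape

        k = calibrate_kappa(107.0)
        grid = np.arange(0.0, 360.0, 0.01)
        width = (vm_shape(grid, 180.0, k) >= 0.5).sum() * 0.01
        assert width == pytest.approx(107.0, abs=0.05)

    def test_monotone(self):
        assert calibrate_kappa(60.0) > calibrate_kappa(120.0) > calibrate_kappa(300.0)

    def test_invalid_fwhm_rejected(self):
        with pytest.raises(ValueError):
            calibrate_kappa(360.0)


class TestDrive:
    def test_peak_at_preferred_direction(self):
        u = UnitSpec("R1", "RGC", theta_deg=24.0, kappa=2.0)
        grid = np.arange(0.0, 360.0, 1.0)
        assert grid[np.argmax(rgc_drive(grid, u))] == 24.0

    def test_kappa_zero_is_uniform(self):
        u = UnitSpec("R1", "RGC", theta_deg=0.0, kappa=0.0)
        vals = rgc_drive(np.arange(0.0, 360.0, 30.0), u)
        assert np.allclose(vals, 1.0 / (2 * np.pi))

    def test_density_integrates_to_one(self):
        u = UnitSpec("R1", "RGC", theta_deg=77.0, kappa=3.0)
        grid = np.arange(0.0, 360.0, 0.1)
        integral = rgc_drive(grid, u).sum() * np.deg2rad(0.1)
        assert integral == pytest.approx(1.0, abs=1e-6)

    def test_non_rgc_unit_rejected(self):
        with pytest.raises(ValueError):
            rgc_drive(0.0, UnitSpec("S1", "SIN"))


def _chain_spec():
    units = (UnitSpec("R1", "RGC", theta_deg=0.0, kappa=0.0), UnitSpec("S1", "SIN"),
             UnitSpec("P1", "PVN"))
    return CircuitSpec(units, frozenset({("R1", "P1")}), frozenset())


class TestSteadyState:
    def test_pure_excitatory_chain_passes_drive_through(self):
        spec = _chain_spec()
        state = steady_state(spec, build_weights(spec), 90.0)
        assert state.p[0] == pytest.approx(1.0 / (2 * np.pi), abs=1e-8)

    def test_rectifier_zeroes_dominated_unit(self):
        units = (UnitSpec("R1", "RGC", theta_deg=0.0, kappa=0.0), UnitSpec("S1", "SIN"),
                 UnitSpec("P1", "PVN"))
        spec = CircuitSpec(units, frozenset({("R1", "S1")}), frozenset({("S1", "P1")}))
        state = steady_state(spec, build_weights(spec), 0.0)
        assert state.p[0] == pytest.approx(0.0, abs=1e-9)  # inhibition only
        assert state.s[0] == pytest.approx(1.0 / (2 * np.pi), abs=1e-8)

    def test_all_rates_nonnegative(self, refined_circuit):
        w = build_weights(refined_circuit)
        for theta in (0.0, 45.0, 90.0, 200.0, 300.0):
            st = steady_state(refined_circuit, w, theta)
            assert np.all(st.r >= 0) and np.all(st.s >= 0) and np.all(st.p >= 0)

    def test_fixed_point_independent_of_tau(self, refined_circuit):
        w = build_weights(refined_circuit)
        cfg1 = SimulationConfig(tau=1.0, tol=1e-12)
        cfg5 = SimulationConfig(tau=5.0, tol=1e-12)
        a = steady_state(refined_circuit, w, 90.0, cfg1)
        b = steady_state(refined_circuit, w, 90.0, cfg5)
        for x, y in ((a.r, b.r), (a.s, b.s), (a.p, b.p)):
            assert np.abs(x - y).max() <= 1e-9

    def test_non_convergence_raises(self, refined_circuit):
        w = build_weights(refined_circuit)
        cfg = SimulationConfig(tol=1e-12, max_steps=5)
        with pytest.raises(RuntimeError, match="steady state"):
            steady_state(refined_circuit, w, 90.0, cfg)

    def test_agrees_with_independent_oracles(self, refined_circuit):
        """Euler vs damped Picard (and a linear solve when rates stay positive)
        on the full default circuit at an off-peak stimulus."""
        w = build_weights(refined_circuit)
        st = steady_state(refined_circuit, w, 90.0)
        f = np.array([rgc_drive(90.0, u) for u in refined_circuit.by_layer("RGC")])
        _, s_ref, p_ref = picard_oracle(w, f)
        assert np.abs(st.s - s_ref).max() <= 1e-8
        assert np.abs(st.p - p_ref).max() <= 1e-8


class TestTuningCurves:
    def test_rgc_argmax_at_preferred(self, refined_circuit):
        curves = tuning_curves(refined_circuit, SimulationConfig(direction_grid_deg=2.0))
        for u in refined_circuit.by_layer("RGC"):
            c = curves[u.id]
            assert c.directions[np.argmax(c.response)] == u.theta_deg

    def test_single_input_pvn_inherits_rgc_preference(self, refined_circuit):
        curves = tuning_curves(refined_circuit, SimulationConfig(direction_grid_deg=2.0))
        assert curves["P1"].directions[np.argmax(curves["P1"].response)] == 24.0

    def test_normalization_to_unit_interval(self, refined_circuit):
        curves = tuning_curves(refined_circuit, SimulationConfig(direction_grid_deg=5.0))
        n = curves["P2"].normalized
        assert n.min() == 0.0 and n.max() == 1.0

    def test_euler_and_picard_solvers_agree(self, refined_circuit):
        cfg = SimulationConfig(direction_grid_deg=10.0)
        a = tuning_curves(refined_circuit, cfg, solver="euler")
        b = tuning_curves(refined_circuit, cfg, solver="picard")
        for uid in a:
            assert np.abs(a[uid].response - b[uid].response).max() <= 1e-8


class TestPerturbations:
    def test_full_ablation_removes_all_inhibition(self):
        spec = default_circuit()
        sub = apply_perturbation(spec, PerturbationSpec("ablate", frozenset({"S1", "S2", "S3"})))
        assert sub.inhibitory_edges == frozenset()
        assert len(sub.units) == 7

    def test_no_reciprocal_keeps_feedforward_support(self):
        spec = default_circuit()
        w = perturbed_weights(spec, PerturbationSpec("no_reciprocal_SIN"))
        w0 = build_weights(spec)
        assert np.all(w.w_ss == 0.0)
        for a, b in ((w.w_sr, w0.w_sr), (w.w_pr, w0.w_pr), (w.w_ps, w0.w_ps)):
            assert np.array_equal(a > 0, b > 0)

    def test_single_ablation_edge_bookkeeping(self):
        spec = default_circuit()
        sub = apply_perturbation(spec, PerturbationSpec("ablate", frozenset({"S1"})))
        p2_inh = [e for e in sub.inhibitory_edges if e[1] == "P2"]
        assert sorted(e[0] for e in p2_inh) == ["S2", "S3"]

    def test_ablating_non_sin_rejected(self):
        with pytest.raises(ValueError, match="SIN"):
            apply_perturbation(default_circuit(),
                               PerturbationSpec("ablate", frozenset({"P2"})))

    def test_default_ablation_keeps_surviving_strengths(self):
        """Without renormalization, surviving synapses keep intact strengths."""
        spec = default_circuit()
        w0 = build_weights(spec)
        w = perturbed_weights(spec, PerturbationSpec("ablate", frozenset({"S1"})))
        assert np.all(w.w_ps[:, 0] == 0.0)
        assert np.array_equal(w.w_ps[:, 1:], w0.w_ps[:, 1:])

    def test_renormalized_ablation_rescales(self):
        spec = default_circuit()
        w = perturbed_weights(spec, PerturbationSpec("ablate", frozenset({"S1"})),
                              renormalize=True)
        assert w.w_ps.sum() == pytest.approx(1.0)
        assert np.all(w.w_ps[1, 1:] == pytest.approx(0.5))


class TestTuningMetrics:
    def _vm_curve(self, mu=91.0, kappa=2.0):
        grid = np.arange(0.0, 360.0, 1.0)
        from tectumds.angles import vm_shape

        return TuningCurve(directions=grid, response=vm_shape(grid, mu, kappa))

    def test_tuning_error_simple_and_wrapped(self):
        assert tuning_metrics(self._vm_curve(91.0), 90.0).tuning_error_deg == 1.0
        assert tuning_metrics(self._vm_curve(10.0), 350.0).tuning_error_deg == 20.0

    def test_fwhm_matches_closed_form(self):
        from tectumds.angles import fwhm_from_kappa

        m = tuning_metrics(self._vm_curve(kappa=2.0), 90.0)
        assert m.fwhm_deg == pytest.approx(fwhm_from_kappa(2.0), abs=1.0)

    def test_amplitude_preferred_and_dsi(self):
        m = tuning_metrics(self._vm_curve(91.0, 2.0), 90.0)
        assert m.amplitude == pytest.approx(1.0)
        assert m.preferred_deg == 91.0
        expected_dsi = (1 - np.exp(-4.0)) / (1 + np.exp(-4.0))
        assert m.dsi == pytest.approx(expected_dsi, abs=1e-6)

    def test_constant_curve_rejected(self):
        grid = np.arange(0.0, 360.0, 1.0)
        with pytest.raises(ValueError):
            tuning_metrics(TuningCurve(directions=grid, response=np.ones_like(grid)), 0.0)


class TestRandomCircuitOracles:
    def test_steady_state_matches_picard_on_random_circuits(self):
        """20 random circuits and stimuli: Euler vs independent Picard <= 1e-8;
        when the linear solve is admissible (all rates positive), all three
        agree."""
        rng = np.random.default_rng(2024)
        for trial in range(20):
            thetas = rng.uniform(0, 360, 3)
            kappas = rng.uniform(0.3, 4.0, 3)
            units = tuple(
                [UnitSpec(f"R{i+1}", "RGC", float(thetas[i]), float(kappas[i]))
                 for i in range(3)]
                + [UnitSpec(f"S{i+1}", "SIN") for i in range(3)]
                + [UnitSpec(f"P{i+1}", "PVN") for i in range(4)])
            excit = {(f"R{i+1}", f"S{i+1}") for i in range(3)}
            excit |= {(f"R{rng.integers(1, 4)}", f"P{j+1}") for j in range(4)}
            inhib = {(f"S{i+1}", f"S{j+1}") for i in range(3) for j in range(3)
                     if i != j and rng.random() < 0.7}
            inhib |= {(f"S{i+1}", f"P{rng.integers(1, 5)}") for i in range(3)
                      if rng.random() < 0.8}
            spec = CircuitSpec(units, frozenset(excit), frozenset(inhib))
            w = build_weights(spec)
            theta = float(rng.uniform(0, 360))

            st = steady_state(spec, w, theta)
            f = np.array([rgc_drive(theta, u) for u in spec.by_layer("RGC")])
            _, s_ref, p_ref = picard_oracle(w, f)
            assert np.abs(st.s - s_ref).max() <= 1e-8, f"trial {trial}"
            assert np.abs(st.p - p_ref).max() <= 1e-8, f"trial {trial}"

            _, s_lin, p_lin = linear_oracle(w, f)
            if np.all(s_lin > 1e-9) and np.all(p_lin > 1e-9):
                assert np.abs(st.s - s_lin).max() <= 1e-8
                assert np.abs(st.p - p_lin).max() <= 1e-8


class TestRefinement:
    def test_refined_intact_preference_aligns_with_reference(self, refined_circuit):
        curves = tuning_curves(refined_circuit, solver="picard")
        p2 = curves["P2"]
        pref = p2.directions[np.argmax(p2.response)]
        assert circ_dist_deg(pref, circuit.OBSERVED_P2_PREF_DEG) <= 1.0

    def test_refinement_only_scales_selected_unit(self):
        spec = default_circuit()
        refined = circuit.refine_kappas(spec)
        base = np.array([u.kappa for u in spec.by_layer("RGC")])
        assert refined[1] == base[1] and refined[2] == base[2]
        assert refined[0] != base[0]

    def test_symmetric_drive_without_inhibition_peaks_at_circular_midpoint(self):
        """Equal concentrations on R1/R2 and no SINs: P2 peaks at 74 degrees,
        the circular midpoint of 24 and 124 (kappa kept in the regime where
        the pooled two-bump drive is unimodal)."""
        spec = default_circuit()
        kappas = [0.9, 0.9, spec.by_layer("RGC")[2].kappa]
        sym = spec.with_kappas(kappas)
        w = perturbed_weights(sym, PerturbationSpec("ablate", frozenset({"S1", "S2", "S3"})))
        curves = tuning_curves(sym, weights=w, solver="picard")
        p2 = curves["P2"]
        assert p2.directions[np.argmax(p2.response)] == pytest.approx(74.0, abs=1.0)
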