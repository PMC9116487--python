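"""Fixture-catalog tests: each packaged model honors its documented behavior."""

import numpy as np
import pytest

from dbst.model import PowerDomainError, RegimeSet, rhs, validate_model
from dbst.models import (AHR_RATE_CONSTANTS, LAC_THRESHOLDS, MODEL_CATALOG,
                         ahr_model, branched_pathway_template,
                         branched_pathway_truth, build_catalog_model,
                         generate_synthetic_timeseries, lac_operon,
                         limit_cycle_oscillator, linear_pathway,
                         lorenz_discrete)
from dbst.solver import SimulationError, simulate
from dbst.steady_state import gma_steady_state, ssystem_steady_state


class TestCatalog:
    @pytest.mark.parametrize("name", sorted(MODEL_CATALOG))
    def test_every_fixture_validates(self, name):
        spec = build_catalog_model(name)
        assert validate_model(spec) == spec  # builders return normalized specs

    def test_unknown_name_lists_catalog(self):
        with pytest.raises(KeyError, match="linear_pathway"):
            build_catalog_model("nope")


class TestLinearPathway:
    def test_documented_steady_state_is_a_fixed_point(self):
        res = ssystem_steady_state(linear_pathway())
        assert res.residual_norm < 1e-10

    def test_jitter_variant_tracks_deterministic_run(self):
        noisy = simulate(linear_pathway(rate_jitter=0.1), 50.0, seed=1)
        det = simulate(linear_pathway(), 50.0)
        # ±10% rate jitter perturbs but does not derail the trajectory
        dev = np.abs(noisy.value("X1") - det.value("X1"))
        assert dev.max() < 0.2 and dev.mean() < 0.1
        assert not np.array_equal(noisy.states, det.states)


class TestLimitCycleOscillator:
    def test_zero_state_is_invalid_for_fractional_powers(self):
        spec = limit_cycle_oscillator(initial=(0.0, 0.0))
        with pytest.raises((SimulationError, PowerDomainError)):
            simulate(spec, 1.0)

    def test_coarse_step_still_oscillates_with_larger_amplitude(self):
        from scipy.signal import find_peaks
        fine = simulate(limit_cycle_oscillator(theta=0.1), 1500.0)
        coarse = simulate(limit_cycle_oscillator(theta=1.0), 1500.0)
        pf, _ = find_peaks(fine.value("X1"))
        pc, _ = find_peaks(coarse.value("X1"))
        assert len(pc) >= 3
        assert coarse.value("X1")[pc[-1]] > fine.value("X1")[pf[-1]]


class TestLorenzDiscrete:
    def test_origin_is_a_fixed_point(self):
        spec = lorenz_discrete(initial=(0.0, 0.0, 0.0))
        traj = simulate(spec, 50.0)
        assert np.all(traj.states == 0.0)


class TestLacOperon:
    def test_base_steady_state_matches_printed_values(self):
        res = ssystem_steady_state(lac_operon())
        assert (res.state["X1"], res.state["X2"], res.state["X3"]) == \
            pytest.approx((0.43, 0.22, 0.46), abs=5e-3)

    def test_scheduled_run_tracks_fine_grid_reference_within_2pct(self):
        coarse = simulate(lac_operon("scheduled", theta=0.1), 360.0)
        fine = simulate(lac_operon("scheduled", theta=0.01), 360.0)
        idx = np.round(coarse.times / 0.01).astype(int)
        cols = [fine.columns.index(c) for c in coarse.columns[:3]]
        ref = fine.states[idx][:, cols]
        rel = np.abs(coarse.states[:, :3] - ref) / np.maximum(np.abs(ref), 1e-9)
        assert rel.max() < 0.02

    def test_piecewise_thresholds_preserve_rate_continuity(self):
        spec = lac_operon("piecewise")
        reg = spec.equations["X1"]
        assert isinstance(reg, RegimeSet)
        low, high = reg.low, reg.high
        # at each threshold the constant regime equals the power law
        assert reg.below.terms[0].rate_constant == pytest.approx(0.2 * low ** 2)
        assert reg.above.terms[0].rate_constant == pytest.approx(0.2 * high ** 2)
        assert spec.metadata["thresholds"] == LAC_THRESHOLDS

    def test_piecewise_variant_switches_regime_under_schedule(self):
        spec = lac_operon("piecewise")
        traj = simulate(spec, 200.0)
        x3 = traj.value("X3")
        assert (x3 > LAC_THRESHOLDS["X3_high"]).any(), \
            "schedule never drove internal lactose into the saturated regime"
        assert (x3 <= LAC_THRESHOLDS["X3_high"]).any()

    def test_renewal_variant_runs_and_logs_events(self):
        traj = simulate(lac_operon("renewal"), 360.0, seed=2)
        renewals = [e for e in traj.event_log if e["kind"] == "renewal"]
        assert renewals and all(e["value"] >= 0 for e in renewals)


class TestAhr:
    def test_ligand_free_state_is_fixed_point(self):
        spec = ahr_model("no_delay_no_noise")
        state = spec.initial_values()
        assert np.max(np.abs(rhs(spec, state))) < 1e-10

    def test_table3_constants_and_metadata(self):
        spec = ahr_model("delays_only")
        assert AHR_RATE_CONSTANTS == (1, 2, 1, 1, 1, 2, 2, 2, 10, 10, 10, 10, 6)
        assert spec.metadata["tau1"] == 3.0 and spec.metadata["tau2"] == 4.0
        assert spec.metadata["g"] == -4.0

    def test_delay_scenario_timing(self):
        traj = simulate(ahr_model("delays_only"), 25.0)
        t = traj.times
        mrna, prot = traj.value("X7"), traj.value("X9")
        # ligand on at t=2: transcription is silent until t ≈ 2+τ₁ = 5
        assert np.abs(mrna[t <= 4.9]).max() < 1e-9
        assert mrna[t <= 6.0].max() > 1e-3
        # translation lags a further τ₂ = 4: proteins emerge near t = 9
        assert np.abs(prot[t <= 8.9]).max() < 1e-9
        assert prot[t <= 10.5].max() > 1e-3

    def test_mrna_trajectories_are_identical(self):
        traj = simulate(ahr_model("delays_only"), 30.0)
        assert np.array_equal(traj.value("X7"), traj.value("X8"))

    def test_delays_unleash_target_protein_expression(self):
        peak_a = simulate(ahr_model("no_delay_no_noise"), 40.0).value("X9").max()
        peak_b = simulate(ahr_model("delays_only"), 40.0).value("X9").max()
        assert peak_a < 0.25 * peak_b

    def test_system_returns_to_rest_after_ligand_removal(self):
        traj = simulate(ahr_model("delays_only"), 80.0)
        final = traj.final_state()
        assert final["X1"] == pytest.approx(10.0, abs=1e-2)
        assert final["X3"] == pytest.approx(10.0, abs=5e-2)
        assert final["X9"] < 1e-2

    def test_noise_scenario_perturbs_but_preserves_shape(self):
        det = simulate(ahr_model("delays_only"), 30.0)
        noisy = simulate(ahr_model("delays_and_noise"), 30.0, seed=7)
        assert not np.array_equal(det.value("X9"), noisy.value("X9"))
        # same order of magnitude and same delayed onset
        assert noisy.value("X9")[noisy.times <= 8.5].max() < 1e-6
        assert 0.5 * det.value("X9").max() < noisy.value("X9").max() \
            < 2.0 * det.value("X9").max()

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="scenario"):
            ahr_model("delays_maybe")


class TestSyntheticData:
    def test_dense_grid_has_61_rows(self):
        spec = branched_pathway_truth()
        s = generate_synthetic_timeseries(spec, np.arange(0.0, 61.0, 1.0),
                                          generator="fine_grid_reference")
        assert s.values.shape == (61, 4) and s.n_data == 4 * 61

    def test_sparse_grid_has_21_rows(self):
        spec = branched_pathway_truth()
        s = generate_synthetic_timeseries(spec, np.arange(0.0, 61.0, 3.0),
                                          generator="fine_grid_reference")
        assert s.values.shape == (21, 4) and s.n_data == 4 * 21

    def test_initial_state_is_recorded_in_metadata(self):
        spec = branched_pathway_truth()
        s = generate_synthetic_timeseries(spec, np.arange(0.0, 11.0, 1.0))
        assert s.metadata["initial_state"] == {f"X{i}": 1.0 for i in range(1, 5)}

    def test_noise_is_seed_reproducible_and_positive(self):
        spec = branched_pathway_truth()
        grid = np.arange(0.0, 31.0, 1.0)
        a = generate_synthetic_timeseries(spec, grid, noise_fraction=0.1, seed=3)
        b = generate_synthetic_timeseries(spec, grid, noise_fraction=0.1, seed=3)
        c = generate_synthetic_timeseries(spec, grid, noise_fraction=0.1, seed=4)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)
        assert (a.values > 0).all()

    def test_off_grid_times_rejected_for_recursion_generator(self):
        spec = branched_pathway_truth()  # ϑ = 1
        with pytest.raises(ValueError, match="grid"):
            generate_synthetic_timeseries(spec, [0.0, 0.25, 0.5])

    def test_optional_terms_extend_the_template(self):
        from dbst.models import BRANCHED_TRUTH
        params = dict(BRANCHED_TRUTH, d1=0.1, X0=1.0)
        spec = branched_pathway_template(params, include_x0=True, include_d1=True)
        spec = validate_model(spec)
        assert "X0" in spec.independent_names
        assert len(spec.equations["X1"]) == 4
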