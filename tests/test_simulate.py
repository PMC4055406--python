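"""Transient integration to periodic steady state and probe bookkeeping."""

import numpy as np
import pytest

from fetalflow.indices import pulsatility_index
from fetalflow.inflow import FlowWaveform
from fetalflow.network import assemble_state_space, dc_operating_point
from fetalflow.simulate import ConvergenceError, probe, run_to_periodic


def constant_inflow(value, period=0.5, n=500):
    t = np.arange(n) * period / n
    return FlowWaveform(time=t, values=np.full(n, float(value)), period=period)


class TestPeriodicConvergence:
    def test_constant_inflows_match_dc_oracle(self, control_model):
        """With constant sources the periodic state is the resistive solution."""
        system = assemble_state_space(control_model)
        result = run_to_periodic(system, (constant_inflow(5.7), constant_inflow(6.7)))
        dc = dc_operating_point(control_model, {"aortic": 5.7, "pulmonary": 6.7})
        for bed, q_dc in dc["bed_flows"].items():
            q_sim = np.mean(result.flows[f"bed:{bed}"])
            assert q_sim == pytest.approx(q_dc, rel=5e-3)

    def test_zero_inflows_stay_zero(self, control_model):
        system = assemble_state_space(control_model)
        result = run_to_periodic(system, (constant_inflow(0.0), constant_inflow(0.0)))
        for w in result.flows.values():
            assert np.allclose(w, 0.0)
        for p in result.pressures.values():
            assert np.allclose(p, 0.0)

    def test_mass_conservation_at_periodicity(self, control_result):
        """Mean combined inflow equals the sum of mean bed outflows (0.1%)."""
        inflow = np.mean(control_result.flows["aortic_valve"]) + np.mean(
            control_result.flows["pulmonary_valve"]
        )
        outflow = sum(
            np.mean(w) for site, w in control_result.flows.items() if site.startswith("bed:")
        )
        assert outflow == pytest.approx(inflow, rel=1e-3)

    def test_junction_conservation(self, control_result):
        """Mean isthmus + ductus flow equals mean descending-aorta flow."""
        lhs = np.mean(control_result.flows["aortic_isthmus"]) + np.mean(
            control_result.flows["ductus_arteriosus"]
        )
        rhs = np.mean(control_result.flows["descending_aorta"])
        assert lhs == pytest.approx(rhs, rel=1e-3)

    def test_convergence_metric_below_tolerance(self, control_result):
        assert control_result.convergence_metric < 1e-4
        assert control_result.cycles_run <= 50

    def test_non_convergence_raises_with_metric(self, control_model, control_inflows):
        system = assemble_state_space(control_model)
        with pytest.raises(ConvergenceError) as err:
            run_to_periodic(system, control_inflows, tolerance=1e-12, max_cycles=2)
        assert err.value.metric > 0

    def test_invalid_tolerance(self, control_model, control_inflows):
        system = assemble_state_space(control_model)
        with pytest.raises(ValueError):
            run_to_periodic(system, control_inflows, tolerance=-1.0)

    def test_mismatched_periods_rejected(self, control_model):
        system = assemble_state_space(control_model)
        with pytest.raises(ValueError):
            run_to_periodic(system, (constant_inflow(5, period=0.5), constant_inflow(6, period=0.6)))


class TestLinearity:
    def test_scaling_inflows_scales_all_outputs(self, control_model, control_inflows):
        system = assemble_state_space(control_model)
        qao, qpv = control_inflows
        r1 = run_to_periodic(system, (qao, qpv))
        r2 = run_to_periodic(system, (qao.scaled(2.0), qpv.scaled(2.0)))
        for site in ("aortic_isthmus", "descending_aorta", "bed:left_brain"):
            np.testing.assert_allclose(r2.flows[site], 2 * r1.flows[site], rtol=1e-6, atol=1e-9)
        np.testing.assert_allclose(
            r2.pressures["arch"], 2 * r1.pressures["arch"], rtol=1e-6
        )


class TestGridIndependence:
    def test_halving_step_changes_indices_below_half_percent(
        self, control_model, control_record
    ):
        from fetalflow.inflow import synthesize_inflow_pair

        system = assemble_state_space(control_model)
        results = {}
        for n in (1000, 2000):
            inflows = synthesize_inflow_pair(
                control_record.heart_rate,
                control_record.aortic_peak_velocity,
                control_record.pulmonary_peak_velocity,
                control_record.aortic_valve_diameter,
                control_record.pulmonary_valve_diameter,
                samples_per_cycle=n,
                left_output_fraction=0.46,
            )
            r = run_to_periodic(system, inflows)
            results[n] = {
                "pi_aoi": pulsatility_index(r.probe("aortic_isthmus")),
                "pi_ca": pulsatility_index(r.probe("cerebral_arteries")),
                "mbp": float(np.mean(r.pressures["arch"])),
            }
        for key in results[1000]:
            rel = abs(results[2000][key] - results[1000][key]) / abs(results[1000][key])
            assert rel < 5e-3, key


class TestProbes:
    def test_valve_flow_equals_imposed_inflow(self, control_result, control_inflows):
        np.testing.assert_allclose(
            control_result.flows["aortic_valve"], control_inflows[0].values
        )

    def test_unknown_site(self, control_result):
        with pytest.raises(KeyError):
            probe(control_result, "umbilical_vein")

    def test_probe_returns_waveform_on_final_cycle_grid(self, control_result):
        w = probe(control_result, "aortic_isthmus")
        assert w.n_samples == control_result.time.size
        assert w.period == pytest.approx(control_result.period)

    def test_cerebral_sites(self, control_result):
        np.testing.assert_allclose(
            control_result.flows["cerebral_arteries"],
            control_result.flows["cerebral_left"] + control_result.flows["cerebral_right"],
        )

    def test_quartered_brain_resistance_reverses_isthmus_diastole(
        self, mbp_calibrated, control_inflows
    ):
        """Brain vasodilation drives late-systolic/diastolic isthmus reversal."""
        model, _ = mbp_calibrated
        vasodilated = model.with_scaled_rp({"brain": 0.25})
        r = run_to_periodic(assemble_state_space(vasodilated), control_inflows)
        w = r.probe("aortic_isthmus")
        assert w.values.min() < 0

    def test_tidy_export_shape(self, control_result):
        from fetalflow.simulate import to_tidy_frame

        df = to_tidy_frame(control_result)
        assert set(df.columns) == {"site", "kind", "time_s", "value"}
        n_sites = len(control_result.flows) + len(control_result.pressures)
        assert len(df) == n_sites * control_result.time.size
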