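"""Shared fixtures: the control circuit, its inflows and simulations.

Session-scoped fixtures cache the expensive objects (calibrated model,
steady-state simulations) so the suite stays fast.
"""

import numpy as np
import pytest

from fetalflow.fit import calibrate_control, calibrate_mbp, load_patient_records
from fetalflow.inflow import ejection_time, synthesize_inflow_pair
from fetalflow.network import assemble_state_space, build_control_network
from fetalflow.simulate import run_to_periodic

CONTROL_GA = 33.2


@pytest.fixture(scope="session")
def control_record():
    return load_patient_records()["control"]


@pytest.fixture(scope="session")
def control_model():
    """GA 33.2 network with the built-in control bed parameters."""
    return build_control_network(CONTROL_GA)


@pytest.fixture(scope="session")
def control_inflows(control_record):
    """Synthetic half-sine pair with the 46/54 left/right output split."""
    return synthesize_inflow_pair(
        heart_rate=control_record.heart_rate,
        aortic_peak_velocity=control_record.aortic_peak_velocity,
        pulmonary_peak_velocity=control_record.pulmonary_peak_velocity,
        aortic_valve_diameter_mm=control_record.aortic_valve_diameter,
        pulmonary_valve_diameter_mm=control_record.pulmonary_valve_diameter,
        left_output_fraction=0.46,
    )


@pytest.fixture(scope="session")
def control_systole(control_record):
    return (0.0, ejection_time(control_record.heart_rate))


@pytest.fixture(scope="session")
def control_result(control_model, control_inflows):
    return run_to_periodic(assemble_state_space(control_model), control_inflows)


@pytest.fixture(scope="session")
def mbp_calibrated(control_model, control_inflows):
    model, factor = calibrate_mbp(control_model, control_inflows, CONTROL_GA)
    return model, factor


@pytest.fixture(scope="session")
def calibrated_control():
    """Fully calibrated control: MBP targeting plus compliance estimation."""
    model, inflows, systole, factor, fit = calibrate_control(seed=0, n_starts=4)
    return {
        "model": model,
        "inflows": inflows,
        "systole": systole,
        "factor": factor,
        "fit": fit,
    }


@pytest.fixture(scope="session")
def calibrated_result(calibrated_control):
    return run_to_periodic(
        assemble_state_space(calibrated_control["model"]),
        calibrated_control["inflows"],
    )
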