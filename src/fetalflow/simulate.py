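"""Periodic-steady-state simulation of the circuit and named probe waveforms.

The circuit is linear time-invariant for fixed parameters, so the transient
is advanced with an exact exponential (first-order-hold) discretization of
``dx/dt = A x + B u`` at the output sampling rate: stiff-safe by
construction, with no step-size restriction from the smallest compliances.
Integration starts from a zero state and proceeds cycle by cycle; the run is
converged when the maximum relative change of cycle-averaged pressure states
between consecutive cycles drops below the tolerance.  Cycle-to-cycle
propagation uses the precomputed one-cycle transition operator, so the cost
is dominated by two rollouts of the sampled grid regardless of how many
cycles convergence takes.

Flow sign convention: positive along each segment's proximal → distal
orientation (isthmus: positive toward the descending aorta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from . import units
from .inflow import FlowWaveform, PressureWaveform, Waveform
from .network import ODESystem

DEFAULT_TOLERANCE = 1e-4
DEFAULT_MAX_CYCLES = 50


class ConvergenceError(RuntimeError):
    """Periodic steady state not reached within the cycle budget."""

    def __init__(self, metric: float, max_cycles: int):
        self.metric = metric
        self.max_cycles = max_cycles
        super().__init__(
            f"no periodic convergence after {max_cycles} cycles (metric {metric:.3e})"
        )


@dataclass(frozen=True)
class SimulationResult:
    """Final-cycle waveforms at the named probe sites.

    ``flows`` are in ml·s⁻¹, ``pressures`` in mmHg, all sharing one uniform
    time grid over exactly the final cycle.
    """

    time: np.ndarray
    period: float
    flows: dict[str, np.ndarray]
    pressures: dict[str, np.ndarray]
    cycles_run: int
    convergence_metric: float

    def probe(self, site_id: str) -> Waveform:
        return probe(self, site_id)

    def sites(self) -> dict[str, tuple[str, ...]]:
        return {
            "flow": tuple(self.flows),
            "pressure": tuple(self.pressures),
        }


def _periodic_gradient(y: np.ndarray, dt: float) -> np.ndarray:
    """Central differences with periodic wrap."""
    return (np.roll(y, -1) - np.roll(y, 1)) / (2.0 * dt)


def run_to_periodic(
    system: ODESystem,
    inflows: tuple[FlowWaveform, FlowWaveform],
    tolerance: float = DEFAULT_TOLERANCE,
    max_cycles: int = DEFAULT_MAX_CYCLES,
) -> SimulationResult:
    """Integrate from a zero state until the pressure field is cycle-periodic.

    ``inflows`` is the (aortic, pulmonary) pair sharing one period.  Raises
    :class:`ConvergenceError` if ``max_cycles`` is exceeded.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    q_ao, q_pv = inflows
    if not np.isclose(q_ao.period, q_pv.period, rtol=1e-9):
        raise ValueError("both inflows must share the system period")
    period = q_ao.period
    n_samples = max(q_ao.n_samples, q_pv.n_samples)
    if q_ao.n_samples != n_samples:
        q_ao = q_ao.resample(n_samples)
    if q_pv.n_samples != n_samples:
        q_pv = q_pv.resample(n_samples)
    dt = period / n_samples
    u = np.stack([q_ao.values, q_pv.values])  # (2, N)

    n = system.n_states
    Ad, B0, B1 = _foh_discretize(system.A, system.B, dt)
    # precomputed forcing per step for the piecewise-linear (periodic) input
    bu = B0 @ u + B1 @ np.roll(u, -1, axis=1)  # (n, N)

    # zero-state response over one cycle: x_{k+1} = Ad x_k + bu[k]
    zero_state = np.zeros(n)
    traj = _rollout(Ad, bu, zero_state)
    c = traj[:, -1]  # state after one cycle from rest
    forced_mean = traj[:, :-1].mean(axis=1)

    # one-cycle transition operator and within-cycle averaging operator
    M = np.linalg.matrix_power(Ad, n_samples)
    S = np.linalg.solve(np.eye(n) - Ad, np.eye(n) - M) / n_samples

    p_rows = slice(len(system.flow_index), n)
    scale = max(np.max(np.abs(forced_mean[p_rows])), 1e-12)

    x0 = zero_state
    prev_mean = S @ x0 + forced_mean
    metric = np.inf
    cycles = 0
    for cycles in range(1, max_cycles + 1):
        x0 = M @ x0 + c
        mean = S @ x0 + forced_mean
        metric = float(
            np.max(np.abs(mean[p_rows] - prev_mean[p_rows]))
            / max(np.max(np.abs(prev_mean[p_rows])), scale)
        )
        prev_mean = mean
        if metric < tolerance:
            break
    else:
        raise ConvergenceError(metric, max_cycles)

    final = _rollout(Ad, bu, x0)[:, :-1]  # (n, N) over the final cycle
    return _collect_outputs(system, final, u, dt, period, cycles, metric)


def _foh_discretize(A: np.ndarray, B: np.ndarray, dt: float):
    """Exact discretization for piecewise-linear input.

    Returns (Ad, B0, B1) such that ``x_{k+1} = Ad x_k + B0 u_k + B1 u_{k+1}``
    reproduces the continuous response exactly when u is linearly
    interpolated between samples.  Uses closed forms
    ``P = A^{-1}(Ad - I)B`` and ``Q = (A^{-1} dt Ad - A^{-2}(Ad - I))B``
    (A is invertible: every state leaks to ground through a resistor).
    """
    Ad = expm(A * dt)
    n = A.shape[0]
    AinvE = np.linalg.solve(A, Ad - np.eye(n))
    P = AinvE @ B
    Q = (dt * np.linalg.solve(A, Ad) - np.linalg.solve(A, AinvE)) @ B
    B0 = Q / dt
    B1 = P - Q / dt
    return Ad, B0, B1


def _rollout(Ad: np.ndarray, bu: np.ndarray, x0: np.ndarray) -> np.ndarray:
    """Advance N steps with per-step forcing ``bu``; returns states at k = 0..N."""
    n, N = Ad.shape[0], bu.shape[1]
    out = np.empty((n, N + 1))
    out[:, 0] = x0
    x = x0
    for k in range(N):
        x = Ad @ x + bu[:, k]
        out[:, k + 1] = x
    return out


def _collect_outputs(
    system: ODESystem,
    x: np.ndarray,
    u: np.ndarray,
    dt: float,
    period: float,
    cycles: int,
    metric: float,
) -> SimulationResult:
    net = system.network
    time = np.arange(x.shape[1]) * dt

    flows: dict[str, np.ndarray] = {}
    pressures: dict[str, np.ndarray] = {}

    for vessel, iq in system.flow_index.items():
        flows[vessel] = x[iq]
    for src, info in system.source_info.items():
        q = u[info["input"]]
        flows[info["vessel"]] = q
        flows[f"{src}_valve"] = q
        # valve-node pressure: entry-node pressure plus the R–L drop
        p_entry = x[system.node_index[info["entry"]]]
        dqdt = _periodic_gradient(q, dt)
        pressures[info["root"]] = p_entry + info["R"] * q + info["L"] * dqdt

    for node, ip in system.node_index.items():
        pressures[node] = x[ip]
    for bed_id, ib in system.bed_index.items():
        pressures[f"bed:{bed_id}"] = x[ib]

    for bed_id, bed in net.beds.items():
        p_node = x[system.node_index[net.bed_nodes[bed_id]]]
        if bed.is_coronary:
            flows[f"bed:{bed_id}"] = p_node / bed.peripheral_resistance
        else:
            p_bed = x[system.bed_index[bed_id]]
            flows[f"bed:{bed_id}"] = (p_node - p_bed) / bed.characteristic_resistance

    flows["cerebral_left"] = flows["left_internal_carotid_artery"]
    flows["cerebral_right"] = flows["right_internal_carotid_artery"]
    flows["cerebral_arteries"] = flows["cerebral_left"] + flows["cerebral_right"]

    pressures = {k: v / units.MMHG for k, v in pressures.items()}
    return SimulationResult(
        time=time,
        period=period,
        flows=flows,
        pressures=pressures,
        cycles_run=cycles,
        convergence_metric=metric,
    )


def probe(result: SimulationResult, site_id: str) -> Waveform:
    """Final-cycle waveform at a named site (flow unless a pressure node)."""
    if site_id in result.flows:
        return FlowWaveform(
            time=result.time, values=result.flows[site_id], period=result.period
        )
    if site_id in result.pressures:
        return PressureWaveform(
            time=result.time, values=result.pressures[site_id], period=result.period
        )
    known = sorted(result.flows) + sorted(f"pressure {p}" for p in result.pressures)
    raise KeyError(f"unknown probe site {site_id!r}; known sites: {known}")


def to_tidy_frame(result: SimulationResult):
    """Long-format DataFrame (site, kind, time_s, value) for export."""
    import pandas as pd

    frames = []
    for kind, table in (("flow_ml_s", result.flows), ("pressure_mmhg", result.pressures)):
        for site, values in table.items():
            frames.append(
                pd.DataFrame(
                    {"site": site, "kind": kind, "time_s": result.time, "value": values}
                )
            )
    return pd.concat(frames, ignore_index=True)
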