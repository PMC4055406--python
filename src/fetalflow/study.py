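"""Parametric resistance sweeps over the calibrated control model.

To emulate the two remodeling processes of growth restriction, the combined
lower-body-and-placenta (peripheral) resistance is multiplied by factors up
to 4 (placental insufficiency and peripheral vasoconstriction) and the two
brain bed resistances are divided by factors up to 4 (cerebral
vasodilation), with every other parameter — including the inflow waveforms
— held fixed.  Each grid cell records the full index panel (PI_AoI, IFI,
% reversal, PI_CA, PI_dAo, PI_dAo/PI_CA and CCO fractions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .indices import IndexReport, compute_index_report
from .inflow import FlowWaveform
from .network import NetworkModel, assemble_state_space
from .simulate import ConvergenceError, run_to_periodic

DEFAULT_GRID_SIZE = 13


def default_factors(n: int = DEFAULT_GRID_SIZE) -> np.ndarray:
    """Log-spaced factors in [1, 4]."""
    return np.geomspace(1.0, 4.0, n)


@dataclass(frozen=True)
class SweepGrid:
    """Per-cell index panels over (peripheral factor, brain divisor)."""

    peripheral_factors: tuple[float, ...]
    brain_divisors: tuple[float, ...]
    reports: dict[tuple[int, int], IndexReport | None]

    @property
    def baseline(self) -> IndexReport:
        report = self.reports[(0, 0)]
        if report is None:
            raise RuntimeError("baseline cell did not converge")
        return report

    def failed_cells(self) -> list[tuple[int, int]]:
        return [k for k, v in self.reports.items() if v is None]


def resistance_sweep(
    control_model: NetworkModel,
    inflows: tuple[FlowWaveform, FlowWaveform],
    systole: tuple[float, float],
    peripheral_factors=None,
    brain_divisors=None,
    tolerance: float = 1e-4,
    max_cycles: int = 50,
) -> SweepGrid:
    """Simulate every (f_per, f_brain) combination of the factor grid.

    Factors must be ≥ 1 and include 1 as the first entry so the (1, 1)
    baseline cell reproduces the calibrated control.  Non-convergent cells
    are recorded as ``None`` rather than aborting the sweep.
    """
    peripheral_factors = np.atleast_1d(
        default_factors() if peripheral_factors is None else np.asarray(peripheral_factors, float)
    )
    brain_divisors = np.atleast_1d(
        default_factors() if brain_divisors is None else np.asarray(brain_divisors, float)
    )
    for name, arr in (("peripheral_factors", peripheral_factors), ("brain_divisors", brain_divisors)):
        if np.any(arr < 1.0):
            raise ValueError(f"{name} must be ≥ 1")

    reports: dict[tuple[int, int], IndexReport | None] = {}
    for i, f_per in enumerate(peripheral_factors):
        for j, f_brain in enumerate(brain_divisors):
            model = control_model.with_scaled_rp(
                {"peripheral": float(f_per), "brain": 1.0 / float(f_brain)}
            )
            try:
                result = run_to_periodic(
                    assemble_state_space(model), inflows, tolerance, max_cycles
                )
                reports[(i, j)] = compute_index_report(result, systole, model)
            except ConvergenceError:
                reports[(i, j)] = None
    return SweepGrid(
        peripheral_factors=tuple(float(f) for f in peripheral_factors),
        brain_divisors=tuple(float(f) for f in brain_divisors),
        reports=reports,
    )


_SCALAR_INDICES = (
    "pi_aoi",
    "pi_ca",
    "pi_dao",
    "pi_ratio_dao_ca",
    "ifi",
    "percent_reversed_aoi",
    "mbp",
)


def summarize_sweep(grid: SweepGrid) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Long-format table plus the two single-factor marginal slices.

    Returns ``(table, marginals)`` where the table has columns
    ``(f_per, f_brain, index, value)`` and ``marginals`` holds the
    ``peripheral_only`` (brain divisor 1) and ``brain_only`` (peripheral
    factor 1) slices.
    """
    rows = []
    for (i, j), report in grid.reports.items():
        f_per = grid.peripheral_factors[i]
        f_brain = grid.brain_divisors[j]
        if report is None:
            rows.append((f_per, f_brain, "converged", 0.0))
            continue
        for name in _SCALAR_INDICES:
            rows.append((f_per, f_brain, name, getattr(report, name)))
        for group, frac in report.cco_fraction.items():
            rows.append((f_per, f_brain, f"cco_{group}", frac))
    table = pd.DataFrame(rows, columns=["f_per", "f_brain", "index", "value"])
    marginals = {
        "peripheral_only": table[table["f_brain"] == 1.0].reset_index(drop=True),
        "brain_only": table[table["f_per"] == 1.0].reset_index(drop=True),
    }
    return table, marginals
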