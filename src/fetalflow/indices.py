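"""Doppler-derived hemodynamic indices computed from model waveforms.

* Pulsatility index, PI = (systolic − diastolic) / time-averaged value; on
  model flow waveforms the cycle max/min stand in for the systolic/diastolic
  velocities of a Doppler envelope.  PI is invariant to amplitude scaling,
  so it is identical on a flow trace and on the corresponding velocity
  envelope (the valve area cancels).
* Isthmic flow index, IFI = (systolic + diastolic) / systolic velocity-time
  integrals, with the diastolic integral signed (negative under reversal).
* Percentage of reversed flow; by default referenced to total absolute flow
  ``|backward| / (|backward| + forward)``, configurably to the forward
  integral alone.
* Mean arterial blood pressure (cycle average at the ascending-aorta node).
* Distribution of combined cardiac output (CCO) over the five bed groups.

The systole/diastole demarcation is the imposed ejection window of the
aortic inflow source, as the model has no valve events of its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .inflow import Waveform
from .network import NetworkModel
from .simulate import SimulationResult

#: bed groups reported as fractions of combined cardiac output
CCO_GROUPS = ("brain", "upper_body", "lungs", "lower_body_placenta", "coronary")

_GROUP_BEDS = {
    "brain": ("left_brain", "right_brain"),
    "upper_body": ("left_upper", "right_upper"),
    "lungs": ("left_lung", "right_lung"),
    "lower_body_placenta": ("peripheral",),
    "coronary": ("coronary",),
}


class UndefinedIndexError(ValueError):
    """Raised when an index is undefined for the given waveform."""


def pulsatility_index(w: Waveform) -> float:
    """PI = (max − min) / |time-average| over one cycle.

    The magnitude of the time-averaged value is used in the denominator so
    the index stays positive even when diastolic reversal makes the net flow
    negative, matching how the clinical index is reported for severely
    abnormal isthmus traces.
    """
    mean = w.mean()
    span = float(np.max(w.values) - np.min(w.values))
    if mean == 0.0 and span == 0.0:
        return 0.0
    if abs(mean) < 1e-12 * max(span, 1.0):
        raise UndefinedIndexError("time-averaged value is zero; PI undefined")
    return span / abs(mean)


def _split_systole(w: Waveform, systole: tuple[float, float]):
    t0, t1 = systole
    if not (0.0 <= t0 < t1 <= w.period + 1e-12):
        raise ValueError(f"systole {systole} must lie within the cycle [0, {w.period}]")
    mask = (w.time >= t0) & (w.time < t1)
    return mask


def isthmus_flow_index(w: Waveform, systole: tuple[float, float]) -> float:
    """IFI = (systolic + diastolic) / systolic integrals, diastole signed."""
    mask = _split_systole(w, systole)
    sys_int = float(np.sum(w.values[mask]) * w.dt)
    dia_int = float(np.sum(w.values[~mask]) * w.dt)
    if sys_int <= 0:
        raise UndefinedIndexError("systolic integral must be positive for IFI")
    return (sys_int + dia_int) / sys_int


def percent_reversed(w: Waveform, convention: str = "total") -> float:
    """Percentage of reversed (negative) flow over the cycle.

    ``"total"``: 100·|backward| / (|backward| + forward);
    ``"forward"``: 100·|backward| / forward.
    """
    fwd = float(np.sum(np.clip(w.values, 0.0, None)) * w.dt)
    bwd = float(-np.sum(np.clip(w.values, None, 0.0)) * w.dt)
    if fwd + bwd == 0.0:
        raise UndefinedIndexError("identically zero waveform")
    if convention == "total":
        return 100.0 * bwd / (bwd + fwd)
    if convention == "forward":
        if fwd == 0.0:
            raise UndefinedIndexError("no forward flow; forward-referenced reversal undefined")
        return 100.0 * bwd / fwd
    raise ValueError(f"unknown reversal convention {convention!r}")


def mean_pressure(p: Waveform) -> float:
    """Cycle-averaged pressure (mmHg in the reporting convention)."""
    return p.mean()


def target_mbp(gestational_age: float) -> float:
    """Gestational-age-appropriate mean arterial pressure, 0.87·GA + 10.33 mmHg."""
    return 0.87 * gestational_age + 10.33


def cco_distribution(
    result: SimulationResult, network: NetworkModel | None = None
) -> dict[str, float]:
    """Mean bed inflows grouped and expressed as % of combined cardiac output.

    Also reports the left/right ventricular output split.  Only cycle-mean
    flows enter, so for fixed resistances the result matches the purely
    resistive (DC) solution regardless of waveform shape.
    """
    mean_left = float(np.mean(result.flows["aortic_valve"]))
    mean_right = float(np.mean(result.flows["pulmonary_valve"]))
    cco = mean_left + mean_right
    if cco <= 0:
        raise UndefinedIndexError("combined cardiac output is not positive")
    out = {}
    for group, beds in _GROUP_BEDS.items():
        q = sum(float(np.mean(result.flows[f"bed:{b}"])) for b in beds)
        out[group] = 100.0 * q / cco
    out["left_output"] = 100.0 * mean_left / cco
    out["right_output"] = 100.0 * mean_right / cco
    return out


@dataclass(frozen=True)
class IndexReport:
    """The model-based index panel for one simulation."""

    pi_aoi: float
    pi_ca: float
    pi_dao: float
    pi_ratio_dao_ca: float
    ifi: float
    percent_reversed_aoi: float
    mbp: float
    cco_fraction: dict[str, float] = field(default_factory=dict)
    reversal_convention: str = "total"
    systole_definition: str = "aortic ejection window"

    def to_dict(self) -> dict:
        return asdict(self)


def compute_index_report(
    result: SimulationResult,
    systole: tuple[float, float],
    network: NetworkModel | None = None,
    reversal_convention: str = "total",
) -> IndexReport:
    """Assemble the full panel from a converged simulation."""
    w_aoi = result.probe("aortic_isthmus")
    w_ca = result.probe("cerebral_arteries")
    w_dao = result.probe("descending_aorta")
    p_central = result.probe("arch")

    def guarded(fn, *args):
        # extreme parameter combinations can make single indices undefined
        # (e.g. fully reversed systolic isthmus flow); report NaN per-field
        # instead of failing the whole panel
        try:
            return fn(*args)
        except UndefinedIndexError:
            return float("nan")

    pi_aoi = guarded(pulsatility_index, w_aoi)
    pi_ca = guarded(pulsatility_index, w_ca)
    pi_dao = guarded(pulsatility_index, w_dao)
    cco = cco_distribution(result, network)
    return IndexReport(
        pi_aoi=pi_aoi,
        pi_ca=pi_ca,
        pi_dao=pi_dao,
        pi_ratio_dao_ca=pi_dao / pi_ca,
        ifi=guarded(isthmus_flow_index, w_aoi, systole),
        percent_reversed_aoi=guarded(percent_reversed, w_aoi, reversal_convention),
        mbp=mean_pressure(p_central),
        cco_fraction=cco,
        reversal_convention=reversal_convention,
    )
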