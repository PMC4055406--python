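"""Inflow boundary conditions: synthetic ejection waveforms and velocity traces.

The two flow sources of the circuit are the aortic- and pulmonary-valve
volumetric inflows.  When traced Doppler envelopes are available they are
read from two-column text files; otherwise a synthetic ventricular-outflow
envelope is generated as a single half-sine ejection pulse with zero
diastolic flow:

    V(t) = Vpeak * sin(pi * t / ET)   for 0 <= t <= ET,   0 elsewhere,

with ET the ejection time expressed as a fraction of the cardiac period
(default 0.40).  The velocity-time integral of the pulse is
``(2/pi) * Vpeak * ET``.  Velocity is converted to flow through the valve
cross-section, ``Q = V * pi * r**2``.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

DEFAULT_EJECTION_FRACTION = 0.40
DEFAULT_SAMPLES_PER_CYCLE = 1000


@dataclass(frozen=True)
class Waveform:
    """One cardiac cycle of a uniformly sampled periodic signal.

    ``time`` holds ``n`` samples on ``[0, period)``; the sample at ``period``
    wraps back to the first value.
    """

    time: np.ndarray
    values: np.ndarray
    period: float

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("time and values must be 1-D arrays of equal length")
        if self.period <= 0:
            raise ValueError("period must be positive")
        dt = np.diff(t)
        if t.size >= 2 and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("samples must be uniform")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "values", v)

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        return self.period / self.n_samples

    def mean(self) -> float:
        return float(np.mean(self.values))

    def integral(self) -> float:
        """Integral over one full period (left-rectangle rule on the uniform grid)."""
        return float(np.sum(self.values) * self.dt)

    def resample(self, n_samples: int) -> "Waveform":
        t_new = np.arange(n_samples) * self.period / n_samples
        wrapped_t = np.concatenate([self.time, [self.period]])
        wrapped_v = np.concatenate([self.values, [self.values[0]]])
        return replace(self, time=t_new, values=np.interp(t_new, wrapped_t, wrapped_v))

    def scaled(self, factor: float) -> "Waveform":
        return replace(self, values=self.values * factor)


class VelocityWaveform(Waveform):
    """Velocity envelope in cm·s⁻¹."""

    @property
    def velocity(self) -> np.ndarray:
        return self.values


class FlowWaveform(Waveform):
    """Volumetric flow in ml·s⁻¹."""

    @property
    def flow(self) -> np.ndarray:
        return self.values


class PressureWaveform(Waveform):
    """Pressure in mmHg."""

    @property
    def pressure(self) -> np.ndarray:
        return self.values


def synthesize_ejection_waveform(
    heart_rate: float,
    peak_velocity: float,
    ejection_fraction_of_cycle: float = DEFAULT_EJECTION_FRACTION,
    samples_per_cycle: int = DEFAULT_SAMPLES_PER_CYCLE,
) -> VelocityWaveform:
    """Half-sine systolic ejection pulse with zero diastolic flow."""
    if heart_rate <= 0:
        raise ValueError("heart rate must be positive")
    if not 0.0 < ejection_fraction_of_cycle < 1.0:
        raise ValueError("ejection fraction must lie in (0, 1)")
    if peak_velocity < 0:
        raise ValueError("peak velocity must be non-negative")
    period = 60.0 / heart_rate
    et = ejection_fraction_of_cycle * period
    t = np.arange(samples_per_cycle) * period / samples_per_cycle
    v = np.where(t <= et, peak_velocity * np.sin(math.pi * np.minimum(t, et) / et), 0.0)
    v = np.clip(v, 0.0, None)
    return VelocityWaveform(time=t, values=v, period=period)


def ejection_time(heart_rate: float, ejection_fraction_of_cycle: float = DEFAULT_EJECTION_FRACTION) -> float:
    """Duration of the systolic ejection window in seconds."""
    return ejection_fraction_of_cycle * 60.0 / heart_rate


def velocity_to_flow(v: VelocityWaveform, valve_diameter_mm: float) -> FlowWaveform:
    """Pointwise ``Q(t) = V(t) * pi * r**2`` with the valve radius in cm."""
    if valve_diameter_mm <= 0:
        raise ValueError("valve diameter must be positive")
    r_cm = valve_diameter_mm / 20.0
    return FlowWaveform(
        time=v.time, values=v.values * math.pi * r_cm**2, period=v.period
    )


def synthesize_inflow_pair(
    heart_rate: float,
    aortic_peak_velocity: float,
    pulmonary_peak_velocity: float,
    aortic_valve_diameter_mm: float,
    pulmonary_valve_diameter_mm: float,
    ejection_fraction_of_cycle: float = DEFAULT_EJECTION_FRACTION,
    samples_per_cycle: int = DEFAULT_SAMPLES_PER_CYCLE,
    left_output_fraction: float | None = None,
) -> tuple[FlowWaveform, FlowWaveform]:
    """Build the (aortic, pulmonary) inflow pair from clinical scalars.

    When ``left_output_fraction`` is given (e.g. 0.46 for a 46/54 left/right
    split), the two stroke volumes are rescaled — preserving the combined
    output — so the split is met exactly.  This compensates for the pulse
    shapes of the real traced envelopes, whose ejection morphologies (and
    hence stroke-volume split) are not recoverable from peak velocities
    alone.
    """
    vao = synthesize_ejection_waveform(
        heart_rate, aortic_peak_velocity, ejection_fraction_of_cycle, samples_per_cycle
    )
    vpv = synthesize_ejection_waveform(
        heart_rate, pulmonary_peak_velocity, ejection_fraction_of_cycle, samples_per_cycle
    )
    qao = velocity_to_flow(vao, aortic_valve_diameter_mm)
    qpv = velocity_to_flow(vpv, pulmonary_valve_diameter_mm)
    if left_output_fraction is not None:
        if not 0.0 < left_output_fraction < 1.0:
            raise ValueError("left output fraction must lie in (0, 1)")
        sv_l, sv_r = qao.integral(), qpv.integral()
        total = sv_l + sv_r
        qao = qao.scaled(left_output_fraction * total / sv_l)
        qpv = qpv.scaled((1.0 - left_output_fraction) * total / sv_r)
    return qao, qpv


# ---------------------------------------------------------------------------
# velocity-trace files
# ---------------------------------------------------------------------------

_HEADER = "time_s,velocity_cm_s"


def write_velocity_trace(path: str | Path, w: VelocityWaveform) -> None:
    """Write a trace as CSV with a ``# period_s=`` comment line."""
    lines = [f"# period_s={float(w.period)!r}", _HEADER]
    lines += [f"{float(t)!r},{float(v)!r}" for t, v in zip(w.time, w.values)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_velocity_trace(
    path: str | Path, samples_per_cycle: int | None = None
) -> VelocityWaveform:
    """Read a two-column (time_s, velocity_cm_s) trace.

    Time must be strictly increasing and cover at least 16 samples.  The
    period is taken from an optional ``# period_s=`` comment, falling back to
    the file's time span plus one sample interval.  The trace is resampled
    onto the uniform internal grid.
    """
    text = Path(path).read_text()
    period = None
    rows = []
    for line in io.StringIO(text):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "period_s=" in line:
                period = float(line.split("period_s=")[1])
            continue
        if line.lower().startswith("time"):
            continue
        parts = line.replace("\t", ",").split(",")
        rows.append((float(parts[0]), float(parts[1])))
    if len(rows) < 16:
        raise ValueError(f"trace has {len(rows)} samples; need at least 16")
    t = np.array([r[0] for r in rows])
    v = np.array([r[1] for r in rows])
    if np.any(np.diff(t) <= 0):
        raise ValueError("time column must be strictly increasing")
    t = t - t[0]
    if period is None:
        period = float(t[-1] + np.median(np.diff(t)))
    n = samples_per_cycle or len(rows)
    t_new = np.arange(n) * period / n
    v_new = np.interp(t_new, t, v)  # flat extrapolation beyond last sample
    return VelocityWaveform(time=t_new, values=v_new, period=period)
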