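"""Lumped electrical elements for arterial segments and Windkessel beds.

Each arterial segment is represented by a series resistor–inductor carrying
the segment flow, with a shunt capacitor at its distal end:

* viscous (Poiseuille) resistance  ``R = 8 μ l / (π r⁴)``
* blood inertance                  ``L = ρ l / (π r²)``
* thin-wall vessel compliance      ``C = 3 π r³ l / (2 E h)``

with ``l`` and ``r`` the segment length and radius, ``μ`` the blood
viscosity, ``ρ`` the blood density, ``h = 0.15 r`` the wall thickness and
``E`` the Young's modulus.  All values are in CGS; converters to the
clinical mmHg-based units live in :mod:`fetalflow.units`.

Terminal vascular beds are three-element Windkessels: a characteristic
resistance ``Rc`` in series with a peripheral resistance ``Rp`` shunted by a
compliance ``Cp``.  ``Rc`` equals the high-frequency characteristic impedance
of the feeding segment, ``sqrt(L/C)`` in the lossless-line limit (a
Moens–Korteweg wave-speed variant is available for sensitivity checks).
The coronary bed is a single resistor.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from . import units
from .anatomy import FluidProperties, SegmentGeometry

#: vascular-bed identifiers
BED_IDS: tuple[str, ...] = (
    "right_upper",
    "left_upper",
    "right_brain",
    "left_brain",
    "right_lung",
    "left_lung",
    "peripheral",
    "coronary",
)

#: grouping used by the parameter tables (left/right members are tied)
BED_GROUPS: dict[str, tuple[str, ...]] = {
    "brain": ("left_brain", "right_brain"),
    "upper": ("left_upper", "right_upper"),
    "lungs": ("left_lung", "right_lung"),
    "peripheral": ("peripheral",),
    "coronary": ("coronary",),
}


@dataclass(frozen=True)
class SegmentElectrical:
    """R, L, C of one arterial segment, CGS units."""

    resistance: float  # dyn·s·cm⁻⁵
    inertance: float  # g·cm⁻⁴
    compliance: float  # cm⁵·dyn⁻¹

    def __post_init__(self):
        if self.resistance <= 0 or self.inertance <= 0 or self.compliance <= 0:
            raise ValueError("segment R, L, C must all be positive")


@dataclass(frozen=True)
class VascularBed:
    """Three-element Windkessel terminal (or single-resistor coronary bed).

    ``characteristic_resistance`` and ``compliance`` are ``None`` exactly for
    the coronary bed.
    """

    bed_id: str
    peripheral_resistance: float  # dyn·s·cm⁻⁵
    characteristic_resistance: float | None = None
    compliance: float | None = None

    def __post_init__(self):
        if self.bed_id not in BED_IDS:
            raise ValueError(f"unknown bed_id {self.bed_id!r}")
        if self.peripheral_resistance <= 0:
            raise ValueError("Rp must be positive")
        if self.is_coronary:
            if self.characteristic_resistance is not None or self.compliance is not None:
                raise ValueError("coronary bed is a single resistor (no Rc, no Cp)")
        else:
            if self.characteristic_resistance is None or self.compliance is None:
                raise ValueError(f"{self.bed_id}: Windkessel bed needs Rc and Cp")
            if self.characteristic_resistance <= 0 or self.compliance <= 0:
                raise ValueError(f"{self.bed_id}: Rc and Cp must be positive")

    @property
    def is_coronary(self) -> bool:
        return self.bed_id == "coronary"

    @property
    def dc_resistance(self) -> float:
        """Resistance seen at zero frequency (Cp open): Rc + Rp."""
        if self.is_coronary:
            return self.peripheral_resistance
        return self.characteristic_resistance + self.peripheral_resistance


def poiseuille_resistance(geom: SegmentGeometry, fluid: FluidProperties) -> float:
    """Viscous resistance ``8 μ l / (π r⁴)`` in dyn·s·cm⁻⁵."""
    if geom.radius <= 0:
        raise ValueError("radius must be positive")
    return 8.0 * fluid.viscosity * geom.length / (math.pi * geom.radius**4)


def blood_inertance(geom: SegmentGeometry, fluid: FluidProperties) -> float:
    """Blood inertance ``ρ l / (π r²)`` in g·cm⁻⁴."""
    if geom.radius <= 0:
        raise ValueError("radius must be positive")
    return fluid.density * geom.length / (math.pi * geom.radius**2)


def wall_compliance(geom: SegmentGeometry) -> float:
    """Thin-wall volumetric compliance ``3 π r³ l / (2 E h)`` in cm⁵·dyn⁻¹."""
    if geom.young_modulus <= 0 or geom.wall_thickness <= 0:
        raise ValueError("Young's modulus and wall thickness must be positive")
    return (
        3.0
        * math.pi
        * geom.radius**3
        * geom.length
        / (2.0 * geom.young_modulus * geom.wall_thickness)
    )


def segment_electrical(geom: SegmentGeometry, fluid: FluidProperties) -> SegmentElectrical:
    return SegmentElectrical(
        resistance=poiseuille_resistance(geom, fluid),
        inertance=blood_inertance(geom, fluid),
        compliance=wall_compliance(geom),
    )


def characteristic_resistance(
    elec: SegmentElectrical,
    geom: SegmentGeometry | None = None,
    fluid: FluidProperties | None = None,
    convention: str = "lossless_line",
) -> float:
    """Characteristic impedance of a feeding segment at high frequencies.

    The default ``"lossless_line"`` convention is ``sqrt(L/C)`` of the
    segment.  The alternative ``"wave_speed"`` convention uses the
    Moens–Korteweg pulse-wave speed, ``Rc = ρ c / (π r²)`` with
    ``c = sqrt(E h / (2 ρ r))``; the two differ by O(10%) and the choice is
    recorded on the assembled network.
    """
    if convention == "lossless_line":
        if elec.inertance <= 0 or elec.compliance <= 0:
            raise ValueError("L and C must be positive")
        return math.sqrt(elec.inertance / elec.compliance)
    if convention == "wave_speed":
        if geom is None or fluid is None:
            raise ValueError("wave_speed convention needs geometry and fluid properties")
        c = math.sqrt(
            geom.young_modulus * geom.wall_thickness / (2.0 * fluid.density * geom.radius)
        )
        return fluid.density * c / (math.pi * geom.radius**2)
    raise ValueError(f"unknown Rc convention {convention!r}")


def windkessel_bed(
    bed_id: str,
    feeding: SegmentElectrical,
    rp: float,
    cp: float,
    geom: SegmentGeometry | None = None,
    fluid: FluidProperties | None = None,
    rc_convention: str = "lossless_line",
) -> VascularBed:
    """Build a Windkessel bed with Rc taken from its feeding segment (CGS inputs)."""
    return VascularBed(
        bed_id=bed_id,
        peripheral_resistance=rp,
        characteristic_resistance=characteristic_resistance(
            feeding, geom, fluid, rc_convention
        ),
        compliance=cp,
    )


def coronary_bed(rp: float) -> VascularBed:
    return VascularBed(bed_id="coronary", peripheral_resistance=rp)


@functools.lru_cache(maxsize=1)
def _bed_parameter_table() -> pd.DataFrame:
    with resources.files("fetalflow.data").joinpath("bed_parameters.csv").open() as fh:
        return pd.read_csv(fh)


def load_bed_parameters(case: str = "control") -> dict[str, dict[str, float | None]]:
    """Built-in per-group bed parameters in clinical units (mmHg·s·ml⁻¹, ml·mmHg⁻¹).

    Returns ``{group: {"rp": ..., "cp": ...}}`` with ``cp`` ``None`` for the
    coronary group.  Cases: ``control``, ``iugr_pedf``, ``iugr_aedf``,
    ``iugr_redf`` (the IUGR columns are starting values prior to estimation).
    """
    table = _bed_parameter_table()
    sub = table[table["case"] == case]
    if sub.empty:
        raise KeyError(
            f"unknown case {case!r}; available: {sorted(table['case'].unique())}"
        )
    out: dict[str, dict[str, float | None]] = {}
    for _, row in sub.iterrows():
        cp = row["cp_ml_mmhg"]
        out[row["group"]] = {
            "rp": float(row["rp_mmhg_s_ml"]),
            "cp": None if pd.isna(cp) else float(cp),
        }
    return out


def bed_parameters_to_cgs(params: dict[str, dict[str, float | None]]):
    """Convert a per-group parameter mapping from clinical units to CGS."""
    out = {}
    for group, p in params.items():
        out[group] = {
            "rp": units.resistance_from_mmhg(p["rp"]),
            "cp": None if p.get("cp") is None else units.compliance_from_mmhg(p["cp"]),
        }
    return out
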