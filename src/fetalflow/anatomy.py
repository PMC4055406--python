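"""Gestational-age-dependent vessel geometry, blood properties and allometric scaling.

The arterial tree is described by 14 named segments whose length and diameter
grow linearly with gestational age (GA, in weeks).  The regression coefficients
(in mm and mm/week) and the Young's modulus of each segment are shipped as a
versioned CSV (``data/vessel_table.csv``) and evaluated on demand.  Wall
thickness is taken as 15% of the luminal radius throughout.

Blood viscosity rises linearly with gestational age,
``mu = (1.15 + 0.075*GA)/100`` poise, and density is fixed at 1.05 g·cm⁻³.

For personalization to an individual fetus, dimensions and vascular-bed
parameters are rescaled allometrically with the ratio of the subject's
estimated weight to the gestational-age reference weight (Gallivan growth
curve), each quantity with its own power-law exponent.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping

import pandas as pd

#: canonical vessel identifiers, in tree order
VESSELS: tuple[str, ...] = (
    "ascending_aorta",
    "aortic_isthmus",
    "descending_aorta",
    "ductus_arteriosus",
    "main_pulmonary_artery",
    "right_pulmonary_artery",
    "left_pulmonary_artery",
    "brachiocephalic_trunk",
    "left_subclavian_artery",
    "right_subclavian_artery",
    "left_common_carotid_artery",
    "right_common_carotid_artery",
    "left_internal_carotid_artery",
    "right_internal_carotid_artery",
)

#: default validity window of the geometric regressions, weeks
GA_WINDOW: tuple[float, float] = (20.0, 42.0)

WALL_THICKNESS_RATIO = 0.15  # h = 0.15 r

BLOOD_DENSITY = 1.05  # g·cm⁻³

# Gallivan log10-weight growth polynomial coefficients
_GALLIVAN = (0.2508, 0.1458, -0.0016)


class GestationalAgeError(ValueError):
    """GA outside the validity window or yielding non-positive dimensions."""


@dataclass(frozen=True)
class SegmentGeometry:
    """Physical dimensions of one arterial segment (CGS units)."""

    vessel_id: str
    length: float  # cm
    radius: float  # cm
    wall_thickness: float  # cm
    young_modulus: float  # dyn·cm⁻²

    def __post_init__(self):
        if self.length <= 0 or self.radius <= 0:
            raise GestationalAgeError(
                f"{self.vessel_id}: non-positive dimensions "
                f"(l={self.length:.4g} cm, r={self.radius:.4g} cm)"
            )

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass(frozen=True)
class FluidProperties:
    """Blood viscosity (poise) and density (g·cm⁻³)."""

    viscosity: float
    density: float = BLOOD_DENSITY

    def __post_init__(self):
        if self.viscosity <= 0 or self.density <= 0:
            raise ValueError("viscosity and density must be positive")


@dataclass(frozen=True)
class AllometricConfig:
    """Power-law exponents and weights for allometric rescaling.

    A quantity Y computed for the reference weight ``W0`` is rescaled for a
    subject of weight ``Wi`` as ``Y_i = Y_0 * (Wi/W0)**k`` with the exponent
    appropriate to its kind.  Default exponents follow the scaling laws
    commonly adopted for human fetal lumped circulation models: dimensions
    grow close to isometrically (k = 0.33), vascular resistance falls roughly
    inversely with weight (k = -0.933) and compliance grows super-linearly
    (k = 1.33).  All three are deliberately configurable, as they are
    literature conventions rather than quantities this model determines.
    """

    reference_weight: float  # g
    subject_weight: float  # g
    exponent_dimension: float = 0.33
    exponent_resistance: float = -0.933
    exponent_compliance: float = 1.33

    def __post_init__(self):
        if self.reference_weight <= 0 or self.subject_weight <= 0:
            raise ValueError("weights must be positive")
        for name in ("exponent_dimension", "exponent_resistance", "exponent_compliance"):
            v = getattr(self, name)
            if v != v or v in (float("inf"), float("-inf")):
                raise ValueError(f"{name} must be finite")

    @property
    def weight_ratio(self) -> float:
        return self.subject_weight / self.reference_weight

    def factor(self, kind: str) -> float:
        """Multiplicative scale factor for a quantity of the given kind."""
        try:
            exponent = {
                "dimension": self.exponent_dimension,
                "resistance": self.exponent_resistance,
                "compliance": self.exponent_compliance,
            }[kind]
        except KeyError:
            raise KeyError(f"unknown allometric kind {kind!r}") from None
        return self.weight_ratio**exponent


@functools.lru_cache(maxsize=1)
def load_vessel_table() -> pd.DataFrame:
    """Regression coefficients for the 14 segments, indexed by vessel_id."""
    with resources.files("fetalflow.data").joinpath("vessel_table.csv").open() as fh:
        table = pd.read_csv(fh, index_col="vessel_id")
    return table


def blood_viscosity(gestational_age: float) -> float:
    """Blood viscosity in poise, ``(1.15 + 0.075*GA)/100``."""
    if gestational_age <= 0:
        raise GestationalAgeError("gestational age must be positive")
    return (1.15 + 0.075 * gestational_age) / 100.0


def blood_properties(gestational_age: float) -> FluidProperties:
    return FluidProperties(viscosity=blood_viscosity(gestational_age))


def segment_geometry(
    vessel_id: str,
    gestational_age: float,
    ga_window: tuple[float, float] = GA_WINDOW,
) -> SegmentGeometry:
    """Evaluate the linear growth regressions for one segment at a given GA.

    Lengths and diameters are regressed in mm and converted to cm; radius is
    half the diameter, wall thickness 15% of the radius.  Raises
    :class:`GestationalAgeError` if the GA lies outside ``ga_window`` or a
    regression evaluates non-positive.
    """
    table = load_vessel_table()
    if vessel_id not in table.index:
        raise KeyError(f"unknown vessel_id {vessel_id!r}; expected one of {VESSELS}")
    lo, hi = ga_window
    if not lo <= gestational_age <= hi:
        raise GestationalAgeError(
            f"gestational age {gestational_age} weeks outside validity window {ga_window}"
        )
    row = table.loc[vessel_id]
    length_mm = row["length_intercept_mm"] + row["length_slope_mm_per_week"] * gestational_age
    diam_mm = row["diam_intercept_mm"] + row["diam_slope_mm_per_week"] * gestational_age
    if length_mm <= 0 or diam_mm <= 0:
        raise GestationalAgeError(
            f"{vessel_id}: regression non-positive at GA {gestational_age} weeks "
            f"(length {length_mm:.3g} mm, diameter {diam_mm:.3g} mm)"
        )
    radius_cm = diam_mm / 20.0
    return SegmentGeometry(
        vessel_id=vessel_id,
        length=length_mm / 10.0,
        radius=radius_cm,
        wall_thickness=WALL_THICKNESS_RATIO * radius_cm,
        young_modulus=row["young_modulus_dyn_cm2"],
    )


def all_segment_geometries(
    gestational_age: float, ga_window: tuple[float, float] = GA_WINDOW
) -> dict[str, SegmentGeometry]:
    return {v: segment_geometry(v, gestational_age, ga_window) for v in VESSELS}


def reference_weight(
    gestational_age: float, ga_window: tuple[float, float] = GA_WINDOW
) -> float:
    """Reference fetal weight (g) from the Gallivan growth curve.

    ``log10(W) = 0.2508 + 0.1458*GA - 0.0016*GA**2`` with GA in weeks.
    """
    lo, hi = ga_window
    if not lo <= gestational_age <= hi:
        raise GestationalAgeError(
            f"gestational age {gestational_age} weeks outside validity window {ga_window}"
        )
    a, b, c = _GALLIVAN
    return 10.0 ** (a + b * gestational_age + c * gestational_age**2)


def scale_geometry(geom: SegmentGeometry, config: AllometricConfig) -> SegmentGeometry:
    """Allometrically rescale every linear dimension of a segment."""
    f = config.factor("dimension")
    return replace(
        geom,
        length=geom.length * f,
        radius=geom.radius * f,
        wall_thickness=geom.wall_thickness * f,
    )


def allometric_scale(
    values: Mapping[str, float], config: AllometricConfig, kind: str
) -> dict[str, float]:
    """Rescale a mapping of named parameters of one kind.

    ``kind`` selects the exponent: ``"dimension"``, ``"resistance"`` or
    ``"compliance"``.  Scaling is purely multiplicative, so composing two
    scalings equals scaling by the composed weight ratio.
    """
    f = config.factor(kind)
    return {k: v * f for k, v in values.items()}
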