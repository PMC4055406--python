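"""Assembly of the full arterial circuit and its state-space realization.

The circuit couples 14 arterial RLC segments, 8 terminal vascular beds and
two imposed inflow sources (aortic and pulmonary valves).  The topology:

* aortic source → ascending aorta → arch node, which feeds the coronary
  resistor, the brachiocephalic trunk, the left common carotid, the left
  subclavian and the aortic isthmus;
* brachiocephalic trunk → right subclavian (right-upper bed) and right
  common → right internal carotid (right-brain bed);
* left common → left internal carotid (left-brain bed); left subclavian →
  left-upper bed;
* pulmonary source → main pulmonary artery → pulmonary junction, feeding
  both lung beds and the ductus arteriosus;
* ductus and isthmus join at the descending-aorta junction → descending
  aorta → combined lower-body & placenta (peripheral) bed.

Component census: 29 resistors (14 segment + 7 bed Rc + 7 bed Rp + 1
coronary), 21 capacitors (14 segment + 7 bed Cp) and 14 inductors, with the
venous side grounded at 0 mmHg.

The state-space realization treats each segment as a series R–L branch with
a shunt C at its distal node and each Windkessel bed as Rc in series with
the parallel Rp‖Cp pair.  The two valve-fed segments carry the imposed
inflows directly, so their inductor currents are inputs rather than states;
the isthmus and the ductus share their distal node, merging their shunt
capacitors into one pressure unknown.  The resulting LTI system has
12 inductor-flow states and 20 pressure states (13 capacitive nodes + 7 bed
compliances).

:func:`dc_operating_point` provides an independent purely resistive solve of
the same circuit (inductors shorted, capacitors open) used as a
cross-checking oracle for cycle-averaged quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import yaml

from . import units
from .anatomy import GA_WINDOW, all_segment_geometries, blood_properties
from .components import (
    BED_GROUPS,
    BED_IDS,
    SegmentElectrical,
    VascularBed,
    bed_parameters_to_cgs,
    coronary_bed,
    load_bed_parameters,
    segment_electrical,
    windkessel_bed,
)

#: (vessel_id, proximal node, distal node); flows are positive proximal → distal
SEGMENT_TOPOLOGY: tuple[tuple[str, str, str], ...] = (
    ("ascending_aorta", "aortic_root", "arch"),
    ("brachiocephalic_trunk", "arch", "brachiocephalic_distal"),
    ("left_common_carotid_artery", "arch", "left_carotid_distal"),
    ("left_subclavian_artery", "arch", "left_upper_attach"),
    ("aortic_isthmus", "arch", "dao_junction"),
    ("right_subclavian_artery", "brachiocephalic_distal", "right_upper_attach"),
    ("right_common_carotid_artery", "brachiocephalic_distal", "right_carotid_distal"),
    ("right_internal_carotid_artery", "right_carotid_distal", "right_brain_attach"),
    ("left_internal_carotid_artery", "left_carotid_distal", "left_brain_attach"),
    ("main_pulmonary_artery", "pulmonary_root", "pulmonary_junction"),
    ("right_pulmonary_artery", "pulmonary_junction", "right_lung_attach"),
    ("left_pulmonary_artery", "pulmonary_junction", "left_lung_attach"),
    ("ductus_arteriosus", "pulmonary_junction", "dao_junction"),
    ("descending_aorta", "dao_junction", "peripheral_attach"),
)

#: bed_id → (attachment node, feeding vessel providing Rc; None for coronary)
BED_ATTACHMENT: dict[str, tuple[str, str | None]] = {
    "right_upper": ("right_upper_attach", "right_subclavian_artery"),
    "left_upper": ("left_upper_attach", "left_subclavian_artery"),
    "right_brain": ("right_brain_attach", "right_internal_carotid_artery"),
    "left_brain": ("left_brain_attach", "left_internal_carotid_artery"),
    "right_lung": ("right_lung_attach", "right_pulmonary_artery"),
    "left_lung": ("left_lung_attach", "left_pulmonary_artery"),
    "peripheral": ("peripheral_attach", "descending_aorta"),
    "coronary": ("arch", None),
}

#: source id → (injection node, segment carrying the imposed flow)
SOURCES: dict[str, tuple[str, str]] = {
    "aortic": ("aortic_root", "ascending_aorta"),
    "pulmonary": ("pulmonary_root", "main_pulmonary_artery"),
}

#: node whose pressure defines mean arterial blood pressure (ascending aorta)
CENTRAL_NODE = "arch"


class NetworkError(ValueError):
    """Raised when a circuit fails its structural invariants."""


@dataclass(frozen=True)
class Segment:
    vessel_id: str
    elec: SegmentElectrical
    proximal: str
    distal: str


@dataclass(frozen=True)
class NetworkModel:
    """The assembled circuit: segments, beds, sources, venous ground at 0 mmHg."""

    segments: tuple[Segment, ...]
    beds: dict[str, VascularBed]
    bed_nodes: dict[str, str]
    sources: dict[str, tuple[str, str]] = field(default_factory=lambda: dict(SOURCES))
    gestational_age: float | None = None
    rc_convention: str = "lossless_line"

    def __post_init__(self):
        self.validate()

    # -- structural invariants -------------------------------------------------

    @property
    def census(self) -> tuple[int, int, int]:
        """(resistors, capacitors, inductors) counted from actual components."""
        n_r = len(self.segments)
        n_c = len(self.segments)
        n_l = len(self.segments)
        for bed in self.beds.values():
            if bed.is_coronary:
                n_r += 1
            else:
                n_r += 2
                n_c += 1
        return n_r, n_c, n_l

    def validate(self) -> None:
        if len(self.segments) != 14:
            raise NetworkError(f"expected 14 segments, got {len(self.segments)}")
        if set(self.beds) != set(BED_IDS):
            raise NetworkError(f"expected beds {BED_IDS}, got {sorted(self.beds)}")
        if len(self.sources) != 2:
            raise NetworkError("expected exactly 2 flow sources")
        if self.census != (29, 21, 14):
            raise NetworkError(f"component census {self.census} != (29, 21, 14)")
        # connectivity of the segment graph plus bed attachments
        nodes = {s.proximal for s in self.segments} | {s.distal for s in self.segments}
        for bed_id, node in self.bed_nodes.items():
            if node not in nodes:
                raise NetworkError(f"bed {bed_id} attached to unknown node {node!r}")
        parent = {n: n for n in nodes}

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for s in self.segments:
            parent[find(s.proximal)] = find(s.distal)
        # the ductus ties the two sides; beds connect to ground, not to each other
        roots = {find(n) for n in nodes}
        if len(roots) != 1:
            raise NetworkError("segment graph is disconnected")

    # -- convenience accessors -------------------------------------------------

    def segment(self, vessel_id: str) -> Segment:
        for s in self.segments:
            if s.vessel_id == vessel_id:
                return s
        raise KeyError(vessel_id)

    def source_segments(self) -> dict[str, str]:
        """source id → vessel carrying its imposed flow."""
        return {src: vessel for src, (_node, vessel) in self.sources.items()}

    # -- parameter variation ---------------------------------------------------

    def with_scaled_rp(self, factors: float | Mapping[str, float]) -> "NetworkModel":
        """Return a copy with bed peripheral resistances multiplied by factors.

        ``factors`` may be a single scalar (uniform scaling, as used for mean
        pressure calibration) or a mapping keyed by bed group (``brain``,
        ``upper``, ``lungs``, ``peripheral``, ``coronary``) or bed id.
        """
        if isinstance(factors, (int, float)):
            per_bed = {b: float(factors) for b in BED_IDS}
        else:
            per_bed = {b: 1.0 for b in BED_IDS}
            for key, f in factors.items():
                members = BED_GROUPS.get(key, (key,))
                for m in members:
                    if m not in per_bed:
                        raise KeyError(f"unknown bed or group {key!r}")
                    per_bed[m] = float(f)
        beds = {
            b: replace(bed, peripheral_resistance=bed.peripheral_resistance * per_bed[b])
            for b, bed in self.beds.items()
        }
        return replace(self, beds=beds)

    def with_bed_compliances(self, cp_by_group: Mapping[str, float]) -> "NetworkModel":
        """Return a copy with grouped bed compliances replaced (CGS values)."""
        beds = dict(self.beds)
        for group, cp in cp_by_group.items():
            for m in BED_GROUPS.get(group, (group,)):
                if beds[m].is_coronary:
                    raise ValueError("coronary bed has no compliance")
                beds[m] = replace(beds[m], compliance=float(cp))
        return replace(self, beds=beds)

    def rp_by_group(self, clinical_units: bool = False) -> dict[str, float]:
        out = {}
        for group, members in BED_GROUPS.items():
            rp = self.beds[members[0]].peripheral_resistance
            out[group] = units.resistance_to_mmhg(rp) if clinical_units else rp
        return out

    def cp_by_group(self, clinical_units: bool = False) -> dict[str, float]:
        out = {}
        for group, members in BED_GROUPS.items():
            if group == "coronary":
                continue
            cp = self.beds[members[0]].compliance
            out[group] = units.compliance_to_mmhg(cp) if clinical_units else cp
        return out


def build_control_network(
    gestational_age: float,
    bed_parameters: Mapping[str, Mapping[str, float | None]] | None = None,
    rc_convention: str = "lossless_line",
    ga_window: tuple[float, float] = GA_WINDOW,
    dimension_scale: float = 1.0,
) -> NetworkModel:
    """Build the circuit at a given gestational age.

    ``bed_parameters`` maps bed groups to ``{"rp": ..., "cp": ...}`` in
    clinical units (mmHg·s·ml⁻¹ and ml·mmHg⁻¹); the built-in control values
    are used when omitted.  Segment R, L, C follow from the growth-regressed
    geometry and GA-dependent viscosity; each Windkessel Rc is set from its
    feeding segment.  ``dimension_scale`` multiplies every vessel dimension
    (used for allometric rescaling to a subject's weight).
    """
    if bed_parameters is None:
        bed_parameters = load_bed_parameters("control")
    missing = set(BED_GROUPS) - set(bed_parameters)
    if missing:
        raise NetworkError(f"missing bed parameters for groups: {sorted(missing)}")
    params = bed_parameters_to_cgs(dict(bed_parameters))

    fluid = blood_properties(gestational_age)
    geoms = all_segment_geometries(gestational_age, ga_window)
    if dimension_scale != 1.0:
        if dimension_scale <= 0:
            raise ValueError("dimension_scale must be positive")
        from dataclasses import replace as _dc_replace

        geoms = {
            v: _dc_replace(
                g,
                length=g.length * dimension_scale,
                radius=g.radius * dimension_scale,
                wall_thickness=g.wall_thickness * dimension_scale,
            )
            for v, g in geoms.items()
        }
    elecs = {v: segment_electrical(g, fluid) for v, g in geoms.items()}

    segments = tuple(
        Segment(vessel_id=v, elec=elecs[v], proximal=p, distal=d)
        for v, p, d in SEGMENT_TOPOLOGY
    )

    group_of = {m: g for g, members in BED_GROUPS.items() for m in members}
    beds: dict[str, VascularBed] = {}
    bed_nodes: dict[str, str] = {}
    for bed_id, (node, feeding) in BED_ATTACHMENT.items():
        p = params[group_of[bed_id]]
        if bed_id == "coronary":
            beds[bed_id] = coronary_bed(p["rp"])
        else:
            if p["cp"] is None:
                raise NetworkError(f"bed group {group_of[bed_id]!r} needs a compliance")
            beds[bed_id] = windkessel_bed(
                bed_id,
                elecs[feeding],
                rp=p["rp"],
                cp=p["cp"],
                geom=geoms[feeding],
                fluid=fluid,
                rc_convention=rc_convention,
            )
        bed_nodes[bed_id] = node

    return NetworkModel(
        segments=segments,
        beds=beds,
        bed_nodes=bed_nodes,
        gestational_age=gestational_age,
        rc_convention=rc_convention,
    )


# ---------------------------------------------------------------------------
# state-space realization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ODESystem:
    """LTI realization ``dx/dt = A x + B u`` of a :class:`NetworkModel`.

    States: inductor flows of the non-source-fed segments, then pressures of
    the capacitive nodes, then bed-compliance pressures.  Inputs
    ``u = (Q_aortic, Q_pulmonary)`` in ml·s⁻¹.
    """

    A: np.ndarray
    B: np.ndarray
    state_names: tuple[str, ...]
    flow_index: dict[str, int]  # vessel_id → state row (free segments)
    node_index: dict[str, int]  # capacitive node → state row
    bed_index: dict[str, int]  # non-coronary bed → state row
    source_info: dict[str, dict]  # source id → {vessel, input, R, L, root, entry}
    network: NetworkModel

    @property
    def n_states(self) -> int:
        return self.A.shape[0]


def assemble_state_space(network: NetworkModel) -> ODESystem:
    """Derive the Kirchhoff ODEs of the circuit."""
    source_vessels = {vessel: src for src, (_n, vessel) in network.sources.items()}
    input_order = ("aortic", "pulmonary")

    free_segments = [s for s in network.segments if s.vessel_id not in source_vessels]

    # node capacitance: shunt C of every segment at its distal node (parallel
    # capacitors at a shared node merge into one pressure unknown)
    cap_nodes: dict[str, float] = {}
    for s in network.segments:
        cap_nodes[s.distal] = cap_nodes.get(s.distal, 0.0) + s.elec.compliance

    nodes = [s.distal for s in network.segments]
    nodes = list(dict.fromkeys(nodes))  # stable order, dedup

    wk_beds = [b for b in BED_IDS if not network.beds[b].is_coronary]

    n_q = len(free_segments)
    n_p = len(nodes)
    n_b = len(wk_beds)
    n = n_q + n_p + n_b

    flow_index = {s.vessel_id: i for i, s in enumerate(free_segments)}
    node_index = {node: n_q + i for i, node in enumerate(nodes)}
    bed_index = {b: n_q + n_p + i for i, b in enumerate(wk_beds)}

    A = np.zeros((n, n))
    B = np.zeros((n, 2))

    # inductor branches: L dq/dt = p_prox - p_dist - R q
    for s in free_segments:
        iq = flow_index[s.vessel_id]
        L, R = s.elec.inertance, s.elec.resistance
        for node, sign in ((s.proximal, 1.0), (s.distal, -1.0)):
            if node in node_index:
                A[iq, node_index[node]] += sign / L
            elif node in ("aortic_root", "pulmonary_root"):
                raise NetworkError(f"free segment {s.vessel_id} starts at a source node")
        A[iq, iq] -= R / L

    # node balances: C_n dp/dt = inflows - outflows - bed drain
    for node, ip in node_index.items():
        C = cap_nodes[node]
        for s in network.segments:
            if s.vessel_id in source_vessels:
                if s.distal == node:
                    j = input_order.index(source_vessels[s.vessel_id])
                    B[ip, j] += 1.0 / C
                continue
            iq = flow_index[s.vessel_id]
            if s.distal == node:
                A[ip, iq] += 1.0 / C
            if s.proximal == node:
                A[ip, iq] -= 1.0 / C
        for bed_id, attach in network.bed_nodes.items():
            if attach != node:
                continue
            bed = network.beds[bed_id]
            if bed.is_coronary:
                A[ip, ip] -= 1.0 / (bed.peripheral_resistance * C)
            else:
                rc = bed.characteristic_resistance
                A[ip, ip] -= 1.0 / (rc * C)
                A[ip, bed_index[bed_id]] += 1.0 / (rc * C)

    # bed compliances: Cp dp_b/dt = (p_attach - p_b)/Rc - p_b/Rp
    for bed_id in wk_beds:
        bed = network.beds[bed_id]
        ib = bed_index[bed_id]
        ip = node_index[network.bed_nodes[bed_id]]
        rc, rp, cp = bed.characteristic_resistance, bed.peripheral_resistance, bed.compliance
        A[ib, ip] += 1.0 / (rc * cp)
        A[ib, ib] -= 1.0 / (rc * cp) + 1.0 / (rp * cp)

    source_info = {}
    for src, (root, vessel) in network.sources.items():
        seg = network.segment(vessel)
        source_info[src] = {
            "vessel": vessel,
            "input": input_order.index(src),
            "R": seg.elec.resistance,
            "L": seg.elec.inertance,
            "root": root,
            "entry": seg.distal,
        }

    state_names = tuple(
        [f"q:{s.vessel_id}" for s in free_segments]
        + [f"p:{node}" for node in nodes]
        + [f"p:bed:{b}" for b in wk_beds]
    )
    return ODESystem(
        A=A,
        B=B,
        state_names=state_names,
        flow_index=flow_index,
        node_index=node_index,
        bed_index=bed_index,
        source_info=source_info,
        network=network,
    )


# ---------------------------------------------------------------------------
# DC resistive oracle
# ---------------------------------------------------------------------------


def dc_operating_point(
    network: NetworkModel, mean_inflows: Mapping[str, float]
) -> dict[str, dict[str, float]]:
    """Solve the purely resistive circuit for cycle-averaged quantities.

    At zero frequency inductors are shorts and capacitors are open, so each
    segment reduces to its resistance and each Windkessel bed to Rc + Rp in
    series.  ``mean_inflows`` gives the cycle-mean source flows in ml·s⁻¹,
    keyed ``"aortic"``/``"pulmonary"``.  Returns node pressures (CGS), bed
    flows and segment flows.  This nodal solve shares no code with the
    transient state-space path and serves as its oracle.
    """
    source_vessels = {vessel: src for src, (_n, vessel) in network.sources.items()}
    nodes = list(dict.fromkeys(s.distal for s in network.segments))
    idx = {node: i for i, node in enumerate(nodes)}
    G = np.zeros((len(nodes), len(nodes)))
    inj = np.zeros(len(nodes))

    for s in network.segments:
        if s.vessel_id in source_vessels:
            inj[idx[s.distal]] += mean_inflows[source_vessels[s.vessel_id]]
            continue
        g = 1.0 / s.elec.resistance
        iu, iv = idx[s.proximal], idx[s.distal]
        G[iu, iu] += g
        G[iv, iv] += g
        G[iu, iv] -= g
        G[iv, iu] -= g

    for bed_id, node in network.bed_nodes.items():
        g = 1.0 / network.beds[bed_id].dc_resistance
        G[idx[node], idx[node]] += g

    try:
        p = np.linalg.solve(G, inj)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by validate()
        raise NetworkError("singular resistive network") from exc

    node_pressures = {node: p[i] for node, i in idx.items()}
    bed_flows = {
        bed_id: node_pressures[node] / network.beds[bed_id].dc_resistance
        for bed_id, node in network.bed_nodes.items()
    }
    segment_flows = {}
    for s in network.segments:
        if s.vessel_id in source_vessels:
            segment_flows[s.vessel_id] = float(mean_inflows[source_vessels[s.vessel_id]])
        else:
            segment_flows[s.vessel_id] = (
                node_pressures[s.proximal] - node_pressures[s.distal]
            ) / s.elec.resistance
    return {
        "node_pressures": node_pressures,
        "bed_flows": bed_flows,
        "segment_flows": segment_flows,
    }


# ---------------------------------------------------------------------------
# YAML description
# ---------------------------------------------------------------------------


def to_dict(network: NetworkModel) -> dict:
    """Serializable description (element values in CGS)."""
    return {
        "gestational_age": network.gestational_age,
        "rc_convention": network.rc_convention,
        "segments": [
            {
                "vessel_id": s.vessel_id,
                "proximal": s.proximal,
                "distal": s.distal,
                "resistance": float(s.elec.resistance),
                "inertance": float(s.elec.inertance),
                "compliance": float(s.elec.compliance),
            }
            for s in network.segments
        ],
        "beds": [
            {
                "bed_id": b,
                "node": network.bed_nodes[b],
                "peripheral_resistance": float(bed.peripheral_resistance),
                "characteristic_resistance": None
                if bed.characteristic_resistance is None
                else float(bed.characteristic_resistance),
                "compliance": None if bed.compliance is None else float(bed.compliance),
            }
            for b, bed in network.beds.items()
        ],
        "sources": {src: list(v) for src, v in network.sources.items()},
    }


def from_dict(d: dict) -> NetworkModel:
    segments = tuple(
        Segment(
            vessel_id=s["vessel_id"],
            elec=SegmentElectrical(
                resistance=s["resistance"],
                inertance=s["inertance"],
                compliance=s["compliance"],
            ),
            proximal=s["proximal"],
            distal=s["distal"],
        )
        for s in d["segments"]
    )
    beds = {}
    bed_nodes = {}
    for b in d["beds"]:
        beds[b["bed_id"]] = VascularBed(
            bed_id=b["bed_id"],
            peripheral_resistance=b["peripheral_resistance"],
            characteristic_resistance=b["characteristic_resistance"],
            compliance=b["compliance"],
        )
        bed_nodes[b["bed_id"]] = b["node"]
    return NetworkModel(
        segments=segments,
        beds=beds,
        bed_nodes=bed_nodes,
        sources={src: tuple(v) for src, v in d["sources"].items()},
        gestational_age=d.get("gestational_age"),
        rc_convention=d.get("rc_convention", "lossless_line"),
    )


def to_yaml(network: NetworkModel) -> str:
    return yaml.safe_dump(to_dict(network), sort_keys=False)


def from_yaml(text: str) -> NetworkModel:
    return from_dict(yaml.safe_load(text))
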