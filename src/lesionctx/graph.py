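"""Lesion-context graphs and human-readable pathway panels.

The graph is a purely summarizing, post-hoc structure: nodes are the tumor,
pleural regions (a contact patch and a 1-10 mm ring), adhesion patches and
vessel segments; edges encode spatial relations (distance, contact, crossing)
with weight exp(-distance / lambda). One or two rounds of linear message
passing aggregate neighbor features; nothing here feeds back into concepts,
edits or model predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage

from . import concepts as cx
from .audit import AuditReport
from .volumes import ADHESION, LabelVolume, PLEURA, TUMOR, VESSEL

#: Edge-weight length scale (mm) and maximum node separation for an edge (mm).
DEFAULT_LAMBDA_MM = 5.0
DEFAULT_EDGE_RADIUS_MM = 10.0
#: Distance at or below which two structures are "in contact" (mm).
CONTACT_MM = 1.0
#: A vessel "crosses" the tumor when it intersects this expansion shell (mm).
CROSSING_SHELL_MM = 5.0

_STRUCT26 = ndimage.generate_binary_structure(3, 3)

#: Feature vector layout shared by all nodes: (size, distance-to-tumor, caliber).
NODE_FEATURES = ("size", "distance_to_tumor_mm", "caliber_mm")


@dataclass
class PathwayPanel:
    """Per-risk explanation sentences with full numeric traceability."""

    case_id: str
    model_id: str
    config_hash: str
    risks: dict[str, float]
    pathways: dict[str, list[dict]]

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "model_id": self.model_id,
            "config_hash": self.config_hash,
            "risks": self.risks,
            "pathways": self.pathways,
        }

    def to_text(self) -> str:
        lines = [f"Pathway panel for {self.case_id} (model {self.model_id})"]
        for risk, entries in self.pathways.items():
            lines.append(f"\n{risk} (predicted risk {self.risks[risk]:.3f}):")
            for e in entries:
                lines.append(f"  {e['arrow']} {e['sentence']}")
        return "\n".join(lines)


def _component_masks(mask: np.ndarray) -> list[np.ndarray]:
    comps, n = ndimage.label(mask, structure=_STRUCT26)
    return [comps == i for i in range(1, n + 1)]


def build_graph(
    vol: LabelVolume,
    concepts: dict[str, float] | None = None,
    edge_radius_mm: float = DEFAULT_EDGE_RADIUS_MM,
    lambda_mm: float = DEFAULT_LAMBDA_MM,
) -> nx.Graph:
    """Build the lesion-context graph for one case.

    Nodes: the tumor; pleural regions partitioned by distance band around the
    tumor (contact patch at <= 1 mm, ring at 1-10 mm); adhesion patches and
    vessel segments as connected components. Edges join node pairs whose
    minimum surface distance is within ``edge_radius_mm``, carry weight
    exp(-d / lambda), and flag contact (d <= 1 mm) and vessel-tumor crossing
    (vessel inside the tumor's 5 mm expansion shell).
    """
    tumor = vol.mask(TUMOR)
    if not tumor.any():
        raise ValueError("tumor label is required")
    concepts = concepts if concepts is not None else cx.extract_concepts(vol)
    sp = vol.spacing
    voxel_area = sp[0] * sp[1]
    voxel_vol = sp[0] * sp[1] * sp[2]

    g = nx.Graph(lambda_mm=lambda_mm, edge_radius_mm=edge_radius_mm)
    g.add_node(
        "tumor",
        kind="tumor",
        size=concepts["tumor_volume_mm3"],
        distance_to_tumor_mm=0.0,
        caliber_mm=math.nan,
    )

    masks: dict[str, np.ndarray] = {"tumor": tumor}
    d_tumor = ndimage.distance_transform_edt(~tumor, sampling=sp)

    pleura = vol.mask(PLEURA)
    if pleura.any():
        contact = pleura & (d_tumor <= CONTACT_MM)
        ring = pleura & (d_tumor > CONTACT_MM) & (d_tumor <= edge_radius_mm)
        for name, m in (("pleura_contact", contact), ("pleura_ring", ring)):
            if m.any():
                g.add_node(
                    name,
                    kind="pleural region",
                    size=float(m.sum()) * voxel_area,
                    distance_to_tumor_mm=float(d_tumor[m].min()),
                    caliber_mm=math.nan,
                )
                masks[name] = m

    for i, m in enumerate(_component_masks(vol.mask(ADHESION))):
        name = f"adhesion_{i}"
        g.add_node(
            name,
            kind="adhesion patch",
            size=float(m.sum()) * voxel_area,
            distance_to_tumor_mm=float(d_tumor[m].min()),
            caliber_mm=math.nan,
        )
        masks[name] = m

    caliber = vol.caliber if vol.caliber is not None else np.zeros(vol.shape, np.float32)
    for i, m in enumerate(_component_masks(vol.mask(VESSEL))):
        name = f"vessel_{i}"
        g.add_node(
            name,
            kind="vessel segment",
            size=float(m.sum()) * voxel_vol,
            distance_to_tumor_mm=float(d_tumor[m].min()),
            caliber_mm=float(caliber[m].max()),
        )
        masks[name] = m

    names = list(masks)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            d = cx.min_surface_distance(masks[a], masks[b], sp)
            if d > edge_radius_mm:
                continue
            crossing = False
            if {g.nodes[a]["kind"], g.nodes[b]["kind"]} == {"tumor", "vessel segment"}:
                crossing = d <= CROSSING_SHELL_MM
            g.add_edge(
                a,
                b,
                distance_mm=d,
                weight=math.exp(-d / lambda_mm),
                contact=d <= CONTACT_MM,
                crossing=crossing,
            )
    return g


def _node_state(g: nx.Graph, v: str) -> np.ndarray:
    n = g.nodes[v]
    cal = n["caliber_mm"]
    return np.array([n["size"], n["distance_to_tumor_mm"], 0.0 if math.isnan(cal) else cal])


def message_passing(g: nx.Graph, rounds: int = 1, M: np.ndarray | None = None) -> nx.Graph:
    """h_v' = h_v + sum_u w_uv (M h_u), with a fixed linear map M (identity by
    default). Returns a copy with per-round states under node attribute
    ``state``; the input graph and every upstream structure are untouched.
    """
    if rounds not in (1, 2):
        raise ValueError("rounds must be 1 or 2")
    out = g.copy()
    dim = len(NODE_FEATURES)
    M = np.eye(dim) if M is None else np.asarray(M, dtype=float)
    if M.shape != (dim, dim):
        raise ValueError(f"M must be {dim}x{dim}")
    states = {v: _node_state(out, v) for v in out.nodes}
    for _ in range(rounds):
        new_states = {}
        for v in out.nodes:
            acc = states[v].copy()
            for u in out.neighbors(v):
                acc = acc + out.edges[u, v]["weight"] * (M @ states[u])
            new_states[v] = acc
        states = new_states
    for v, s in states.items():
        out.nodes[v]["state"] = s.tolist()
    return out


def graph_to_dict(g: nx.Graph) -> dict:
    return {
        "lambda_mm": g.graph.get("lambda_mm"),
        "edge_radius_mm": g.graph.get("edge_radius_mm"),
        "nodes": [{"name": v, **{k: _json_safe(val) for k, val in g.nodes[v].items()}} for v in sorted(g.nodes)],
        "edges": [
            {"source": a, "target": b, **{k: _json_safe(val) for k, val in g.edges[a, b].items()}}
            for a, b in sorted(g.edges)
        ],
    }


def _json_safe(v):
    if isinstance(v, float) and math.isnan(v):
        return None
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.bool_):
        return bool(v)
    return v


_RISK_CONCEPTS = {
    "pneumothorax": ("min_pleura_distance_mm", "mm", -1, "shorter tumor-pleura distance -> higher pneumothorax risk"),
    "hemorrhage": ("vessel_proximity_per_mm", "1/mm", +1, "higher vascular proximity -> higher hemorrhage risk"),
    "pleural_reaction": ("log_adhesion_area", "log mm^2", +1, "larger contiguous adhesion area -> higher pleural-reaction risk"),
}


def render_panel(
    graph: nx.Graph,
    concepts: dict[str, float],
    risks: dict[str, float],
    audit: AuditReport | None = None,
    case_id: str = "case",
    model_id: str = "model",
    config_hash: str = "",
) -> PathwayPanel:
    """Emit per-risk templated sentences binding measured concept values,
    prior directions and (optionally) cohort-level audit statistics.

    Every number in a sentence is copied verbatim from the concept vector or
    the audit report; the panel is deterministic given its inputs.
    """
    audit_by_pair = {}
    if audit is not None:
        for m in audit.monotonicity:
            audit_by_pair[(m.concept, m.risk)] = m

    pathways: dict[str, list[dict]] = {}
    for risk, (concept, unit, direction, template) in _RISK_CONCEPTS.items():
        if risk not in risks:
            continue
        value = concepts[concept]
        arrow = "(-)" if direction < 0 else "(+)"
        entry = {
            "concept": concept,
            "value": value,
            "unit": unit,
            "direction": direction,
            "arrow": arrow,
            "sentence": f"{template}: measured {concept} = {value:.3g} {unit}",
        }
        if risk == "pleural_reaction" and concepts.get("adhesion_area_mm2", 0.0) == 0.0:
            entry["sentence"] = (
                "no pleural adhesion present: adhesion pathway contributes no risk "
                f"(adhesion_area_mm2 = {concepts['adhesion_area_mm2']:.3g} mm^2)"
            )
        m = audit_by_pair.get((concept, risk))
        if m is not None:
            entry["audit"] = {
                "kendall_tau": m.tau,
                "violation_rate": m.violation_rate,
                "n": m.n,
            }
            entry["sentence"] += (
                f"; cohort audit: tau = {m.tau:.3g}, violation rate = {m.violation_rate:.3g} (n = {m.n})"
            )
        pathways[risk] = [entry]
    return PathwayPanel(
        case_id=case_id,
        model_id=model_id,
        config_hash=config_hash,
        risks={k: float(v) for k, v in risks.items()},
        pathways=pathways,
    )
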