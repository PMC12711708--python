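"""Lesion-context concept extraction from label volumes.

Concepts are the small set of pathophysiology-grounded measurements that sit
between the image and any risk explanation: tumor size and shape, the minimum
tumor-pleura distance and pleural contact area, proximity and caliber of the
nearest major (>= 2 mm) vessel, and the extent of pleural adhesion contiguous
with the tumor. All quantities carry physical units (mm, mm^2, mm^3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import ADHESION, LabelVolume, PLEURA, TUMOR, VESSEL

#: ConceptVector fields, in canonical column order.
CONCEPT_COLUMNS = [
    "tumor_volume_mm3",
    "tumor_surface_area_mm2",
    "sphericity",
    "elongation",
    "min_pleura_distance_mm",
    "pleural_contact_area_mm2",
    "vessel_min_distance_mm",
    "vessel_proximity_per_mm",
    "nearest_vessel_caliber_mm",
    "adhesion_present",
    "adhesion_area_mm2",
    "log_adhesion_area",
]

#: Minimum caliber (mm) for a vessel to qualify as "major".
MIN_VESSEL_CALIBER_MM = 2.0
#: Floor applied to the vessel distance before inverting, so proximity = 1/d
#: stays finite at contact (half a voxel on the reference 1 mm grid).
PROXIMITY_EPS_MM = 0.5
#: Tumor boundary voxels within this distance of the pleura count as contact.
CONTACT_THRESHOLD_MM = 1.0
#: Adhesion components within this distance of the tumor count as contiguous.
ADHESION_CONTIGUITY_MM = 2.0

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def _distance_to_mask(mask: np.ndarray, spacing) -> np.ndarray:
    """Euclidean distance (mm) from every voxel center to the nearest voxel
    center of ``mask`` (exact, via the sampled distance transform)."""
    return ndimage.distance_transform_edt(~mask, sampling=spacing)


def min_surface_distance(mask_a: np.ndarray, mask_b: np.ndarray, spacing) -> float:
    """Minimum Euclidean distance between any voxel center of A and of B.

    Returns 0.0 when the masks overlap. Equal to the brute-force all-pairs
    minimum: the distance transform is exact on the sampled grid.
    """
    if not mask_a.any():
        raise ValueError("mask A is empty")
    if not mask_b.any():
        raise ValueError("mask B is empty")
    d_to_b = _distance_to_mask(mask_b, spacing)
    return float(d_to_b[mask_a].min())


def _boundary_voxels(mask: np.ndarray) -> np.ndarray:
    interior = ndimage.binary_erosion(mask, structure=_FACE_STRUCT, border_value=0)
    return mask & ~interior


def pleural_contact_area(
    tumor: np.ndarray,
    pleura: np.ndarray,
    spacing,
    contact_mm: float = CONTACT_THRESHOLD_MM,
) -> float:
    """Contact area (mm^2): tumor boundary voxels within ``contact_mm`` of the
    pleura, times the voxel face area."""
    if not tumor.any():
        raise ValueError("tumor mask is empty")
    if not pleura.any():
        return 0.0
    boundary = _boundary_voxels(tumor)
    dist = _distance_to_mask(pleura, spacing)
    n_contact = int(np.count_nonzero(dist[boundary] <= contact_mm))
    face_area = spacing[0] * spacing[1]
    return n_contact * face_area


def vessel_concepts(
    tumor: np.ndarray,
    vessel_mask: np.ndarray,
    caliber_map: np.ndarray | None,
    spacing,
    min_caliber_mm: float = MIN_VESSEL_CALIBER_MM,
    eps_mm: float = PROXIMITY_EPS_MM,
) -> tuple[float, float, float]:
    """(min distance, proximity, nearest caliber) against vessels >= 2 mm.

    With no qualifying vessel in the volume the distance is ``inf``, the
    proximity 0 and the caliber ``nan`` (undefined marker). Proximity is
    1/max(distance, eps). Caliber ties at the minimum distance resolve to the
    largest caliber.
    """
    if not tumor.any():
        raise ValueError("tumor mask is empty")
    if caliber_map is None:
        caliber_map = np.where(vessel_mask, 0.0, 0.0)
    qualifying = vessel_mask & (caliber_map >= min_caliber_mm)
    if not qualifying.any():
        return math.inf, 0.0, math.nan
    dist = _distance_to_mask(qualifying, spacing)
    tumor_idx = np.argwhere(tumor)
    d_at_tumor = dist[tumor]
    i_min = int(np.argmin(d_at_tumor))
    d_min = float(d_at_tumor[i_min])
    # caliber at the argmin vessel voxel; ties -> largest caliber
    p = tumor_idx[i_min] * np.asarray(spacing)
    q_idx = np.argwhere(qualifying)
    q_mm = q_idx * np.asarray(spacing)
    dq = np.linalg.norm(q_mm - p, axis=1)
    at_min = dq <= dq.min() + 1e-9
    caliber = float(caliber_map[tuple(q_idx[at_min].T)].max())
    proximity = 1.0 / max(d_min, eps_mm)
    return d_min, proximity, caliber


def shape_descriptors(tumor: np.ndarray, spacing) -> tuple[float, float, float, float]:
    """(volume mm^3, surface area mm^2, sphericity, elongation).

    Surface area is boundary-face counting; sphericity is
    pi^(1/3) (6V)^(2/3) / A; elongation is sqrt(lambda_2 / lambda_1) of the
    voxel-coordinate covariance (second over first principal axis length),
    defined as 1 for a single voxel.
    """
    if not tumor.any():
        raise ValueError("tumor mask is empty")
    sx, sy, sz = spacing
    voxel_vol = sx * sy * sz
    volume = float(tumor.sum()) * voxel_vol

    area = 0.0
    face_areas = (sy * sz, sx * sz, sx * sy)
    t = tumor.astype(np.int8)
    for axis, fa in enumerate(face_areas):
        d = np.diff(t, axis=axis)
        n_faces = int(np.abs(d).sum())
        # faces at the array border
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = 0
        sl_hi[axis] = -1
        n_faces += int(t[tuple(sl_lo)].sum()) + int(t[tuple(sl_hi)].sum())
        area += n_faces * fa

    sphericity = (math.pi ** (1 / 3)) * (6.0 * volume) ** (2 / 3) / area

    coords = np.argwhere(tumor) * np.asarray(spacing)
    if coords.shape[0] < 2:
        elongation = 1.0
    else:
        cov = np.cov(coords.T)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
        elongation = float(math.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
    return volume, area, sphericity, elongation


def adhesion_concepts(
    vol: LabelVolume,
    contiguity_mm: float = ADHESION_CONTIGUITY_MM,
) -> tuple[bool, float]:
    """(adhesion present anywhere, adhesion area contiguous with tumor, mm^2).

    "Contiguous" adhesion components lie within ``contiguity_mm`` of the tumor
    surface. Area is component voxel count times voxel face area (the patch is
    a shell of roughly one-voxel thickness).
    """
    adhesion = vol.mask(ADHESION)
    present = bool(adhesion.any())
    if not present:
        return False, 0.0
    tumor = vol.mask(TUMOR)
    comps, n = ndimage.label(adhesion, structure=ndimage.generate_binary_structure(3, 3))
    d_to_tumor = _distance_to_mask(tumor, vol.spacing)
    area = 0.0
    face_area = vol.spacing[0] * vol.spacing[1]
    for i in range(1, n + 1):
        comp = comps == i
        if float(d_to_tumor[comp].min()) <= contiguity_mm:
            area += float(comp.sum()) * face_area
    return present, area


def extract_concepts(
    vol: LabelVolume,
    contact_mm: float = CONTACT_THRESHOLD_MM,
    contiguity_mm: float = ADHESION_CONTIGUITY_MM,
) -> dict[str, float]:
    """Assemble the full per-case ConceptVector as an ordered dict."""
    missing = [name for lbl, name in ((TUMOR, "tumor"), (PLEURA, "pleura")) if not vol.mask(lbl).any()]
    if missing:
        raise ValueError(f"missing required labels: {', '.join(missing)}")
    tumor = vol.mask(TUMOR)
    pleura = vol.mask(PLEURA)
    vessel = vol.mask(VESSEL)

    volume, area, sphericity, elongation = shape_descriptors(tumor, vol.spacing)
    d_pleura = min_surface_distance(tumor, pleura, vol.spacing)
    contact = pleural_contact_area(tumor, pleura, vol.spacing, contact_mm)
    d_vessel, proximity, caliber = vessel_concepts(tumor, vessel, vol.caliber, vol.spacing)
    present, adh_area = adhesion_concepts(vol, contiguity_mm)

    return {
        "tumor_volume_mm3": volume,
        "tumor_surface_area_mm2": area,
        "sphericity": sphericity,
        "elongation": elongation,
        "min_pleura_distance_mm": d_pleura,
        "pleural_contact_area_mm2": contact,
        "vessel_min_distance_mm": d_vessel,
        "vessel_proximity_per_mm": proximity,
        "nearest_vessel_caliber_mm": caliber,
        "adhesion_present": float(present),
        "adhesion_area_mm2": adh_area,
        "log_adhesion_area": math.log1p(adh_area),
    }


@dataclass
class ZScorer:
    """Train-fit / test-apply per-concept standardization.

    Means and SDs are estimated on the training split only; constant columns
    (SD == 0) are flagged and passed through untransformed.
    """

    columns: list[str] = field(default_factory=list)
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    constant_columns: list[str] = field(default_factory=list)
    fitted: bool = False

    def fit(self, table: pd.DataFrame, columns: list[str] | None = None) -> "ZScorer":
        if len(table) == 0:
            raise ValueError("cannot fit a ZScorer on an empty table")
        self.columns = list(columns) if columns is not None else [
            c for c in CONCEPT_COLUMNS if c in table.columns
        ]
        self.means, self.sds, self.constant_columns = {}, {}, []
        for c in self.columns:
            vals = table[c].to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            m = float(finite.mean()) if finite.size else 0.0
            s = float(finite.std(ddof=0)) if finite.size else 0.0
            self.means[c] = m
            self.sds[c] = s
            if s <= 1e-12 * max(1.0, abs(m)):
                self.constant_columns.append(c)
        self.fitted = True
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if not self.fitted:
            raise RuntimeError("ZScorer.transform called before fit")
        out = table.copy()
        for c in self.columns:
            if c in self.constant_columns:
                continue  # flagged passthrough
            out[c] = (table[c].to_numpy(dtype=float) - self.means[c]) / self.sds[c]
        return out

    def transform_row(self, concepts: dict[str, float]) -> dict[str, float]:
        if not self.fitted:
            raise RuntimeError("ZScorer.transform_row called before fit")
        out = dict(concepts)
        for c in self.columns:
            if c in self.constant_columns or c not in concepts:
                continue
            out[c] = (float(concepts[c]) - self.means[c]) / self.sds[c]
        return out

    def to_dict(self) -> dict:
        return {
            "columns": self.columns,
            "means": self.means,
            "sds": self.sds,
            "constant_columns": self.constant_columns,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ZScorer":
        z = cls(
            columns=list(d["columns"]),
            means=dict(d["means"]),
            sds=dict(d["sds"]),
            constant_columns=list(d["constant_columns"]),
        )
        z.fitted = True
        return z


def zscore_fit(train_table: pd.DataFrame, columns: list[str] | None = None) -> ZScorer:
    return ZScorer().fit(train_table, columns)


def zscore_apply(scorer: ZScorer, table: pd.DataFrame) -> pd.DataFrame:
    return scorer.transform(table)
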