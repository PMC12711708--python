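"""Controlled counterfactual edits of fixed label volumes.

Three geometric edit operators probe a frozen risk model's directional
response: receding the tumor from the pleura by a target distance (signed-
distance level-set carving), growing the tumor toward the nearest major
vessel, and inserting/removing a pleural adhesion patch adjacent to the
tumor. Every edit certifies the *achieved* geometric change against the
target and records validity with explicit reasons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import concepts as cx
from .volumes import ADHESION, BODY, LUNG, LabelVolume, PLEURA, TUMOR, VESSEL

#: |achieved - target| tolerance for a valid edit (one voxel at 1 mm grids).
EDIT_TOLERANCE_MM = 1.0
#: Residual tumor-vessel distance is never pushed below this floor.
VESSEL_FLOOR_MM = 0.5

_STRUCT6 = ndimage.generate_binary_structure(3, 1)
_STRUCT26 = ndimage.generate_binary_structure(3, 3)


@dataclass
class EditResult:
    edit_kind: str
    target_delta_mm: float | None
    achieved_delta_mm: float | None
    valid: bool
    reasons: list[str] = field(default_factory=list)
    volume: LabelVolume | None = None
    mode: str | None = None  # adhesion toggles: "add" | "remove"

    def to_dict(self) -> dict:
        return {
            "edit_kind": self.edit_kind,
            "mode": self.mode,
            "target_delta_mm": self.target_delta_mm,
            "achieved_delta_mm": self.achieved_delta_mm,
            "valid": self.valid,
            "reasons": list(self.reasons),
        }


def signed_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """Signed distance (mm) to the mask boundary: negative inside, positive
    outside. Computed as (outside distance transform) - (inside distance
    transform) on voxel centers."""
    if not mask.any():
        raise ValueError("mask is empty")
    d_out = ndimage.distance_transform_edt(~mask, sampling=spacing)
    d_in = ndimage.distance_transform_edt(mask, sampling=spacing)
    return d_out - d_in


def _largest_component(mask: np.ndarray) -> np.ndarray:
    comps, n = ndimage.label(mask, structure=_STRUCT26)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(comps), comps, index=np.arange(1, n + 1))
    return comps == (int(np.argmax(sizes)) + 1)


def edit_pleura_distance(vol: LabelVolume, delta_mm: float = 5.0) -> EditResult:
    """Increase the minimum tumor-pleura distance by ``delta_mm``.

    The tumor surface recedes along pleural normals: tumor voxels closer to
    the pleura than (current minimum + delta) are relabeled lung, which is the
    level-set realization of "+delta mm along surface normals". Carving (not
    translating) keeps the tumor's vessel relations untouched. Negative deltas
    are not supported by this operator (grow toward structures with the
    vessel-style approach edit instead).
    """
    if delta_mm < 0:
        raise ValueError(
            "negative delta not supported: use edit_vessel_proximity-style approach edits"
        )
    tumor = vol.mask(TUMOR)
    pleura = vol.mask(PLEURA)
    if not tumor.any() or not pleura.any():
        raise ValueError("tumor and pleura labels are both required")

    d_pleura = ndimage.distance_transform_edt(~pleura, sampling=vol.spacing)
    d0 = float(d_pleura[tumor].min())
    if delta_mm == 0:
        return EditResult("pleura_distance", 0.0, 0.0, True, volume=vol.copy())

    target = d0 + delta_mm
    new_tumor = tumor & (d_pleura >= target)
    reasons: list[str] = []
    if not new_tumor.any():
        out = vol.copy()
        return EditResult(
            "pleura_distance", delta_mm, None, False, ["tumor emptied by edit"], out
        )
    new_tumor = _largest_component(new_tumor)

    vol_loss = 1.0 - new_tumor.sum() / tumor.sum()
    if vol_loss > 0.5:
        reasons.append(f"volume loss {vol_loss:.0%} exceeds 50%")

    labels = vol.labels.copy()
    labels[tumor & ~new_tumor] = LUNG
    out = LabelVolume(labels=labels, spacing=vol.spacing, caliber=vol.caliber, origin=vol.origin)

    d1 = float(d_pleura[new_tumor].min())
    achieved = d1 - d0
    if abs(d1 - target) > EDIT_TOLERANCE_MM:
        reasons.append(f"achieved distance {d1:.2f} mm misses target {target:.2f} mm")
    return EditResult("pleura_distance", delta_mm, achieved, not reasons, reasons, out)


def _segment_distance(points_mm: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(points_mm - a, axis=-1)
    t = np.clip(((points_mm - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t[..., None] * ab
    return np.linalg.norm(points_mm - proj, axis=-1)


def edit_vessel_proximity(
    vol: LabelVolume,
    delta_mm: float = -3.0,
    cylinder_radius_mm: float = 2.0,
    min_caliber_mm: float = cx.MIN_VESSEL_CALIBER_MM,
) -> EditResult:
    """Reduce the tumor-vessel distance by |delta| (delta is negative).

    The tumor grows along a cylinder (default radius 2 mm) between its closest
    surface point and the nearest qualifying (>= 2 mm caliber) vessel point,
    claiming non-vessel voxels whose residual vessel distance stays at or above
    the target; the residual distance is floored at 0.5 mm so tumor and vessel
    never overlap.
    """
    tumor = vol.mask(TUMOR)
    vessel = vol.mask(VESSEL)
    if not tumor.any():
        raise ValueError("tumor label is required")
    caliber = vol.caliber if vol.caliber is not None else np.zeros(vol.shape, np.float32)
    qualifying = vessel & (caliber >= min_caliber_mm)
    if not qualifying.any():
        raise ValueError("no qualifying vessel (caliber >= 2 mm) in the volume")
    if delta_mm > 0:
        raise ValueError("positive delta not supported: this operator approaches the vessel")

    sp = np.asarray(vol.spacing)
    d_vessel, idx = ndimage.distance_transform_edt(
        ~qualifying, sampling=vol.spacing, return_indices=True
    )
    d_at_tumor = d_vessel[tumor]
    d0 = float(d_at_tumor.min())
    if delta_mm == 0:
        return EditResult("vessel_proximity", 0.0, 0.0, True, volume=vol.copy())

    tumor_idx = np.argwhere(tumor)
    p_t = tumor_idx[int(np.argmin(d_at_tumor))]
    p_v = idx[:, p_t[0], p_t[1], p_t[2]]

    reasons: list[str] = []
    target = d0 + delta_mm
    if target < VESSEL_FLOOR_MM:
        reasons.append(f"floor reached: target {target:.2f} mm below {VESSEL_FLOOR_MM} mm")
        target = VESSEL_FLOOR_MM

    # voxels inside the connecting cylinder, off the vessel, not closer than target
    lo = np.maximum(np.minimum(p_t, p_v) - int(math.ceil(cylinder_radius_mm / sp.min())) - 2, 0)
    hi = np.minimum(
        np.maximum(p_t, p_v) + int(math.ceil(cylinder_radius_mm / sp.min())) + 3, vol.shape
    )
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    box_idx = np.stack(
        np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij"), axis=-1
    )
    box_mm = box_idx * sp
    d_axis = _segment_distance(box_mm, p_t * sp, p_v * sp)
    grow_box = (
        (d_axis <= cylinder_radius_mm)
        & (d_vessel[sl] >= target)
        & ~vessel[sl]
        & ~vol.mask(PLEURA)[sl]
    )
    grow = np.zeros(vol.shape, dtype=bool)
    grow[sl] = grow_box
    new_tumor = tumor | grow
    new_tumor = _largest_component(new_tumor)  # keep only growth connected to tumor

    labels = vol.labels.copy()
    labels[new_tumor] = TUMOR
    out = LabelVolume(labels=labels, spacing=vol.spacing, caliber=vol.caliber, origin=vol.origin)

    d1 = float(d_vessel[new_tumor].min())
    achieved = d1 - d0
    if abs(d1 - target) > EDIT_TOLERANCE_MM:
        reasons.append(f"achieved distance {d1:.2f} mm misses target {target:.2f} mm")
    return EditResult("vessel_proximity", delta_mm, achieved, not reasons, reasons, out)


def toggle_adhesion(
    vol: LabelVolume,
    mode: str,
    patch_radius_mm: float = 3.0,
    contiguity_mm: float = cx.ADHESION_CONTIGUITY_MM,
) -> EditResult:
    """Insert or remove an adhesion patch adjacent to the tumor.

    ``add``: a spherical-cap patch (radius 3 mm) is centered at the pleural
    point nearest the tumor; if the tumor is too far from the pleura for the
    patch to count as contiguous, the edit is flagged invalid (the concept it
    is meant to move cannot move). ``remove``: the adhesion component nearest
    the tumor is relabeled back to pleura/lung/body according to the lung
    geometry, so an add followed by a remove restores the original volume.
    """
    if mode not in ("add", "remove"):
        raise ValueError(f"unknown adhesion toggle mode '{mode}'")
    tumor = vol.mask(TUMOR)
    if not tumor.any():
        raise ValueError("tumor label is required")
    sp = np.asarray(vol.spacing)

    if mode == "add":
        pleura = vol.mask(PLEURA)
        if not pleura.any():
            raise ValueError("pleura label is required to add an adhesion")
        d_tumor = ndimage.distance_transform_edt(~tumor, sampling=vol.spacing)
        pl_idx = np.argwhere(pleura)
        anchor = pl_idx[int(np.argmin(d_tumor[pleura]))]
        # shell plus one voxel outward, never into the lung interior: remove-mode
        # can then always reconstruct the anatomy beneath the patch
        shell_band = ndimage.binary_dilation(pleura, structure=_STRUCT26) & ~vol.mask(LUNG)
        coords = np.argwhere(shell_band) * sp
        ball = np.linalg.norm(coords - anchor * sp, axis=1) <= patch_radius_mm
        patch = np.zeros(vol.shape, dtype=bool)
        patch[tuple((np.argwhere(shell_band)[ball]).T)] = True
        patch &= ~tumor & ~vol.mask(VESSEL)
        labels = vol.labels.copy()
        labels[patch] = ADHESION
        out = LabelVolume(labels=labels, spacing=vol.spacing, caliber=vol.caliber, origin=vol.origin)
        reasons: list[str] = []
        if not patch.any():
            reasons.append("patch rendered empty")
        elif float(d_tumor[patch].min()) > contiguity_mm:
            reasons.append("patch not contiguous with tumor")
        return EditResult("adhesion_toggle", None, None, not reasons, reasons, out, mode="add")

    adhesion = vol.mask(ADHESION)
    if not adhesion.any():
        raise ValueError("no adhesion component to remove")
    comps, n = ndimage.label(adhesion, structure=_STRUCT26)
    d_tumor = ndimage.distance_transform_edt(~tumor, sampling=vol.spacing)
    dists = [float(d_tumor[comps == i].min()) for i in range(1, n + 1)]
    nearest = comps == (int(np.argmin(dists)) + 1)

    # reconstruct the underlying anatomy: lung interior, its pleural shell, body
    interior = np.isin(vol.labels, (LUNG, TUMOR, VESSEL))
    interior = ndimage.binary_fill_holes(interior)
    shell = ndimage.binary_dilation(interior, structure=_STRUCT6) & ~interior
    labels = vol.labels.copy()
    labels[nearest & shell] = PLEURA
    labels[nearest & interior] = LUNG
    labels[nearest & ~shell & ~interior] = BODY
    out = LabelVolume(labels=labels, spacing=vol.spacing, caliber=vol.caliber, origin=vol.origin)
    return EditResult("adhesion_toggle", None, None, True, [], out, mode="remove")
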