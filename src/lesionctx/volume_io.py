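"""Preprocessing for thoracic CT volumes.

Defaults reproduce a standard ablation-planning pipeline: resampling to 1 mm
isotropic voxels (trilinear for intensities, nearest-neighbor for labels), HU
clipping to [-1000, 400] rescaled to [0, 1], lung extraction by HU < -500
thresholding plus morphological cleanup, and train-time augmentation (rotation
+/-15 deg, elastic deformation alpha=100 sigma=10, Gaussian noise sd 0.05,
intensity scaling 0.9-1.1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import LabelVolume, Volume

HU_CLIP_RANGE = (-1000.0, 400.0)
LUNG_HU_THRESHOLD = -500.0


def resample_isotropic(vol: Volume, target_mm: float = 1.0) -> Volume:
    """Resample to isotropic spacing, preserving physical extent.

    Trilinear interpolation for intensities, nearest-neighbor for labels.
    """
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    factors = tuple(s / target_mm for s in vol.spacing)
    if all(abs(f - 1.0) < 1e-12 for f in factors):
        return vol.copy()
    order = 0 if vol.kind == "label" else 1
    new_shape = tuple(max(int(round(n * f)), 1) for n, f in zip(vol.shape, factors))
    zoom = tuple(ns / n for ns, n in zip(new_shape, vol.shape))
    data = ndimage.zoom(vol.data, zoom, order=order, mode="nearest", grid_mode=True)
    if vol.kind == "label":
        data = np.rint(data).astype(vol.data.dtype)
    return Volume(data=data, spacing=(target_mm,) * 3, origin=vol.origin, kind=vol.kind)


def normalize_hu(vol: Volume, clip_range: tuple[float, float] = HU_CLIP_RANGE) -> Volume:
    """Clip HU to ``clip_range`` and rescale affinely to [0, 1]."""
    if vol.kind == "label":
        raise ValueError("cannot HU-normalize a label volume")
    lo, hi = clip_range
    data = (np.clip(vol.data.astype(np.float64), lo, hi) - lo) / (hi - lo)
    return Volume(data=data, spacing=vol.spacing, origin=vol.origin, kind="normalized")


def extract_lung_mask(
    vol: Volume,
    threshold_hu: float = LUNG_HU_THRESHOLD,
    min_component_fraction: float = 0.1,
) -> LabelVolume:
    """Segment the lung by strict HU < threshold plus morphological cleanup.

    Border-touching air components are removed (outside air), the mask is
    morphologically closed, and only interior components at least
    ``min_component_fraction`` of the largest are kept (both lungs survive,
    small airway/vessel fragments do not). An all-body input yields an empty
    mask rather than an error.
    """
    if vol.kind != "hu":
        raise ValueError("lung extraction expects an HU volume")
    air = vol.data < threshold_hu  # strict: exactly -500 is excluded
    if not air.any():
        return LabelVolume(labels=np.zeros(vol.shape, dtype=np.int16), spacing=vol.spacing)

    comps, n = ndimage.label(air)
    if n:
        border = np.zeros(vol.shape, dtype=bool)
        border[[0, -1], :, :] = border[:, [0, -1], :] = border[:, :, [0, -1]] = True
        for lbl in np.unique(comps[border]):
            if lbl != 0:
                air[comps == lbl] = False

    air = ndimage.binary_closing(air, structure=ndimage.generate_binary_structure(3, 1))
    comps, n = ndimage.label(air)
    mask = np.zeros(vol.shape, dtype=bool)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(comps), comps, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_component_fraction * sizes.max()) + 1
        mask = np.isin(comps, keep)
    return LabelVolume(labels=mask.astype(np.int16), spacing=vol.spacing)


@dataclass
class AugmentParams:
    """Train-time augmentation configuration (all stages can be disabled)."""

    rotate: bool = True
    max_rotation_deg: float = 15.0
    elastic: bool = True
    elastic_alpha: float = 100.0  # displacement amplitude, voxel units
    elastic_sigma: float = 10.0  # Gaussian smoothing of the field, voxels
    noise: bool = True
    noise_sd: float = 0.05
    intensity_scale: bool = True
    scale_range: tuple[float, float] = (0.9, 1.1)


def rotate_axial(
    vol: Volume | None, labels: LabelVolume | None, theta_deg: float
) -> tuple[Volume | None, LabelVolume | None]:
    """In-plane axial rotation by a recorded angle (for invertibility checks)."""
    out_vol = None
    if vol is not None:
        data = ndimage.rotate(
            vol.data.astype(np.float64), theta_deg, axes=(0, 1), reshape=False, order=1, mode="nearest"
        )
        out_vol = Volume(data=data, spacing=vol.spacing, origin=vol.origin, kind=vol.kind)
    out_lab = None
    if labels is not None:
        lab = ndimage.rotate(labels.labels, theta_deg, axes=(0, 1), reshape=False, order=0, mode="nearest")
        out_lab = LabelVolume(labels=lab, spacing=labels.spacing, origin=labels.origin)
    return out_vol, out_lab


def _elastic_field(shape, alpha, sigma, rng):
    disp = []
    for _ in range(3):
        f = rng.uniform(-1, 1, size=shape)
        f = ndimage.gaussian_filter(f, sigma, mode="constant")
        disp.append(f * alpha)
    return disp


def augment(
    vol: Volume,
    labels: LabelVolume | None,
    params: AugmentParams | None = None,
    seed: int = 0,
) -> tuple[Volume, LabelVolume | None]:
    """Apply one random augmentation draw to an intensity volume and its labels.

    The identical spatial transform (axial rotation then elastic warp) is
    applied to both; intensities are interpolated trilinearly, labels
    nearest-neighbor. Noise and intensity scaling touch intensities only, and
    the result is re-clipped to [0, 1]. Reproducible given ``seed``.
    """
    params = params or AugmentParams()
    if labels is not None and labels.shape != vol.shape:
        raise ValueError("volume and label shapes differ")
    rng = np.random.default_rng(seed)
    data = vol.data.astype(np.float64)
    lab = None if labels is None else labels.labels

    if params.rotate:
        theta = rng.uniform(-params.max_rotation_deg, params.max_rotation_deg)
        data = ndimage.rotate(data, theta, axes=(0, 1), reshape=False, order=1, mode="nearest")
        if lab is not None:
            lab = ndimage.rotate(lab, theta, axes=(0, 1), reshape=False, order=0, mode="nearest")

    if params.elastic:
        disp = _elastic_field(vol.shape, params.elastic_alpha, params.elastic_sigma, rng)
        idx = np.meshgrid(*[np.arange(n) for n in vol.shape], indexing="ij")
        coords = [i + d for i, d in zip(idx, disp)]
        data = ndimage.map_coordinates(data, coords, order=1, mode="nearest")
        if lab is not None:
            lab = ndimage.map_coordinates(lab, coords, order=0, mode="nearest")

    if params.noise:
        data = data + rng.normal(0.0, params.noise_sd, size=vol.shape)
    if params.intensity_scale:
        data = data * rng.uniform(*params.scale_range)
    data = np.clip(data, 0.0, 1.0)

    out_vol = Volume(data=data, spacing=vol.spacing, origin=vol.origin, kind="normalized")
    out_lab = None
    if labels is not None:
        out_lab = LabelVolume(
            labels=lab.astype(labels.labels.dtype), spacing=labels.spacing, origin=labels.origin
        )
    return out_vol, out_lab
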