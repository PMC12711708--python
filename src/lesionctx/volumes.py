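"""Core volume containers and NIfTI round-tripping.

Arrays are indexed (x, y, z) in world-aligned order; coordinates are in mm,
voxel indices are 0-based, and voxel *centers* sit at ``index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

# Label ids, in increasing rendering precedence (later overwrites earlier).
BODY = 0
LUNG = 1
PLEURA = 2
ADHESION = 3
VESSEL = 4
TUMOR = 5

LABEL_NAMES = {
    BODY: "body",
    LUNG: "lung",
    PLEURA: "pleura",
    ADHESION: "adhesion",
    VESSEL: "vessel",
    TUMOR: "tumor",
}


@dataclass
class Volume:
    """A 3D scalar volume with physical metadata.

    ``kind`` records the value semantics: ``"hu"`` (Hounsfield units),
    ``"normalized"`` (intensities in [0, 1]) or ``"label"`` (integer ids).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kind: str = "hu"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.kind == "label" and not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volumes must hold integers")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "Volume":
        return replace(self, data=self.data.copy())


@dataclass
class LabelVolume:
    """Integer label grid plus spacing and an optional vessel-caliber map.

    ``caliber`` holds the vessel caliber in mm at vessel voxels (0 elsewhere);
    it is the substrate for the "vessels >= 2 mm" gate in concept extraction.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    caliber: np.ndarray | None = None
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3D label array, got {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.caliber is not None and self.caliber.shape != self.labels.shape:
            raise ValueError("caliber map shape must match labels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def copy(self) -> "LabelVolume":
        return LabelVolume(
            labels=self.labels.copy(),
            spacing=self.spacing,
            caliber=None if self.caliber is None else self.caliber.copy(),
            origin=self.origin,
        )


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def save_nifti(vol: Volume | LabelVolume, path) -> None:
    """Write a volume as NIfTI (int16 for labels, float32 otherwise)."""
    if isinstance(vol, LabelVolume):
        data = vol.labels.astype(np.int16)
    elif vol.kind == "label":
        data = vol.data.astype(np.int16)
    else:
        data = vol.data.astype(np.float32)
    img = nib.Nifti1Image(data, _affine(vol.spacing, vol.origin))
    nib.save(img, str(path))


def load_volume(path, kind: str = "hu") -> Volume:
    """Read a NIfTI file; spacing is taken from the header zooms."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    if kind == "label":
        data = np.rint(np.asarray(data)).astype(np.int16)
    return Volume(data=data, spacing=spacing, origin=origin, kind=kind)


def load_label_volume(path, caliber_path=None) -> LabelVolume:
    vol = load_volume(path, kind="label")
    caliber = None
    if caliber_path is not None:
        caliber = np.asarray(load_volume(caliber_path, kind="hu").data, dtype=np.float32)
    return LabelVolume(labels=vol.data, spacing=vol.spacing, caliber=caliber, origin=vol.origin)
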