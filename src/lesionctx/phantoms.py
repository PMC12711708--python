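"""Synthetic thorax-like phantoms and cohorts with planted concept-risk structure.

A phantom is a spherical "lung" inside soft-tissue "body", a one-voxel pleural
shell at the lung boundary, an ellipsoidal tumor placed so that the minimum
tumor-pleura distance hits a requested target, tubular vessels with a known
caliber, and optional adhesion patches on the pleura. A logistic surrogate risk
model with planted coefficient signs (shorter pleural distance -> more
pneumothorax, higher vascular proximity -> more hemorrhage, more adhesion ->
more pleural reaction) provides a fully known ground truth for auditing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from . import concepts as cx
from .volumes import ADHESION, BODY, LUNG, LabelVolume, PLEURA, TUMOR, VESSEL, Volume

RISK_NAMES = ("pneumothorax", "hemorrhage", "pleural_reaction")

#: Concepts entering the surrogate linear predictor (z-scored).
SURROGATE_CONCEPTS = (
    "min_pleura_distance_mm",
    "vessel_proximity_per_mm",
    "log_adhesion_area",
    "tumor_volume_mm3",
)

_STRUCT6 = ndimage.generate_binary_structure(3, 1)
_STRUCT26 = ndimage.generate_binary_structure(3, 3)


class InfeasibleGeometryError(ValueError):
    """Raised when a requested phantom geometry cannot be rendered."""


@dataclass
class VesselSpec:
    points_mm: np.ndarray  # (k, 3) polyline control points
    caliber_mm: float

    def __post_init__(self) -> None:
        self.points_mm = np.atleast_2d(np.asarray(self.points_mm, dtype=float))
        if self.caliber_mm <= 0:
            raise ValueError("vessel caliber must be positive")


@dataclass
class AdhesionSpec:
    anchor_mm: tuple[float, float, float]
    radius_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("adhesion radius must be positive")


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: float = 1.0
    lung_center_mm: tuple[float, float, float] | None = None
    lung_radius_mm: float = 20.0
    tumor_center_mm: tuple[float, float, float] | None = None
    tumor_radii_mm: tuple[float, float, float] = (7.0, 7.0, 7.0)
    target_pleura_distance_mm: float | None = 8.0
    vessel_specs: list[VesselSpec] = field(default_factory=list)
    adhesion_specs: list[AdhesionSpec] = field(default_factory=list)
    lung_hu: float = -800.0
    body_hu: float = 50.0
    tumor_hu: float = 30.0
    vessel_hu: float = 60.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.tumor_radii_mm):
            raise ValueError("tumor radii must be positive")
        if self.target_pleura_distance_mm is not None and self.target_pleura_distance_mm < 0:
            raise ValueError("target pleura distance must be >= 0")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.spacing_mm,) * 3

    def resolved_lung_center(self) -> np.ndarray:
        if self.lung_center_mm is not None:
            return np.asarray(self.lung_center_mm, dtype=float)
        return (np.asarray(self.grid_shape, dtype=float) - 1) / 2.0 * self.spacing_mm

    def resolved_tumor_center(self) -> np.ndarray:
        """Tumor center, derived from the target pleural distance when not given.

        The tumor is placed along +x from the lung center at an offset such
        that its analytic surface sits ``target`` mm inside the lung boundary.
        """
        if self.tumor_center_mm is not None:
            return np.asarray(self.tumor_center_mm, dtype=float)
        if self.target_pleura_distance_mm is None:
            raise ValueError("either tumor_center_mm or target_pleura_distance_mm is required")
        lc = self.resolved_lung_center()
        # +0.5 voxel calibration: tumor voxel centers sit inside the analytic
        # surface and pleural voxel centers outside the lung boundary, which
        # biases the measured distance up by about half a voxel on each side.
        offset = (
            self.lung_radius_mm
            - self.tumor_radii_mm[0]
            - self.target_pleura_distance_mm
            + 0.5 * self.spacing_mm
        )
        if offset < 0:
            raise InfeasibleGeometryError(
                f"target pleural distance {self.target_pleura_distance_mm} mm with tumor radius "
                f"{self.tumor_radii_mm[0]} mm does not fit in a {self.lung_radius_mm} mm lung"
            )
        return lc + np.array([offset, 0.0, 0.0])


def _voxel_coords(shape, spacing_mm):
    ax = [np.arange(n) * spacing_mm for n in shape]
    return np.meshgrid(*ax, indexing="ij", sparse=True)


def _ellipsoid_mask(shape, spacing_mm, center, radii):
    X, Y, Z = _voxel_coords(shape, spacing_mm)
    return (
        ((X - center[0]) / radii[0]) ** 2
        + ((Y - center[1]) / radii[1]) ** 2
        + ((Z - center[2]) / radii[2]) ** 2
    ) <= 1.0


def generate_phantom(spec: PhantomSpec, with_intensity: bool = True):
    """Render a PhantomSpec to a LabelVolume (+ optional HU intensity Volume).

    Labels are mutually exclusive with precedence
    tumor > vessel > adhesion > pleura > lung > body. The pleura is the
    one-voxel shell just outside the lung; adhesion patches are ball
    intersections with the (1-voxel-dilated) pleural shell; vessels are tubes
    of constant caliber around spline/polyline paths, clipped to the lung.
    Deterministic given ``spec.seed``.
    """
    shape = tuple(spec.grid_shape)
    sp = spec.spacing_mm
    lc = spec.resolved_lung_center()
    tc = spec.resolved_tumor_center()

    lung = _ellipsoid_mask(shape, sp, lc, (spec.lung_radius_mm,) * 3)
    # lung plus shell must sit strictly inside the grid (2-voxel margin)
    extent = (np.asarray(shape) - 1) * sp
    if np.any(lc - spec.lung_radius_mm < 2 * sp) or np.any(lc + spec.lung_radius_mm > extent - 2 * sp):
        raise InfeasibleGeometryError("lung (plus pleural shell) does not fit inside the grid")

    tumor = _ellipsoid_mask(shape, sp, tc, spec.tumor_radii_mm)
    if not tumor.any():
        raise InfeasibleGeometryError("tumor renders to an empty mask")
    if (tumor & ~lung).any():
        raise InfeasibleGeometryError("tumor breaches the lung boundary")

    pleura = ndimage.binary_dilation(lung, structure=_STRUCT6) & ~lung

    adhesion = np.zeros(shape, dtype=bool)
    if spec.adhesion_specs:
        # shell plus one voxel outward; never into the lung interior, so that
        # removing an adhesion can always reconstruct the anatomy beneath it
        shell_band = ndimage.binary_dilation(pleura, structure=_STRUCT26) & ~lung
        for a in spec.adhesion_specs:
            ball = _ellipsoid_mask(shape, sp, np.asarray(a.anchor_mm, float), (a.radius_mm,) * 3)
            adhesion |= ball & shell_band

    vessel = np.zeros(shape, dtype=bool)
    caliber = np.zeros(shape, dtype=np.float32)
    if spec.vessel_specs:
        grid_pts = np.argwhere(lung) * sp
        for v in spec.vessel_specs:
            pts = v.points_mm
            if len(pts) > 1:
                seglens = np.linalg.norm(np.diff(pts, axis=0), axis=1)
                dense = [pts[0]]
                for p0, p1, L in zip(pts[:-1], pts[1:], seglens):
                    n = max(int(math.ceil(L / (0.25 * sp))), 1)
                    for t in np.linspace(0, 1, n + 1)[1:]:
                        dense.append(p0 * (1 - t) + p1 * t)
                dense = np.asarray(dense)
            else:
                dense = pts
            tree = cKDTree(dense)
            d, _ = tree.query(grid_pts)
            tube_pts = grid_pts[d <= v.caliber_mm / 2.0]
            idx = np.rint(tube_pts / sp).astype(int)
            tube = np.zeros(shape, dtype=bool)
            tube[tuple(idx.T)] = True
            vessel |= tube
            caliber[tube] = np.maximum(caliber[tube], v.caliber_mm)

    labels = np.full(shape, BODY, dtype=np.int16)
    labels[lung] = LUNG
    labels[pleura] = PLEURA
    labels[adhesion] = ADHESION
    labels[vessel] = VESSEL
    labels[tumor] = TUMOR
    caliber[labels != VESSEL] = 0.0

    vol = LabelVolume(labels=labels, spacing=(sp,) * 3, caliber=caliber)

    intensity = None
    if with_intensity:
        hu = np.full(shape, spec.body_hu, dtype=np.float32)
        hu[lung] = spec.lung_hu
        hu[labels == PLEURA] = spec.body_hu
        hu[labels == ADHESION] = spec.body_hu
        hu[labels == VESSEL] = spec.vessel_hu
        hu[labels == TUMOR] = spec.tumor_hu
        if spec.noise_sd > 0:
            rng = np.random.default_rng(spec.seed)
            hu = hu + rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)
        intensity = Volume(data=hu, spacing=(sp,) * 3, kind="hu")
    return vol, intensity


def standard_spec(
    pleura_distance_mm: float = 8.0,
    tumor_radius_mm: float = 7.0,
    vessel_distance_mm: float | None = 5.0,
    vessel_caliber_mm: float = 3.0,
    adhesion_radius_mm: float | None = None,
    grid_shape: tuple[int, int, int] = (48, 48, 48),
    spacing_mm: float = 1.0,
    lung_radius_mm: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PhantomSpec:
    """Build a canonical single-tumor spec with controllable concept geometry.

    The tumor sits along +x at the requested pleural distance; the vessel is a
    straight z-parallel tube on the -x side at the requested surface-to-surface
    distance; the adhesion patch (if any) anchors at the pleural point nearest
    the tumor, so it is contiguous exactly when the tumor is juxtapleural.
    """
    spec = PhantomSpec(
        grid_shape=grid_shape,
        spacing_mm=spacing_mm,
        lung_radius_mm=lung_radius_mm,
        tumor_radii_mm=(tumor_radius_mm,) * 3,
        target_pleura_distance_mm=pleura_distance_mm,
        noise_sd=noise_sd,
        seed=seed,
    )
    lc = spec.resolved_lung_center()
    tc = spec.resolved_tumor_center()
    nz = grid_shape[2]
    if vessel_distance_mm is not None:
        # one-voxel calibration: voxel-center shrinkage of both the tumor and the
        # tube surface biases the measured gap up by about half a voxel each
        xv = tc[0] - tumor_radius_mm - vessel_distance_mm - vessel_caliber_mm / 2.0 + 1.0 * spacing_mm
        if xv - vessel_caliber_mm / 2.0 < lc[0] - lung_radius_mm + spacing_mm:
            raise InfeasibleGeometryError(
                f"vessel at distance {vessel_distance_mm} mm falls outside the lung"
            )
        pts = np.array([[xv, lc[1], 0.0], [xv, lc[1], (nz - 1) * spacing_mm]])
        spec.vessel_specs = [VesselSpec(points_mm=pts, caliber_mm=vessel_caliber_mm)]
    if adhesion_radius_mm is not None:
        anchor = lc + np.array([lung_radius_mm + 0.5 * spacing_mm, 0.0, 0.0])
        spec.adhesion_specs = [AdhesionSpec(anchor_mm=tuple(anchor), radius_mm=adhesion_radius_mm)]
    return spec


# ---------------------------------------------------------------------------
# Surrogate risk model


@dataclass
class SurrogateRiskParams:
    """Logistic surrogate with planted concept-risk directions.

    Defaults plant the three clinical priors: shorter tumor-pleura distance ->
    higher pneumothorax risk (negative distance coefficient), higher vascular
    proximity -> higher hemorrhage risk, larger contiguous adhesion area ->
    higher pleural-reaction risk. Coefficients act on z-scored concepts.
    """

    intercepts: dict[str, float] = field(
        default_factory=lambda: {r: -0.5 for r in RISK_NAMES}
    )
    coefs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "pneumothorax": {"min_pleura_distance_mm": -2.0},
            "hemorrhage": {"vessel_proximity_per_mm": 2.0},
            "pleural_reaction": {"log_adhesion_area": 2.0},
        }
    )
    noise_sd: float = 0.0

    @property
    def planted_signs(self) -> dict[tuple[str, str], int]:
        signs = {}
        for risk, cc in self.coefs.items():
            for concept, coef in cc.items():
                if coef != 0:
                    signs[(concept, risk)] = 1 if coef > 0 else -1
        return signs


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def surrogate_risk(
    concepts_z: dict[str, float],
    params: SurrogateRiskParams,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Per-risk logistic(intercept + sum coef * z [+ noise])."""
    risks = {}
    for risk in RISK_NAMES:
        eta = params.intercepts.get(risk, 0.0)
        for concept, coef in params.coefs.get(risk, {}).items():
            if concept not in concepts_z:
                raise KeyError(f"missing concept '{concept}' required by surrogate risk '{risk}'")
            eta += coef * float(concepts_z[concept])
        if params.noise_sd > 0:
            if rng is None:
                raise ValueError("noise_sd > 0 requires an rng")
            eta += rng.normal(0.0, params.noise_sd)
        risks[risk] = _logistic(eta)
    return risks


class SurrogateRiskModel:
    """Frozen predict contract over label volumes, backed by the surrogate.

    ``predict`` re-extracts concepts from the (possibly edited) volume,
    z-scores them with the cohort's training-split statistics and applies the
    noise-free planted logistic — the known-truth stand-in for a trained
    network in audits.
    """

    def __init__(self, params: SurrogateRiskParams, zscorer: cx.ZScorer):
        self.params = params
        self.zscorer = zscorer

    def predict(self, vol: LabelVolume) -> dict[str, float]:
        concepts = cx.extract_concepts(vol)
        z = self.zscorer.transform_row(concepts)
        noise_free = replace(self.params, noise_sd=0.0)
        return surrogate_risk(z, noise_free)

    def predict_concepts(self, concepts: dict[str, float]) -> dict[str, float]:
        z = self.zscorer.transform_row(concepts)
        noise_free = replace(self.params, noise_sd=0.0)
        return surrogate_risk(z, noise_free)


# ---------------------------------------------------------------------------
# Cohort sampling


@dataclass
class SpecRanges:
    """Samplable intervals for phantom geometry and covariates."""

    tumor_radius_mm: tuple[float, float] = (5.0, 9.0)
    #: floor 0.5 mm keeps truly juxtapleural (contact-range) tumors in the mix
    pleura_distance_mm: tuple[float, float] = (0.5, 11.0)
    vessel_distance_mm: tuple[float, float] = (2.0, 8.0)
    vessel_caliber_mm: tuple[float, float] = (2.0, 4.0)
    adhesion_prob: float = 0.6
    adhesion_radius_mm: tuple[float, float] = (1.5, 5.0)
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: float = 1.0
    lung_radius_mm: float = 20.0
    noise_sd_hu: float = 0.0


@dataclass
class CaseRecord:
    case_id: str
    volume: LabelVolume
    intensity: Volume | None
    covariates: dict[str, object]
    concepts: dict[str, float]
    true_risks: dict[str, float]
    outcomes: dict[str, int]
    split: str = "train"


@dataclass
class Cohort:
    cases: list[CaseRecord]
    table: pd.DataFrame
    zscorer: cx.ZScorer  # fit on the training split
    risk_params: SurrogateRiskParams
    seed: int

    def model(self) -> SurrogateRiskModel:
        return SurrogateRiskModel(self.risk_params, self.zscorer)


_LOBES = ("RUL", "RML", "RLL", "LUL", "LLL")


def _sample_covariates(rng: np.random.Generator, tumor_radius_mm: float) -> dict[str, object]:
    diameter_cm = 2 * tumor_radius_mm / 10.0
    if diameter_cm < 2.0:
        size_class = "lt2cm"
    elif diameter_cm <= 3.0:
        size_class = "2to3cm"
    else:
        size_class = "gt3cm"
    return {
        "age": int(rng.integers(45, 86)),
        "sex": str(rng.choice(["M", "F"])),
        "copd": int(rng.random() < 0.3),
        "tumor_size_class": size_class,
        "lobe": str(rng.choice(_LOBES)),
        "scanner": str(rng.choice(["A", "B"])),
    }


def sample_cohort(
    n_cases: int,
    ranges: SpecRanges | None = None,
    risk_params: SurrogateRiskParams | None = None,
    seed: int = 0,
    keep_intensity: bool = False,
    max_retries: int = 20,
    train_fraction: float = 0.7,
) -> Cohort:
    """Sample a reproducible phantom cohort with planted concept-risk truth.

    Geometry is drawn within ``ranges``; concepts are extracted from the
    rendered volumes; true risks come from the surrogate applied to z-scored
    concepts; outcomes are Bernoulli draws; the train/test split is stratified
    on the joint outcome pattern.
    """
    if n_cases < 2:
        raise ValueError("n_cases must be >= 2")
    ranges = ranges or SpecRanges()
    risk_params = risk_params or SurrogateRiskParams()
    rng = np.random.default_rng(seed)

    cases: list[CaseRecord] = []
    for i in range(n_cases):
        spec = None
        last_err: Exception | None = None
        for _ in range(max_retries):
            r = float(rng.uniform(*ranges.tumor_radius_mm))
            d_hi = min(ranges.pleura_distance_mm[1], ranges.lung_radius_mm - r - 1.0)
            d = float(rng.uniform(ranges.pleura_distance_mm[0], d_hi))
            dv = float(rng.uniform(*ranges.vessel_distance_mm))
            cal = float(rng.uniform(*ranges.vessel_caliber_mm))
            adh = (
                float(rng.uniform(*ranges.adhesion_radius_mm))
                if rng.random() < ranges.adhesion_prob
                else None
            )
            try:
                spec = standard_spec(
                    pleura_distance_mm=d,
                    tumor_radius_mm=r,
                    vessel_distance_mm=dv,
                    vessel_caliber_mm=cal,
                    adhesion_radius_mm=adh,
                    grid_shape=ranges.grid_shape,
                    spacing_mm=ranges.spacing_mm,
                    lung_radius_mm=ranges.lung_radius_mm,
                    noise_sd=ranges.noise_sd_hu,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                vol, intensity = generate_phantom(spec, with_intensity=keep_intensity)
                break
            except InfeasibleGeometryError as e:  # resample and retry
                spec = None
                last_err = e
        if spec is None:
            raise InfeasibleGeometryError(
                f"no feasible phantom after {max_retries} retries: {last_err}"
            )
        concepts = cx.extract_concepts(vol)
        covariates = _sample_covariates(rng, r)
        cases.append(
            CaseRecord(
                case_id=f"case_{i:04d}",
                volume=vol,
                intensity=intensity,
                covariates=covariates,
                concepts=concepts,
                true_risks={},
                outcomes={},
            )
        )

    concept_table = pd.DataFrame([c.concepts for c in cases])
    # full-cohort z-scores define the generating risks (the train-split scorer
    # below serves all downstream train-fit/test-apply use)
    gen_scorer = cx.ZScorer().fit(concept_table, list(SURROGATE_CONCEPTS))
    for case in cases:
        z = gen_scorer.transform_row(case.concepts)
        case.true_risks = surrogate_risk(z, risk_params, rng=rng if risk_params.noise_sd > 0 else None)
        case.outcomes = {r: int(rng.random() < p) for r, p in case.true_risks.items()}

    # stratified split on the joint outcome pattern
    strata: dict[tuple, list[int]] = {}
    for i, case in enumerate(cases):
        strata.setdefault(tuple(case.outcomes[r] for r in RISK_NAMES), []).append(i)
    for members in strata.values():
        members = list(members)
        rng.shuffle(members)
        n_train = int(round(train_fraction * len(members)))
        for j, idx in enumerate(members):
            cases[idx].split = "train" if j < n_train else "test"

    rows = []
    for case in cases:
        row: dict[str, object] = {"case_id": case.case_id, "split": case.split}
        row.update(case.covariates)
        row.update(case.concepts)
        for r in RISK_NAMES:
            row[f"risk_{r}"] = case.true_risks[r]
            row[f"outcome_{r}"] = case.outcomes[r]
        rows.append(row)
    table = pd.DataFrame(rows)

    train_rows = table[table["split"] == "train"]
    zscorer = cx.ZScorer().fit(train_rows, [c for c in cx.CONCEPT_COLUMNS if c in table.columns])
    return Cohort(cases=cases, table=table, zscorer=zscorer, risk_params=risk_params, seed=seed)
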