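import math

import numpy as np
import pandas as pd
import pytest

from lesionctx import concepts as cx
from lesionctx import phantoms as ph
from lesionctx import volume_io as vio
from lesionctx.volumes import LabelVolume, PLEURA, TUMOR, Volume

from conftest import brute_force_min_distance


def _mask(shape, voxels):
    m = np.zeros(shape, dtype=bool)
    for v in voxels:
        m[v] = True
    return m


class TestMinSurfaceDistance:
    def test_single_voxel_pair(self):
        a = _mask((8, 8, 8), [(0, 0, 0)])
        b = _mask((8, 8, 8), [(3, 0, 0)])
        assert cx.min_surface_distance(a, b, (1.0,) * 3) == 3.0

    def test_overlap_is_zero(self):
        a = _mask((8, 8, 8), [(2, 2, 2), (3, 3, 3)])
        assert cx.min_surface_distance(a, a, (1.0,) * 3) == 0.0

    def test_spacing_scales_distance(self):
        a = _mask((8, 8, 8), [(0, 0, 0)])
        b = _mask((8, 8, 8), [(3, 0, 0)])
        assert cx.min_surface_distance(a, b, (2.0, 1.0, 1.0)) == 6.0

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((16, 16, 16)) < 0.03
        b = rng.random((16, 16, 16)) < 0.03
        if not (a.any() and b.any()):
            pytest.skip("degenerate draw")
        fast = cx.min_surface_distance(a, b, (1.0,) * 3)
        assert fast == pytest.approx(brute_force_min_distance(a, b, (1.0,) * 3), abs=1e-9)

    def test_empty_mask_error_names_side(self):
        a = _mask((4, 4, 4), [(0, 0, 0)])
        empty = np.zeros((4, 4, 4), dtype=bool)
        with pytest.raises(ValueError, match="mask B"):
            cx.min_surface_distance(a, empty, (1.0,) * 3)
        with pytest.raises(ValueError, match="mask A"):
            cx.min_surface_distance(empty, a, (1.0,) * 3)


class TestPleuralContactArea:
    def test_distant_tumor_has_zero_contact(self, default_phantom):
        _, vol, _ = default_phantom  # tumor ~8 mm from pleura
        assert cx.pleural_contact_area(vol.mask(TUMOR), vol.mask(PLEURA), vol.spacing) == 0.0

    def test_abutting_slab_counts_faces(self):
        shape = (12, 12, 12)
        tumor = np.zeros(shape, dtype=bool)
        tumor[4:8, 4:8, 4:6] = True  # 4x4 face toward the pleura plane
        pleura = np.zeros(shape, dtype=bool)
        pleura[4:8, 4:8, 6] = True
        area = cx.pleural_contact_area(tumor, pleura, (1.0,) * 3)
        assert area == 16.0

    def test_area_scales_with_spacing(self):
        shape = (12, 12, 12)
        tumor = np.zeros(shape, dtype=bool)
        tumor[4:8, 4:8, 4:6] = True
        pleura = np.zeros(shape, dtype=bool)
        pleura[4:8, 4:8, 6] = True
        a1 = cx.pleural_contact_area(tumor, pleura, (1.0,) * 3, contact_mm=2.0)
        a2 = cx.pleural_contact_area(tumor, pleura, (2.0,) * 3, contact_mm=4.0)
        assert a2 == 4.0 * a1


class TestVesselConcepts:
    def _setup(self, caliber_value):
        shape = (16, 16, 16)
        tumor = _mask(shape, [(4, 8, 8)])
        vessel = _mask(shape, [(8, 8, 8)])
        caliber = np.where(vessel, caliber_value, 0.0)
        return tumor, vessel, caliber

    def test_subthreshold_vessel_is_ignored(self):
        tumor, vessel, caliber = self._setup(1.5)
        d, prox, cal = cx.vessel_concepts(tumor, vessel, caliber, (1.0,) * 3)
        assert math.isinf(d) and prox == 0.0 and math.isnan(cal)

    def test_distance_and_proximity(self):
        tumor, vessel, caliber = self._setup(3.0)
        d, prox, cal = cx.vessel_concepts(tumor, vessel, caliber, (1.0,) * 3)
        assert d == 4.0 and prox == 0.25 and cal == 3.0

    def test_contact_is_eps_capped(self):
        shape = (8, 8, 8)
        tumor = _mask(shape, [(4, 4, 4)])
        vessel = _mask(shape, [(4, 4, 4)])
        caliber = np.where(vessel, 2.5, 0.0)
        d, prox, _ = cx.vessel_concepts(tumor, vessel, caliber, (1.0,) * 3)
        assert d == 0.0 and prox == 2.0

    def test_caliber_tie_takes_largest(self):
        shape = (16, 16, 16)
        tumor = _mask(shape, [(8, 8, 8)])
        vessel = _mask(shape, [(5, 8, 8), (11, 8, 8)])
        caliber = np.zeros(shape)
        caliber[5, 8, 8] = 2.0
        caliber[11, 8, 8] = 4.0
        _, _, cal = cx.vessel_concepts(tumor, vessel, caliber, (1.0,) * 3)
        assert cal == 4.0


class TestShapeDescriptors:
    def test_cube_closed_form(self):
        tumor = np.zeros((14, 14, 14), dtype=bool)
        tumor[2:12, 2:12, 2:12] = True
        v, a, sph, elong = cx.shape_descriptors(tumor, (1.0,) * 3)
        assert v == 1000.0 and a == 600.0
        assert sph == pytest.approx(math.pi ** (1 / 3) * 6000 ** (2 / 3) / 600, abs=1e-9)
        assert elong == pytest.approx(1.0, abs=1e-9)

    def test_digital_sphere_staircase_bias(self):
        # face counting overestimates a sphere's area by ~1.5x, so the
        # sphericity of a digital ball sits near 2/3 rather than 1
        coords = np.indices((28, 28, 28)).transpose(1, 2, 3, 0)
        tumor = ((coords - 13.5) ** 2).sum(axis=-1) <= 10.0**2
        v, a, sph, elong = cx.shape_descriptors(tumor, (1.0,) * 3)
        assert v == pytest.approx(4 / 3 * math.pi * 1000, rel=0.05)
        assert 0.60 <= sph <= 0.75
        assert elong == pytest.approx(1.0, abs=0.05)

    def test_prolate_ellipsoid_elongation(self):
        coords = np.indices((52, 32, 32)).transpose(1, 2, 3, 0).astype(float)
        c = np.array([25.5, 15.5, 15.5])
        radii = np.array([20.0, 10.0, 10.0])
        tumor = (((coords - c) / radii) ** 2).sum(axis=-1) <= 1.0
        _, _, _, elong = cx.shape_descriptors(tumor, (1.0,) * 3)
        assert elong == pytest.approx(0.5, abs=0.03)

    def test_single_voxel_defined(self):
        tumor = _mask((4, 4, 4), [(1, 1, 1)])
        v, a, sph, elong = cx.shape_descriptors(tumor, (1.0,) * 3)
        assert v == 1.0 and a == 6.0 and elong == 1.0


class TestExtractConcepts:
    def test_no_adhesion_flags(self, juxtapleural_phantom):
        c = cx.extract_concepts(juxtapleural_phantom)
        assert c["adhesion_present"] == 0.0 and c["log_adhesion_area"] == 0.0

    def test_target_distance_recovered(self, default_phantom):
        _, vol, _ = default_phantom
        c = cx.extract_concepts(vol)
        assert 7.0 <= c["min_pleura_distance_mm"] <= 9.0

    def test_missing_label_listed(self):
        vol = LabelVolume(np.zeros((8, 8, 8), dtype=np.int16), (1.0,) * 3)
        with pytest.raises(ValueError, match="tumor"):
            cx.extract_concepts(vol)

    def test_all_fields_present_and_consistent(self, default_phantom):
        _, vol, _ = default_phantom
        c = cx.extract_concepts(vol)
        assert list(c) == cx.CONCEPT_COLUMNS
        for k, v in c.items():
            if k in ("vessel_min_distance_mm", "nearest_vessel_caliber_mm"):
                continue
            assert np.isfinite(v), k
        assert c["log_adhesion_area"] == pytest.approx(math.log1p(c["adhesion_area_mm2"]))

    def test_translation_invariance(self, default_phantom):
        _, vol, _ = default_phantom
        shifted = LabelVolume(
            np.roll(vol.labels, (2, -3, 1), axis=(0, 1, 2)),
            vol.spacing,
            caliber=np.roll(vol.caliber, (2, -3, 1), axis=(0, 1, 2)),
        )
        c0 = cx.extract_concepts(vol)
        c1 = cx.extract_concepts(shifted)
        for k in cx.CONCEPT_COLUMNS:
            assert c1[k] == pytest.approx(c0[k], abs=1e-9), k

    def test_resolution_consistency(self):
        """Concepts from a 0.5 mm phantom and its 1 mm resampling agree to 10%."""
        spec = ph.standard_spec(
            pleura_distance_mm=6.0,
            tumor_radius_mm=7.0,
            vessel_distance_mm=5.0,
            vessel_caliber_mm=3.0,
            grid_shape=(96, 96, 96),
            spacing_mm=0.5,
            lung_radius_mm=20.0,
        )
        vol, _ = ph.generate_phantom(spec, with_intensity=False)
        fine = cx.extract_concepts(vol)
        lab = vio.resample_isotropic(Volume(vol.labels, vol.spacing, kind="label"), 1.0)
        cal = vio.resample_isotropic(Volume(vol.caliber, vol.spacing, kind="hu"), 1.0)
        coarse_vol = LabelVolume(lab.data, lab.spacing, caliber=np.asarray(cal.data, np.float32))
        coarse = cx.extract_concepts(coarse_vol)
        for k in ("tumor_volume_mm3", "min_pleura_distance_mm", "vessel_min_distance_mm"):
            assert coarse[k] == pytest.approx(fine[k], rel=0.10), k


class TestZScorer:
    def _table(self):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "tumor_volume_mm3": rng.normal(1000, 200, 50),
                "min_pleura_distance_mm": rng.uniform(1, 10, 50),
                "sphericity": np.full(50, 0.8),
            }
        )

    def test_train_transform_standardizes(self):
        t = self._table()
        z = cx.zscore_fit(t).transform(t)
        assert z["tumor_volume_mm3"].mean() == pytest.approx(0.0, abs=1e-9)
        assert z["tumor_volume_mm3"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_constant_column_flagged_and_passed_through(self):
        t = self._table()
        scorer = cx.zscore_fit(t)
        assert "sphericity" in scorer.constant_columns
        assert np.allclose(scorer.transform(t)["sphericity"], 0.8)

    def test_test_set_uses_train_parameters(self):
        train = self._table()
        scorer = cx.zscore_fit(train)
        test = train.copy()
        test["min_pleura_distance_mm"] += 5.0
        z = scorer.transform(test)
        assert abs(z["min_pleura_distance_mm"].mean()) > 1.0

    def test_apply_before_fit_rejected(self):
        with pytest.raises(RuntimeError):
            cx.ZScorer().transform(self._table())

    def test_serialization_round_trip(self):
        scorer = cx.zscore_fit(self._table())
        back = cx.ZScorer.from_dict(scorer.to_dict())
        t = self._table()
        assert back.transform(t).equals(scorer.transform(t))
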