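import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octbands.bands import (
    BANDS,
    loss_area_mm2,
    loss_mask,
    quantify,
    sdd_thickness_map,
    sdd_volume_nl,
    thickness_map,
)
from octbands.geometry import column_cell_area_mm2, make_geometry
from octbands.surfaces import SurfaceOrderingError

from conftest import flat_surface_set


class TestThicknessMap:
    def test_flat_rpe_band_16_um(self, small_geometry):
        ss = flat_surface_set(small_geometry,
                              levels={"ELM": 250, "EZ_inner": 270,
                                      "EZ_outer": 300, "RPE_inner": 300,
                                      "RPE_outer": 316})
        np.testing.assert_allclose(thickness_map(ss, "RPE").values, 16.0)

    def test_zero_thickness_band(self, small_geometry):
        ss = flat_surface_set(small_geometry,
                              levels={"ELM": 270, "EZ_inner": 270,
                                      "EZ_outer": 297, "RPE_inner": 297,
                                      "RPE_outer": 318})
        np.testing.assert_allclose(thickness_map(ss, "ELM_MZ").values, 0.0)

    def test_worked_example_spot_checks(self, worked_example):
        # direct-subtraction oracle on five columns
        eye, _ = worked_example
        ss = eye.acquisitions["standard"]
        tm = thickness_map(ss, "EZ").values
        for b, a in [(0, 0), (2, 10), (4, 32), (6, 50), (8, 63)]:
            expected = ss.surfaces["RPE_inner"][b, a] - ss.surfaces["EZ_inner"][b, a]
            if np.isnan(expected):
                assert np.isnan(tm[b, a])
            else:
                assert tm[b, a] == pytest.approx(expected)

    def test_missing_where_either_boundary_missing(self, flat_eye):
        flat_eye.surfaces["RPE_inner"][1, 1] = np.nan
        flat_eye.surfaces["RPE_outer"][1, 1] = np.nan
        assert np.isnan(thickness_map(flat_eye, "RPE").values[1, 1])
        assert np.isnan(thickness_map(flat_eye, "EZ").values[1, 1])

    def test_ordering_violation_rejected(self, flat_eye):
        flat_eye.surfaces["ELM"][0, 0] = 999.0
        with pytest.raises(SurfaceOrderingError):
            thickness_map(flat_eye, "ELM_MZ")

    def test_unknown_band_rejected(self, flat_eye):
        with pytest.raises(KeyError):
            thickness_map(flat_eye, "IZ")


class TestLossMask:
    def test_complete_surfaces_no_loss(self, flat_eye):
        for band in BANDS:
            assert loss_mask(flat_eye, band).values.sum() == 0

    def test_sdd_disrupted_column_counts_as_ez_loss(self, flat_eye):
        flat_eye.sdd_disrupted[4, 8] = True
        mask = loss_mask(flat_eye, "EZ")
        assert mask.values[4, 8] == 1.0
        assert mask.values.sum() == 1.0
        # thickness at that column is missing by contract
        assert np.isnan(thickness_map(flat_eye, "EZ").values[4, 8])
        # other bands are unaffected
        assert loss_mask(flat_eye, "RPE").values.sum() == 0

    def test_missingness_coherence(self, lesion_only_cohort):
        ss = lesion_only_cohort.eyes[0].acquisitions["standard"]
        for band in BANDS:
            lost = loss_mask(ss, band).values == 1.0
            missing = np.isnan(thickness_map(ss, band).values)
            np.testing.assert_array_equal(lost, missing)

    def test_phantom_ellipse_mask_area_within_2pct_of_truth(
        self, lesion_only_cohort
    ):
        ss = lesion_only_cohort.eyes[0].acquisitions["standard"]
        truth = lesion_only_cohort.truth.loss_areas.query(
            "device == 'standard'").set_index("band").true_loss_mm2
        for band in BANDS:
            measured = loss_area_mm2(loss_mask(ss, band))
            assert measured == pytest.approx(truth[band], rel=0.02)


class TestLossArea:
    def test_empty_mask_zero(self, flat_eye):
        assert loss_area_mm2(loss_mask(flat_eye, "RPE")) == 0.0

    def test_full_field_area(self):
        g = make_geometry()
        ss = flat_surface_set(g)
        mask = loss_mask(ss, "RPE")
        mask.values[:] = 1.0
        expected = g.n_ascans * g.n_bscans * column_cell_area_mm2(g)
        assert loss_area_mm2(mask, g) == pytest.approx(expected)
        assert loss_area_mm2(mask, g) == pytest.approx(35.09, abs=0.02)

    def test_one_slab_row(self, small_geometry):
        ss = flat_surface_set(small_geometry)
        mask = loss_mask(ss, "RPE")
        mask.values[3, :] = 1.0
        expected = small_geometry.n_ascans * column_cell_area_mm2(small_geometry)
        assert loss_area_mm2(mask) == pytest.approx(expected)

    def test_additivity_over_partition(self, lesion_only_cohort):
        ss = lesion_only_cohort.eyes[0].acquisitions["standard"]
        mask = loss_mask(ss, "EZ")
        whole = loss_area_mm2(mask)
        left, right = mask.values[:, :500], mask.values[:, 500:]
        cell = column_cell_area_mm2(ss.geometry)
        assert whole == pytest.approx(
            (left.sum() + right.sum()) * cell, rel=1e-12
        )


class TestSdd:
    @pytest.mark.parametrize("gap, expected", [(4.0, 0.0), (10.0, 10.0),
                                               (3.0, 0.0), (4.001, 4.001)])
    def test_strict_threshold(self, small_geometry, gap, expected):
        ss = flat_surface_set(small_geometry,
                              levels={"ELM": 250, "EZ_inner": 270,
                                      "EZ_outer": 297 - gap,
                                      "RPE_inner": 297, "RPE_outer": 318})
        np.testing.assert_allclose(sdd_thickness_map(ss).values, expected)

    def test_uniform_10um_over_1mm2_is_10_nl(self):
        # 100 x 100 columns of 10 x 10 um cells = 1 mm^2
        g = make_geometry(fov_deg=1.0, mm_per_deg=0.99 / 1.0, n_ascans=100,
                          n_bscans=100, bscan_spacing_um=10.0)
        assert g.lateral_spacing_um == pytest.approx(10.0)
        ss = flat_surface_set(g, levels={"ELM": 250, "EZ_inner": 270,
                                         "EZ_outer": 287, "RPE_inner": 297,
                                         "RPE_outer": 318})
        assert sdd_volume_nl(sdd_thickness_map(ss)) == pytest.approx(10.0)

    def test_mound_profile_matches_closed_form(self, sdd_only_cohort):
        ss = sdd_only_cohort.eyes[0].acquisitions["high_res"]
        truth = sdd_only_cohort.truth
        sdd = sdd_thickness_map(ss)
        g = ss.geometry
        b_f, a_f = ss.fovea_center
        m = truth.mounds.iloc[0]
        # column nearest the mound peak carries ~the analytic peak height
        a = a_f + round(m.x_mm * 1000.0 / g.lateral_spacing_um)
        b = b_f + round(m.y_mm * 1000.0 / g.bscan_spacing_um)
        assert sdd.values[b, a] == pytest.approx(m.height_um, abs=3.0)

    def test_volume_recovery_within_5pct(self, sdd_only_cohort):
        truth = sdd_only_cohort.truth.sdd
        for dev, ss in sdd_only_cohort.eyes[0].acquisitions.items():
            vis = truth.query(
                "device == @dev and region == 'whole_field'"
            ).true_visible_nl.iloc[0]
            measured = sdd_volume_nl(sdd_thickness_map(ss))
            assert measured == pytest.approx(vis, rel=0.05)

    def test_region_mask_shape_mismatch(self, flat_eye):
        with pytest.raises(ValueError, match="mask shape"):
            sdd_volume_nl(sdd_thickness_map(flat_eye),
                          region_mask=np.ones((2, 2), dtype=bool))

    @given(st.lists(st.floats(0.0, 30.0), min_size=2, max_size=6, unique=True))
    @settings(max_examples=25, deadline=None)
    def test_raising_threshold_never_increases_volume(self, thresholds):
        ss = flat_surface_set(make_geometry(n_ascans=16, n_bscans=4))
        rng = np.random.default_rng(0)
        gap = rng.uniform(0.0, 25.0, size=ss.geometry.shape)
        ss.surfaces["EZ_outer"] = ss.surfaces["RPE_inner"] - gap
        ss.surfaces["EZ_inner"] = np.minimum(ss.surfaces["EZ_inner"],
                                             ss.surfaces["EZ_outer"])
        ss.surfaces["ELM"] = ss.surfaces["EZ_inner"] - 20.0
        volumes = [sdd_volume_nl(sdd_thickness_map(ss, threshold_um=t))
                   for t in sorted(thresholds)]
        assert all(v1 >= v2 - 1e-12 for v1, v2 in zip(volumes, volumes[1:]))


class TestQuantify:
    def test_device_invariance(self, worked_example):
        # identical surfaces under a different device label quantify identically
        eye, _ = worked_example
        ss = eye.acquisitions["standard"]
        relabeled = ss.copy()
        relabeled.device_label = "whatever"
        q1, q2 = quantify(ss), quantify(relabeled)
        assert q1.loss_area_mm2 == q2.loss_area_mm2
        assert q1.sdd_volume_nl == q2.sdd_volume_nl
        np.testing.assert_array_equal(q1.thickness["EZ"].values,
                                      q2.thickness["EZ"].values)

    def test_loss_area_equals_count_times_cell(self, lesion_only_cohort):
        ss = lesion_only_cohort.eyes[0].acquisitions["standard"]
        q = quantify(ss)
        for band in BANDS:
            count = q.loss[band].values.sum()
            assert q.loss_area_mm2[band] == pytest.approx(
                count * column_cell_area_mm2(ss.geometry)
            )
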