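import math

import numpy as np
import pandas as pd
import pytest

from octbands.bands import BANDS, quantify
from octbands.etdrs import (
    EtdrsGrid,
    assign_subfield,
    covered_fraction,
    quadrant_area_mm2,
    ring_quadrant_labels,
    sdd_distribution_map,
    subfield_areas_mm2,
    summarize_subfields,
)
from octbands.geometry import column_cell_area_mm2, make_geometry

from conftest import flat_surface_set


def grid_for(ss):
    return EtdrsGrid(fovea_center=ss.fovea_center,
                     laterality=ss.geometry.laterality)


class TestRingAreas:
    def test_standard_ring_areas(self):
        areas = subfield_areas_mm2()
        assert areas == {"center": 0.79, "parafoveal_ring": 6.28,
                         "perifoveal_ring": 21.21}

    def test_unrounded_sum_is_6mm_disc(self):
        areas = subfield_areas_mm2(rounded=False)
        assert sum(areas.values()) == pytest.approx(math.pi * 9.0, rel=1e-12)

    def test_merged_quadrant_area(self):
        assert quadrant_area_mm2() == pytest.approx(math.pi * (9 - 0.25) / 4)

    def test_non_increasing_radii_rejected(self):
        with pytest.raises(ValueError):
            EtdrsGrid(fovea_center=(0, 0), ring_radii_mm=(1.5, 0.5, 3.0))


class TestAssignSubfield:
    def test_fovea_column_is_center(self, default_geometry):
        grid = EtdrsGrid(fovea_center=(24, 512))
        assert assign_subfield(24, 512, grid, default_geometry) == "center"

    def test_1mm_superior_is_parafoveal_superior(self, default_geometry):
        grid = EtdrsGrid(fovea_center=(24, 512))
        db = round(1000.0 / default_geometry.bscan_spacing_um)  # ~1 mm up
        label = assign_subfield(24 + db, 512, grid, default_geometry)
        assert label == "parafoveal_superior"

    def test_2mm_superior_is_perifoveal_superior(self, default_geometry):
        # parafoveal radius bin is [0.5, 1.5) mm, so 2 mm is perifoveal
        grid = EtdrsGrid(fovea_center=(24, 512))
        db = round(2000.0 / default_geometry.bscan_spacing_um)
        label = assign_subfield(24 + db, 512, grid, default_geometry)
        assert label == "perifoveal_superior"

    def test_laterality_flips_nasal_temporal(self, default_geometry):
        da = round(2000.0 / default_geometry.lateral_spacing_um)  # 2 mm left
        grid_od = EtdrsGrid(fovea_center=(24, 512), laterality="OD")
        grid_os = EtdrsGrid(fovea_center=(24, 512), laterality="OS")
        import dataclasses

        g_os = dataclasses.replace(default_geometry, laterality="OS")
        assert assign_subfield(24, 512 - da, grid_od,
                               default_geometry) == "perifoveal_temporal"
        assert assign_subfield(24, 512 - da, grid_os,
                               g_os) == "perifoveal_nasal"

    def test_outside_is_a_valid_label(self, default_geometry):
        grid = EtdrsGrid(fovea_center=(24, 512))
        # the lattice corner lies ~4.1 mm from a centered fovea
        assert assign_subfield(0, 0, grid, default_geometry) == "outside"

    def test_off_lattice_column_rejected(self, default_geometry):
        grid = EtdrsGrid(fovea_center=(24, 512))
        with pytest.raises(ValueError):
            assign_subfield(49, 0, grid, default_geometry)

    def test_every_column_within_3mm_gets_exactly_one_label(
        self, default_geometry
    ):
        grid = EtdrsGrid(fovea_center=(24, 512))
        ring, quadrant = ring_quadrant_labels(grid, default_geometry)
        inside = ring != "outside"
        assert set(np.unique(ring[inside])) <= {"center", "parafoveal",
                                                "perifoveal"}
        assert set(np.unique(quadrant)) == {"superior", "nasal", "inferior",
                                            "temporal"}


class TestSummaries:
    def test_zero_loss_everywhere(self, flat_eye):
        rep = summarize_subfields(quantify(flat_eye), grid_for(flat_eye))
        rel = rep[rep.metric == "rel_loss_pct"]
        assert (rel.value == 0).all()

    def test_perifoveal_relative_loss_normalization(self):
        # a printed absolute perifoveal loss of 2.23 mm^2 is 10.5% of the
        # nominal 21.21 mm^2 ring
        areas = subfield_areas_mm2(rounded=False)
        assert round(2.23 / areas["perifoveal_ring"] * 100, 1) == 10.5

    def test_ring_losses_sum_to_6mm_disc_loss(self, lesion_only_cohort):
        ss = lesion_only_cohort.eyes[0].acquisitions["standard"]
        q = quantify(ss)
        rep = summarize_subfields(q, grid_for(ss))
        for band in BANDS:
            rows = rep[(rep.band == band) & (rep.metric == "abs_loss_mm2")]
            by = rows.set_index("subfield").value
            ring, _ = ring_quadrant_labels(grid_for(ss), ss.geometry)
            in_disc = ring != "outside"
            direct = (q.loss[band].values[in_disc].sum()
                      * column_cell_area_mm2(ss.geometry))
            assert (by["center"] + by["parafoveal_ring"]
                    + by["perifoveal_ring"]) == pytest.approx(direct)

    def test_central_lesion_recovered_in_center_subfield(self):
        from octbands.phantom import (DrusenSpec, LesionSpec, PhantomSpec,
                                      SddSpec, generate_cohort)

        spec = PhantomSpec(
            seed=3, n_patients=1,
            lesion=LesionSpec(center_offset_mm=(0.0, 0.0),
                              rpe_semi_axes_mm=(0.3, 0.3),
                              elm_margin_mm=0.0, ez_margin_mm=0.0,
                              scale_sigma=0.0, center_jitter_mm=0.0),
            drusen=DrusenSpec(count=0), sdd=SddSpec(count_mean=0))
        c = generate_cohort(spec)
        ss = c.eyes[0].acquisitions["standard"]
        rep = summarize_subfields(quantify(ss), grid_for(ss))
        rows = rep[(rep.band == "RPE") & (rep.metric == "abs_loss_mm2")]
        by = rows.set_index("subfield").value
        # a 0.3 mm lesion spans only ~5 B-scan slabs, so the rectangle
        # rule carries a few percent of discretization error here
        assert by["center"] == pytest.approx(math.pi * 0.09, rel=0.05)
        assert by["parafoveal_ring"] == 0.0
        assert by["perifoveal_ring"] == 0.0

    def test_relative_loss_bounded_for_center_and_parafovea(
        self, lesion_only_cohort
    ):
        ss = lesion_only_cohort.eyes[0].acquisitions["standard"]
        rep = summarize_subfields(quantify(ss), grid_for(ss))
        rel = rep[(rep.metric == "rel_loss_pct")
                  & rep.subfield.isin(["center", "parafoveal_ring"])]
        # a fully lost subfield can exceed 100% by a sub-percent rasterization
        # margin (column count x cell area vs the nominal disc area)
        assert ((rel.value >= 0) & (rel.value <= 101)).all()

    def test_quadrant_sdd_volumes_sum_to_6mm_disc(self, sdd_only_cohort):
        from octbands.bands import sdd_volume_nl

        ss = sdd_only_cohort.eyes[0].acquisitions["high_res"]
        q = quantify(ss)
        rep = summarize_subfields(q, grid_for(ss))
        vols = rep[rep.metric == "sdd_volume_nl"].set_index("subfield").value
        ring, _ = ring_quadrant_labels(grid_for(ss), ss.geometry)
        disc = ring != "outside"
        direct = sdd_volume_nl(q.sdd_thickness, region_mask=disc)
        quads = vols[["superior", "nasal", "inferior", "temporal"]].sum()
        assert vols["center"] + quads == pytest.approx(direct, rel=1e-9)

    def test_laterality_mirror_symmetry(self, sdd_only_cohort):
        # flipping the en-face maps left-right together with laterality
        # leaves every subfield summary unchanged
        import dataclasses

        ss = sdd_only_cohort.eyes[0].acquisitions["standard"]
        rep1 = summarize_subfields(quantify(ss), grid_for(ss))

        flipped = ss.copy()
        flipped.surfaces = {k: v[:, ::-1].copy()
                            for k, v in flipped.surfaces.items()}
        flipped.sdd_disrupted = flipped.sdd_disrupted[:, ::-1].copy()
        g = ss.geometry
        flipped.geometry = dataclasses.replace(
            g, laterality="OS" if g.laterality == "OD" else "OD")
        b_f, a_f = ss.fovea_center
        flipped.fovea_center = (b_f, g.n_ascans - 1 - a_f)
        rep2 = summarize_subfields(quantify(flipped), grid_for(flipped))

        merged = rep1.merge(rep2, on=["subfield", "band", "metric"],
                            suffixes=("_od", "_os"))
        assert len(merged) == len(rep1)
        np.testing.assert_allclose(merged.value_od, merged.value_os,
                                   rtol=1e-9, equal_nan=True)

    def test_mismatched_fovea_rejected(self, flat_eye):
        grid = EtdrsGrid(fovea_center=(0, 0))
        with pytest.raises(ValueError, match="fovea"):
            summarize_subfields(quantify(flat_eye), grid)


class TestDistributionMap:
    def test_single_eye_is_its_own_volume_map(self, sdd_only_cohort):
        from octbands.geometry import column_cell_area_um2

        ss = sdd_only_cohort.eyes[0].acquisitions["high_res"]
        q = quantify(ss)
        dist = sdd_distribution_map([q])
        np.testing.assert_allclose(
            dist.values, q.sdd_thickness.values * column_cell_area_um2(ss.geometry)
        )

    def test_mean_of_identical_eyes_is_idempotent(self, sdd_only_cohort):
        q = quantify(sdd_only_cohort.eyes[0].acquisitions["high_res"])
        one = sdd_distribution_map([q])
        two = sdd_distribution_map([q, q])
        np.testing.assert_allclose(one.values, two.values, equal_nan=True)

    def test_superior_mass_exceeds_inferior(self):
        # the generator places more SDD mass superiorly; the cohort map
        # must reproduce that asymmetry
        from octbands.phantom import (DrusenSpec, PhantomSpec, SddSpec,
                                      generate_cohort)

        spec = PhantomSpec(seed=17, n_patients=6, n_ascans=256, n_bscans=25,
                           lesion=None, drusen=DrusenSpec(count=0),
                           sdd=SddSpec(count_mean=25, count_poisson=False))
        c = generate_cohort(spec)
        quants = [quantify(e.acquisitions["high_res"]) for e in c.eyes]
        dist = sdd_distribution_map(quants)
        b_f = dist.fovea_center[0]
        superior = np.nansum(dist.values[b_f + 1:])
        inferior = np.nansum(dist.values[:b_f])
        assert superior > inferior

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sdd_distribution_map([])

    def test_coverage_diagnostic_reports_clipping(self, default_geometry):
        grid = EtdrsGrid(fovea_center=(24, 512))
        cov = covered_fraction(grid, default_geometry)
        assert cov["center"] == pytest.approx(1.0, abs=0.01)
        assert cov["parafoveal"] == pytest.approx(1.0, abs=0.01)
        # the 20-degree field clips the 6-mm circle slightly
        assert 0.97 < cov["perifoveal"] < 1.0
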