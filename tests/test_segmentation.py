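"""Segment partition: contours, sectors, rim exclusion, transmural split, stats."""

import numpy as np
import pytest
from shapely.geometry import Polygon

import cardiomap as cm
from cardiomap.relaxometry import ParameterMap
from cardiomap.segmentation import (
    ContourSet,
    build_segments,
    contours_from_phantom,
    exclude_bright_blood,
    exclude_inner_rim,
    segment_statistics,
    split_transmural,
    transmural_depth,
)


def constant_map(shape, value, mask=None):
    mask = np.ones(shape, bool) if mask is None else mask
    return ParameterMap(values=np.where(mask, float(value), np.nan),
                        r_squared=np.where(mask, 1.0, np.nan),
                        valid_mask=mask, modality="T1")


class TestContours:
    def test_polygon_areas_match_circles(self, contours, geometry):
        px = geometry.pixel_size_mm
        for poly, r_mm in ((contours.epicardial, geometry.epi_radius_mm),
                           (contours.endocardial, geometry.endo_radius_mm)):
            area_mm2 = Polygon(poly).area * px ** 2
            assert area_mm2 == pytest.approx(np.pi * r_mm ** 2, rel=0.01)

    def test_rotated_phantom_rotates_contours(self, geometry):
        import dataclasses
        ph = cm.make_lv_phantom(geometry, cm.HEALTHY_MYOCARDIUM)
        rotated_geom = dataclasses.replace(geometry, reference_angle_deg=90.0)
        ph_rot = cm.make_lv_phantom(rotated_geom, cm.HEALTHY_MYOCARDIUM)
        a = contours_from_phantom(ph)
        b = contours_from_phantom(ph_rot)
        # same circles, different reference angle
        np.testing.assert_allclose(a.epicardial, b.epicardial)
        assert b.reference_angle_deg == 90.0

    def test_non_annular_mask_rejected(self):
        ph = cm.uniform_phantom((10, 10), cm.HEALTHY_MYOCARDIUM)
        ph.geometry = cm.GeometryConfig()
        with pytest.raises(ValueError, match="annular"):
            contours_from_phantom(ph)

    def test_endo_inside_epi_enforced(self, contours):
        with pytest.raises(ValueError, match="inside"):
            ContourSet(epicardial=contours.endocardial,
                       endocardial=contours.epicardial)


class TestBuildSegments:
    def test_mid_level_has_six_sectors(self, labelmap6):
        assert labelmap6.n_segments() == 6
        assert set(labelmap6.names.values()) == {"A", "AS", "IS", "I", "IL", "AL"}

    def test_apical_level_has_four_sectors(self, contours, healthy_phantom):
        lm = build_segments(contours, "apical", healthy_phantom.shape)
        assert lm.n_segments() == 4

    def test_every_myocardial_pixel_gets_exactly_one_label(self, labelmap6, contours,
                                                           healthy_phantom):
        depth = transmural_depth(contours, healthy_phantom.shape)
        wall = (depth >= 0) & (depth <= 1)
        assert ((labelmap6.labels > 0) == wall).all()

    def test_raster_too_small_rejected(self, contours):
        with pytest.raises(ValueError, match="small"):
            build_segments(contours, "mid", (10, 10))

    def test_rotational_equivariance_of_pixel_multisets(self, healthy_phantom,
                                                        geometry):
        # rotating the reference angle by one sector width permutes labels
        # without changing the per-segment pixel-count multiset
        import dataclasses
        c0 = contours_from_phantom(healthy_phantom)
        ph60 = cm.make_lv_phantom(
            dataclasses.replace(geometry, reference_angle_deg=60.0),
            cm.HEALTHY_MYOCARDIUM)
        c60 = contours_from_phantom(ph60)
        lm0 = build_segments(c0, "mid", healthy_phantom.shape)
        lm60 = build_segments(c60, "mid", healthy_phantom.shape)
        counts0 = sorted(np.bincount(lm0.labels.ravel())[1:].tolist())
        counts60 = sorted(np.bincount(lm60.labels.ravel())[1:].tolist())
        assert counts0 == counts60


class TestRimExclusion:
    def test_zero_fraction_is_identity(self, labelmap6, contours):
        out = exclude_inner_rim(labelmap6, contours, 0.0)
        np.testing.assert_array_equal(out.labels, labelmap6.labels)

    def test_matches_bruteforce_depth_threshold(self, labelmap6, contours):
        out = exclude_inner_rim(labelmap6, contours, 0.05)
        depth = transmural_depth(contours, labelmap6.labels.shape)
        removed = (labelmap6.labels > 0) & (out.labels == 0)
        kept = out.labels > 0
        assert (depth[removed] < 0.05).all()
        assert (depth[kept] >= 0.05).all()

    @pytest.mark.parametrize("fractions", [(0.0, 0.05, 0.1, 0.2, 0.3)])
    def test_labeled_count_monotone_in_fraction(self, labelmap6, contours, fractions):
        counts = [int((exclude_inner_rim(labelmap6, contours, f).labels > 0).sum())
                  for f in fractions]
        assert counts == sorted(counts, reverse=True)

    def test_fraction_out_of_range_rejected(self, labelmap6, contours):
        with pytest.raises(ValueError):
            exclude_inner_rim(labelmap6, contours, 0.6)


class TestTransmuralSplit:
    def test_full_annulus_yields_twelve_labels(self, labelmap12):
        assert labelmap12.n_segments() == 12
        names = set(labelmap12.names.values())
        assert names == {f"{s}-{l}" for s in ("A", "AS", "IS", "I", "IL", "AL")
                         for l in ("epi", "endo")}

    def test_pixel_counts_conserved_by_split(self, labelmap6, contours):
        rimless = exclude_inner_rim(labelmap6, contours, 0.05)
        split = split_transmural(rimless, contours)
        assert (split.labels > 0).sum() == (rimless.labels > 0).sum()
        for s in range(1, 7):
            before = int((rimless.labels == s).sum())
            after = int(((split.labels == s) | (split.labels == s + 6)).sum())
            assert before == after

    def test_halves_match_bruteforce_depth_threshold(self, labelmap12, contours):
        depth = transmural_depth(contours, labelmap12.labels.shape)
        epi = (labelmap12.labels >= 1) & (labelmap12.labels <= 6)
        endo = labelmap12.labels > 6
        assert (depth[epi] >= 0.5).all()
        assert (depth[endo] < 0.5).all()

    def test_partition_is_disjoint_and_exhaustive(self, labelmap12, contours):
        depth = transmural_depth(contours, labelmap12.labels.shape)
        rim_excluded_wall = (depth >= 0.05) & (depth <= 1.0)
        assert ((labelmap12.labels > 0) == rim_excluded_wall).all()

    def test_segment_pixel_counts_in_reported_envelope(self, labelmap12):
        counts = np.bincount(labelmap12.labels.ravel())[1:]
        assert len(counts) == 12
        assert counts.min() >= 20 and counts.max() <= 55

    def test_split_of_apical_map_rejected(self, contours, healthy_phantom):
        lm = build_segments(contours, "apical", healthy_phantom.shape)
        with pytest.raises(ValueError):
            split_transmural(lm, contours)


class TestBrightBloodExclusion:
    def test_clean_map_unchanged(self, labelmap12):
        pmap = constant_map(labelmap12.labels.shape, 28.5)
        out = exclude_bright_blood(labelmap12, pmap, z_threshold=5.0)
        np.testing.assert_array_equal(out.labels, labelmap12.labels)

    def test_bright_outliers_removed_exactly(self, labelmap12):
        shape = labelmap12.labels.shape
        rng = np.random.default_rng(5)
        values = np.where(labelmap12.labels > 0,
                          28.5 + 0.5 * rng.standard_normal(shape), np.nan)
        labeled_idx = np.argwhere(labelmap12.labels > 0)[:5]
        for r, c in labeled_idx:
            values[r, c] = 285.0  # stagnant-blood brightness: 10x the median
        pmap = ParameterMap(values=values, r_squared=np.ones(shape),
                            valid_mask=labelmap12.labels > 0, modality="T2")
        out = exclude_bright_blood(labelmap12, pmap, z_threshold=5.0)
        removed = np.argwhere((labelmap12.labels > 0) & (out.labels == 0))
        np.testing.assert_array_equal(sorted(removed.tolist()),
                                      sorted(labeled_idx.tolist()))

    def test_never_adds_pixels(self, labelmap12):
        pmap = constant_map(labelmap12.labels.shape, 28.5)
        out = exclude_bright_blood(labelmap12, pmap, z_threshold=1.0)
        assert ((out.labels > 0) <= (labelmap12.labels > 0)).all()


class TestSegmentStatistics:
    def test_constant_map_statistics(self, labelmap12):
        pmap = constant_map(labelmap12.labels.shape, 1505.0)
        table = segment_statistics(pmap, labelmap12)
        assert len(table) == 12
        assert (table["mean"] == 1505.0).all()
        assert (table["sd"] == 0.0).all()

    def test_means_match_bruteforce_label_averaging(self, labelmap12):
        shape = labelmap12.labels.shape
        rng = np.random.default_rng(17)
        values = rng.uniform(10, 40, shape)
        pmap = ParameterMap(values=values, r_squared=np.ones(shape),
                            valid_mask=np.ones(shape, bool), modality="T2")
        table = segment_statistics(pmap, labelmap12).set_index("segment_id")
        for seg_id in range(1, 13):
            sel = labelmap12.labels == seg_id
            assert table.loc[seg_id, "mean"] == pytest.approx(values[sel].mean())
            assert table.loc[seg_id, "median"] == pytest.approx(np.median(values[sel]))
            assert table.loc[seg_id, "n_pixels"] == int(sel.sum())

    def test_masking_changes_n_but_not_constant_mean(self, labelmap12):
        shape = labelmap12.labels.shape
        mask = np.ones(shape, bool)
        seg1 = np.argwhere(labelmap12.labels == 1)
        for r, c in seg1[: len(seg1) // 2]:
            mask[r, c] = False
        pmap = constant_map(shape, 1505.0, mask)
        table = segment_statistics(pmap, labelmap12).set_index("segment_id")
        assert table.loc[1, "n_pixels"] == len(seg1) - len(seg1) // 2
        assert table.loc[1, "mean"] == 1505.0

    def test_empty_segment_yields_nan_row_and_warning(self, labelmap12):
        shape = labelmap12.labels.shape
        mask = labelmap12.labels != 3  # no valid pixels in segment 3
        pmap = constant_map(shape, 28.5, mask)
        with pytest.warns(UserWarning, match="no valid pixels"):
            table = segment_statistics(pmap, labelmap12).set_index("segment_id")
        assert table.loc[3, "n_pixels"] == 0
        assert np.isnan(table.loc[3, "mean"])
        assert len(table) == 12  # never silently dropped
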