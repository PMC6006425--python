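"""Vectors of ROI: anchors, spline, placement, profiles, interaction ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.anova import AnovaRM

import gradconn as g
from gradconn.roi_vectors import (
    AnchorSet,
    EmptyROIError,
    InsufficientDataError,
    PiecewisePath,
    ProfileResult,
    SegmentationError,
    SpacingError,
    compute_anchors,
    extract_profile,
    fit_spline,
    match_vectors,
    place_rois,
    vector_interaction_test,
)
from gradconn.volumes import StatMap, Volume

AFFINE3 = np.diag([3.0, 3.0, 3.0, 1.0])


def straight_strip(n_y=30, width=3):
    data = np.zeros((10, n_y, 10))
    data[4 : 4 + width, :, 4] = 1.0
    return Volume(data, AFFINE3)


class TestAnchors:
    def test_straight_strip_anchors_collinear(self):
        anch = compute_anchors(straight_strip(), 5)
        xz = anch.coords_mm[:, [0, 2]]
        assert np.allclose(xz, xz[0], atol=1.5)  # within half a voxel

    def test_two_segments_are_half_centroids(self):
        mask = straight_strip(n_y=20)
        anch = compute_anchors(mask, 2)
        xyz = g.geometry.world_coordinates(mask.shape, mask.affine)[mask.data.astype(bool)]
        y = xyz[:, 1]
        mid = (y.min() + y.max()) / 2
        lower = xyz[y < mid].mean(axis=0)
        assert np.allclose(anch.coords_mm[0], lower, atol=1e-9)

    def test_curved_strip_anchor_in_own_bin_bbox(self):
        """Brute-force containment: each anchor lies inside the bounding box
        of its own segment's voxels."""
        data = np.zeros((20, 30, 10))
        for j in range(30):
            i = 5 + int(6 * np.sin(j / 6.0))
            data[i : i + 3, j, 4] = 1.0
        mask = Volume(data, AFFINE3)
        n_seg = 5
        anch = compute_anchors(mask, n_seg)
        xyz = g.geometry.world_coordinates(mask.shape, mask.affine)[data.astype(bool)]
        y = xyz[:, 1]
        edges = np.linspace(y.min(), y.max(), n_seg + 1)
        edges[-1] += 1e-6
        for k in range(n_seg):
            seg = xyz[(y >= edges[k]) & (y < edges[k + 1])]
            assert np.all(anch.coords_mm[k] >= seg.min(axis=0) - 1e-9)
            assert np.all(anch.coords_mm[k] <= seg.max(axis=0) + 1e-9)

    def test_errors(self):
        with pytest.raises(SegmentationError):
            compute_anchors(Volume(np.zeros((5, 5, 5)), AFFINE3), 3)
        # more segments than occupied y slabs leaves an empty bin
        thin = np.zeros((5, 3, 5))
        thin[2, [0, 2], 2] = 1.0
        with pytest.raises(SegmentationError, match="fewer"):
            compute_anchors(Volume(thin, AFFINE3), 3)


class TestSpline:
    def test_two_anchors_single_segment(self):
        a = AnchorSet(np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]]))
        path = fit_spline(a)
        assert path.length == pytest.approx(5.0)

    def test_collinear_length_is_end_to_end(self):
        pts = np.array([[0, y, 0] for y in (0.0, 5.0, 11.0, 20.0)])
        assert fit_spline(AnchorSet(pts)).length == pytest.approx(20.0)

    def test_random_anchors_match_bruteforce_sum(self):
        rng = np.random.default_rng(0)
        pts = np.cumsum(rng.uniform(1, 5, size=(5, 3)), axis=0)
        path = fit_spline(AnchorSet(pts))
        oracle = sum(
            np.linalg.norm(pts[i + 1] - pts[i]) for i in range(len(pts) - 1)
        )
        assert path.length == pytest.approx(oracle)

    def test_duplicate_anchor_degenerate(self):
        with pytest.raises(ValueError, match="degenerate|ordered"):
            PiecewisePath(np.array([[0, 0, 0], [0, 0, 0], [1, 1, 1.0]]))


class TestPlaceROIs:
    def test_five_anchors_two_intermediates_give_13(self):
        pts = np.array([[0, 19.5 * k, 0] for k in range(5)])
        anch = AnchorSet(pts)
        vec = place_rois(fit_spline(anch), anch, 2, 3.0)
        assert len(vec) == 13

    def test_two_anchors_two_per_gap(self):
        pts = np.array([[0, 0, 0], [0, 30.0, 0]])
        anch = AnchorSet(pts)
        assert len(place_rois(fit_spline(anch), anch, 2, 3.0)) == 4

    def test_equal_within_gap_spacing_arc_oracle(self):
        """Numeric arc-length walk: within each gap, consecutive centres sit
        at equal path distance to 1e-9."""
        rng = np.random.default_rng(3)
        pts = np.column_stack(
            [rng.uniform(-5, 5, 5), np.sort(rng.uniform(0, 100, 5)), rng.uniform(-5, 5, 5)]
        )
        pts[:, 1] = np.array([0.0, 25.0, 50.0, 75.0, 100.0])
        anch = AnchorSet(pts)
        path = fit_spline(anch)
        vec = place_rois(path, anch, 2, 3.0)
        # oracle: arc position of each centre found by dense walking
        dense_s = np.linspace(0, path.length, 200001)
        dense_pts = np.array([path.point_at(s) for s in dense_s])
        arc = []
        for c in vec.centres_mm:
            arc.append(dense_s[np.argmin(np.linalg.norm(dense_pts - c, axis=1))])
        arc = np.array(arc)
        for gindex in range(4):
            seg = np.diff(arc[gindex * 3 : gindex * 3 + 4])
            assert np.all(np.abs(seg - seg.mean()) < path.length / 200000 + 1e-9)
        # exact-by-construction check at full precision
        for gindex in range(4):
            a0 = path.cum_lengths[gindex]
            a1 = path.cum_lengths[gindex + 1]
            expected = [a0 + f * (a1 - a0) / 3 for f in range(4)]
            got = [a0] + [
                np.dot(vec.centres_mm[gindex * 3 + i] - path.vertices[gindex],
                       (path.vertices[gindex + 1] - path.vertices[gindex]))
                / np.linalg.norm(path.vertices[gindex + 1] - path.vertices[gindex]) + a0
                for i in (1, 2)
            ] + [a1]
            assert np.allclose(got, expected, atol=1e-9)

    def test_overlap_raises(self):
        pts = np.array([[0, 0, 0], [0, 10.0, 0]])
        anch = AnchorSet(pts)
        with pytest.raises(SpacingError, match="overlap"):
            place_rois(fit_spline(anch), anch, 2, 3.0)

    @given(n=st.integers(2, 6), k=st.integers(0, 3))
    @settings(max_examples=20, deadline=None)
    def test_count_formula(self, n, k):
        pts = np.array([[0, 40.0 * i, 0] for i in range(n)])
        anch = AnchorSet(pts)
        vec = place_rois(fit_spline(anch), anch, k, 3.0)
        assert len(vec) == n + k * (n - 1)


class TestMatchVectors:
    def test_identical_vectors_zero_adjustment(self, roi_vectors):
        v = roi_vectors["FG"]
        matched, adj = match_vectors(v, v)
        assert np.all(adj == 0)

    def test_x_offset_unchanged(self):
        c = np.array([[0, 10.0 * k, 0] for k in range(4)])
        v1 = g.roi_vectors.ROIVector(c, 3.0)
        v2 = g.roi_vectors.ROIVector(c + [12, 0, 0], 3.0)
        matched, adj = match_vectors(v1, v2)
        assert np.all(adj == 0)

    def test_yz_equality_by_construction(self):
        rng = np.random.default_rng(1)
        c1 = np.column_stack([rng.normal(size=6), np.arange(6) * 10.0, rng.normal(size=6)])
        c2 = c1 + rng.normal(size=c1.shape)
        v1 = g.roi_vectors.ROIVector(c1, 3.0)
        v2 = g.roi_vectors.ROIVector(c2, 3.0)
        matched, _ = match_vectors(v1, v2)
        assert np.allclose(matched.centres_mm[:, 1:], c1[:, 1:])
        assert np.allclose(matched.centres_mm[:, 0], c2[:, 0])
        with pytest.raises(ValueError, match="pair"):
            match_vectors(v1, g.roi_vectors.ROIVector(c1[:3], 3.0))


class TestExtractProfile:
    def test_constant_map(self, roi_vectors, geometry):
        m = StatMap(np.full(geometry.shape, 4.5), geometry.affine, kind="beta")
        prof = extract_profile([m], roi_vectors["FG"])
        assert np.allclose(prof.values, 4.5)

    def test_tiny_radius_selects_single_voxel(self, geometry):
        centre = geometry.affine @ np.array([10, 20, 15, 1.0])
        vec = g.roi_vectors.ROIVector(centre[None, :3], radius_mm=1.0)
        data = np.random.default_rng(0).normal(size=geometry.shape)
        m = StatMap(data, geometry.affine, kind="beta")
        prof = extract_profile([m], vec)
        assert prof.values[0, 0] == data[10, 20, 15]

    def test_empty_roi_raises(self, geometry):
        vec = g.roi_vectors.ROIVector(np.array([[1.4, 1.4, 1.4]]), radius_mm=0.5)
        m = StatMap(np.zeros(geometry.shape), geometry.affine, kind="beta")
        with pytest.raises(EmptyROIError):
            extract_profile([m], vec)

    def test_subject_permutation_equivariance(self, roi_vectors, geometry):
        rng = np.random.default_rng(2)
        maps = [
            StatMap(rng.normal(size=geometry.shape), geometry.affine, kind="beta")
            for _ in range(4)
        ]
        p1 = extract_profile(maps, roi_vectors["FG"]).values
        p2 = extract_profile([maps[i] for i in (2, 0, 3, 1)], roi_vectors["FG"]).values
        assert np.allclose(p2, p1[[2, 0, 3, 1]])


def _profiles_from_array(y, y_mm=None):
    """y: (n_subj, 2 vectors, n_contrast, n_roi)."""
    n_s, n_v, n_c, n_r = y.shape
    y_mm = np.arange(n_r, dtype=float) if y_mm is None else y_mm
    out = {}
    for vi, v in enumerate(["FG", "ITG"][:n_v]):
        out[v] = {}
        for ci in range(n_c):
            out[v][f"c{ci}"] = ProfileResult(y[:, vi, ci], y_mm, v, f"c{ci}")
    return out


class TestInteractionANOVA:
    def test_identical_profiles_give_null_interaction(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(10, 1, 1, 5))
        y = np.concatenate([base, base], axis=1)  # both vectors identical
        res = vector_interaction_test(_profiles_from_array(y))
        row = res["per_contrast"]["c0"]
        assert row["F"] == pytest.approx(0.0, abs=1e-9)
        assert row["p"] == pytest.approx(1.0, abs=1e-9)
        assert res["followups"] == {}

    def test_two_by_two_matches_manual_sums_of_squares(self):
        """Oracle: for a 2 x 2 within design the interaction F equals the
        squared paired t of the double difference."""
        rng = np.random.default_rng(7)
        n_s = 9
        y = rng.normal(size=(n_s, 2, 1, 2)) + np.array([[0.0, 0.0], [0.0, 1.2]])[None, :, None, :]
        res = vector_interaction_test(_profiles_from_array(y))
        d = y[:, 0, 0, 0] - y[:, 0, 0, 1] - y[:, 1, 0, 0] + y[:, 1, 0, 1]
        f_manual = n_s * d.mean() ** 2 / d.var(ddof=1)
        assert res["per_contrast"]["c0"]["F"] == pytest.approx(f_manual, rel=1e-9)
        assert res["per_contrast"]["c0"]["df1"] == 1
        assert res["per_contrast"]["c0"]["df2"] == n_s - 1

    def test_followups_gated_on_interaction(self):
        rng = np.random.default_rng(1)
        # strong vector x position effect in contrast 0, pure noise in contrast 1
        y = rng.normal(scale=0.3, size=(12, 2, 2, 6))
        y[:, 1, 0] += np.linspace(0, 3, 6)
        res = vector_interaction_test(_profiles_from_array(y))
        assert "c0" in res["followups"]
        assert "c1" not in res["followups"]
        assert "three_way" in res

    def test_single_subject_insufficient(self):
        y = np.zeros((1, 2, 1, 4))
        with pytest.raises(InsufficientDataError):
            vector_interaction_test(_profiles_from_array(y))
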