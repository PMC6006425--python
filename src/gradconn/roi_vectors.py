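"""Vectors-of-ROI analysis: spheres along a cortical path, profiles, interactions.

A sector mask (a gyrus strip) is partitioned into segments of equal y-extent;
segment centroids become anchor points; a piecewise-linear spline is fitted
through the anchors; intermediate points at equal arc distances within each
inter-anchor gap complete the vector of equidistant, non-overlapping
spherical ROIs (5 anchors with 2 intermediates per gap give the canonical 13
spheres of 3-mm radius).  Contrast values are averaged per sphere and per
subject, and the evolution of profiles along the path is compared between
vectors/contrasts with within-subject factorial ANOVAs; position-wise paired
follow-ups are run only under a significant superordinate interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

from .geometry import world_coordinates
from .volumes import StatMap, Volume

__all__ = [
    "SegmentationError",
    "SpacingError",
    "EmptyROIError",
    "InsufficientDataError",
    "AnchorSet",
    "ROIVector",
    "ProfileResult",
    "compute_anchors",
    "fit_spline",
    "place_rois",
    "match_vectors",
    "extract_profile",
    "vector_interaction_test",
]


class SegmentationError(ValueError):
    pass


class SpacingError(ValueError):
    pass


class EmptyROIError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass
class AnchorSet:
    coords_mm: np.ndarray  # (n, 3), ordered along y
    sector: str = ""

    def __post_init__(self) -> None:
        self.coords_mm = np.atleast_2d(np.asarray(self.coords_mm, dtype=float))
        if len(self.coords_mm) < 2:
            raise ValueError("need at least two anchors")
        y = self.coords_mm[:, 1]
        if not np.all(np.diff(y) > 0):
            raise ValueError("anchors must be strictly ordered along the y-axis")


@dataclass
class PiecewisePath:
    """Ordered vertex list with exact arc length."""

    vertices: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.vertices = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        seg = np.diff(self.vertices, axis=0)
        self.segment_lengths = np.linalg.norm(seg, axis=1)
        if np.any(self.segment_lengths < 1e-12):
            raise ValueError("degenerate (zero-length) path segment from duplicate anchors")
        self.cum_lengths = np.concatenate([[0.0], np.cumsum(self.segment_lengths)])

    @property
    def length(self) -> float:
        return float(self.cum_lengths[-1])

    def point_at(self, s: float) -> np.ndarray:
        """Point at arc distance s from the start."""
        s = float(np.clip(s, 0.0, self.length))
        i = int(np.searchsorted(self.cum_lengths, s, side="right") - 1)
        i = min(i, len(self.segment_lengths) - 1)
        frac = (s - self.cum_lengths[i]) / self.segment_lengths[i]
        return self.vertices[i] + frac * (self.vertices[i + 1] - self.vertices[i])


@dataclass
class ROIVector:
    centres_mm: np.ndarray  # (n, 3) ordered along the path
    radius_mm: float
    path: PiecewisePath | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.centres_mm = np.atleast_2d(np.asarray(self.centres_mm, dtype=float))

    def __len__(self) -> int:
        return len(self.centres_mm)

    @property
    def y_mm(self) -> np.ndarray:
        return self.centres_mm[:, 1]


def compute_anchors(sector_mask: Volume, n_segments: int, sector: str = "") -> AnchorSet:
    """Split a strip mask into equal y-extent bins; anchors are bin centroids."""
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    mask = sector_mask.data.astype(bool)
    if not mask.any():
        raise SegmentationError("sector mask is empty")
    xyz = world_coordinates(mask.shape, sector_mask.affine)[mask]
    y = xyz[:, 1]
    edges = np.linspace(y.min(), y.max(), n_segments + 1)
    edges[-1] += 1e-6  # remainder voxels go to the last bin
    anchors = []
    for k in range(n_segments):
        sel = (y >= edges[k]) & (y < edges[k + 1])
        if not sel.any():
            raise SegmentationError(
                f"segment {k + 1}/{n_segments} contains no voxels; try fewer segments"
            )
        anchors.append(xyz[sel].mean(axis=0))
    return AnchorSet(np.array(anchors), sector=sector)


def fit_spline(anchors: AnchorSet) -> PiecewisePath:
    """Piecewise-linear spline through the anchors, in order."""
    return PiecewisePath(anchors.coords_mm.copy())


def place_rois(
    path: PiecewisePath,
    anchors: AnchorSet,
    intermediates_per_gap: int = 2,
    radius_mm: float = 3.0,
    label: str = "",
) -> ROIVector:
    """Spheres at anchors plus equidistant intermediates within each gap.

    Total count is n_anchors + intermediates_per_gap * (n_anchors - 1);
    within each inter-anchor gap, consecutive centres are separated by equal
    arc distance along the spline.  Overlapping spheres raise SpacingError.
    """
    if intermediates_per_gap < 0:
        raise ValueError("intermediates_per_gap must be >= 0")
    a = anchors.coords_mm
    # arc positions of the anchors along the path
    anchor_s = []
    for pt in a:
        d = np.linalg.norm(path.vertices - pt, axis=1)
        i = int(np.argmin(d))
        if d[i] > 1e-6:
            raise ValueError("anchors must lie on the path vertices")
        anchor_s.append(path.cum_lengths[i])
    centres = [a[0]]
    for g in range(len(a) - 1):
        s0, s1 = anchor_s[g], anchor_s[g + 1]
        for i in range(1, intermediates_per_gap + 1):
            frac = i / (intermediates_per_gap + 1)
            centres.append(path.point_at(s0 + frac * (s1 - s0)))
        centres.append(a[g + 1])
    centres = np.array(centres)
    for i in range(len(centres)):
        for j in range(i + 1, len(centres)):
            d = np.linalg.norm(centres[i] - centres[j])
            if d <= 2.0 * radius_mm:
                raise SpacingError(
                    f"spheres {i} and {j} overlap (centre distance {d:.2f} mm "
                    f"<= 2 x {radius_mm} mm)"
                )
    return ROIVector(centres, radius_mm, path=path, label=label)


def match_vectors(v1: ROIVector, v2: ROIVector) -> tuple[ROIVector, np.ndarray]:
    """Adjust v2 so each pair of ROIs shares y and z with v1 (x kept).

    Returns the adjusted vector and per-ROI adjustment magnitudes (mm).
    """
    if len(v1) != len(v2):
        raise ValueError(f"cannot pair vectors of lengths {len(v1)} and {len(v2)}")
    new = v2.centres_mm.copy()
    new[:, 1:] = v1.centres_mm[:, 1:]
    adjustments = np.linalg.norm(new - v2.centres_mm, axis=1)
    return ROIVector(new, v2.radius_mm, path=v2.path, label=v2.label), adjustments


@dataclass
class ProfileResult:
    """Per-subject, per-ROI mean statistic along a vector."""

    values: np.ndarray          # (n_subjects, n_rois)
    y_mm: np.ndarray            # per-ROI y position
    vector_label: str = ""
    contrast_label: str = ""

    @property
    def mean(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def sem(self) -> np.ndarray:
        n = self.values.shape[0]
        return self.values.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(self.mean)

    def to_frame(self) -> pd.DataFrame:
        n_subj, n_roi = self.values.shape
        return pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n_subj), n_roi),
                "roi": np.tile(np.arange(n_roi), n_subj),
                "y_mm": np.tile(self.y_mm, n_subj),
                "value": self.values.ravel(),
            }
        )


def extract_profile(
    stat_maps: list[StatMap], vector: ROIVector, contrast_label: str = ""
) -> ProfileResult:
    """Mean map value over voxels whose centre falls inside each sphere.

    ``stat_maps`` holds one (beta or t) map per subject, all in the vector's
    space.
    """
    if not stat_maps:
        raise InsufficientDataError("no subject maps supplied")
    ref = stat_maps[0]
    xyz = world_coordinates(ref.shape, ref.affine).reshape(-1, 3)
    roi_indices = []
    for i, centre in enumerate(vector.centres_mm):
        d2 = np.sum((xyz - centre) ** 2, axis=1)
        idx = np.flatnonzero(d2 <= vector.radius_mm**2 + 1e-9)
        if idx.size == 0:
            raise EmptyROIError(f"ROI {i} at {tuple(centre)} contains no voxel centres")
        roi_indices.append(idx)
    values = np.empty((len(stat_maps), len(vector)))
    for s, m in enumerate(stat_maps):
        if m.shape != ref.shape:
            raise ValueError("subject maps have mismatched shapes")
        flat = m.data.reshape(-1)
        for i, idx in enumerate(roi_indices):
            values[s, i] = flat[idx].mean()
    return ProfileResult(values, vector.y_mm.copy(), vector.label, contrast_label)


def _anova_row(table: pd.DataFrame, effect: str) -> dict:
    row = table.loc[effect]
    f, df1, df2 = float(row["F Value"]), float(row["Num DF"]), float(row["Den DF"])
    # a 0/0 sum-of-squares ratio (e.g. perfectly identical profiles) can
    # surface as a tiny or negative value; the true F is non-negative
    if not np.isfinite(f) or f < 1e-10:
        f = 0.0
    p = float(stats.f.sf(f, df1, df2))
    eta = f * df1 / (f * df1 + df2)
    return {"F": f, "df1": df1, "df2": df2, "p": p, "partial_eta_sq": eta}


def vector_interaction_test(
    profiles: dict[str, dict[str, ProfileResult]],
    alpha: float = 0.05,
) -> dict:
    """Within-subject factorial ANOVA on ROI profiles.

    ``profiles[vector][contrast]`` is a :class:`ProfileResult` with aligned
    subjects and ROI counts.  Returns per-contrast vector x position
    interactions, the contrast x vector x position interaction when more
    than one contrast is supplied, and position-wise paired follow-up tests
    — emitted only where the governing interaction is significant.
    """
    vectors = list(profiles)
    if len(vectors) != 2:
        raise ValueError("expected exactly two vectors")
    contrasts = list(profiles[vectors[0]])
    shapes = {
        profiles[v][c].values.shape for v in vectors for c in contrasts
    }
    if len(shapes) != 1:
        raise ValueError("profiles have mismatched subject/ROI counts")
    n_subj, n_roi = shapes.pop()
    if n_subj < 2:
        raise InsufficientDataError("within-subject ANOVA needs at least two subjects")

    rows = []
    for v in vectors:
        for c in contrasts:
            pr = profiles[v][c]
            for s in range(n_subj):
                for r in range(n_roi):
                    rows.append((s, v, c, r, pr.values[s, r]))
    data = pd.DataFrame(rows, columns=["subject", "vector", "contrast", "position", "value"])

    result: dict = {"alpha": alpha, "per_contrast": {}, "followups": {}}
    if len(contrasts) > 1:
        table = AnovaRM(
            data, "value", "subject", within=["contrast", "vector", "position"]
        ).fit().anova_table
        result["three_way"] = _anova_row(table, "contrast:vector:position")

    for c in contrasts:
        sub = data[data["contrast"] == c]
        table = AnovaRM(sub, "value", "subject", within=["vector", "position"]).fit().anova_table
        inter = _anova_row(table, "vector:position")
        result["per_contrast"][c] = inter
        if inter["p"] < alpha:  # family-wise gating: follow-ups only under interaction
            v0 = profiles[vectors[0]][c].values
            v1 = profiles[vectors[1]][c].values
            t, p = stats.ttest_rel(v0, v1, axis=0)
            result["followups"][c] = pd.DataFrame(
                {
                    "position": np.arange(n_roi),
                    "y_mm": profiles[vectors[0]][c].y_mm,
                    "t": t,
                    "p": p,
                    "significant": p < alpha,
                }
            )
    return result
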