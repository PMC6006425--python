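"""Spatial ROC analysis of suprathreshold voxel distributions across zones.

Active voxels (statistic above a liberal p threshold within a search mask)
are ranked by activation strength; walking from the most to the least active
voxel, the curve accumulates the proportion of a *target* functional zone
filled against the proportion of the *non-target* zones filled.  The area
under this curve measures how preferentially strong voxels land in the
target zone: 1 for perfect separation, .5 for chance.  Uncertainty and
between-curve comparisons use bootstrap resampling of the ranked voxels;
polynomial trend fits summarise how normalised activation moves along a
spatial axis for two contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import world_coordinates
from .volumes import StatMap, Volume

__all__ = [
    "EmptySelectionError",
    "ZoneError",
    "RankedVoxelSet",
    "ROCCurve",
    "TrendFit",
    "select_and_rank",
    "roc_curve",
    "auc_vs_chance",
    "compare_aucs",
    "fit_spatial_trend",
]


class EmptySelectionError(ValueError):
    pass


class ZoneError(ValueError):
    pass


@dataclass
class RankedVoxelSet:
    """Suprathreshold voxels ordered by descending statistic."""

    ijk: np.ndarray              # (m, 3) voxel indices, rank order
    coords_mm: np.ndarray        # (m, 3) world coordinates, rank order
    values: np.ndarray           # (m,) statistic values, descending
    label: str = ""
    p_threshold: float = 0.01
    shape: tuple[int, int, int] | None = None

    def __len__(self) -> int:
        return len(self.values)

    @property
    def percentiles(self) -> np.ndarray:
        """Descending percentile rank (100 = most active)."""
        m = len(self.values)
        return 100.0 * (m - np.arange(m)) / m

    def linear_indices(self) -> np.ndarray:
        return np.ravel_multi_index(self.ijk.T, self.shape)


@dataclass
class ROCCurve:
    x: np.ndarray                # proportion of non-target zone filled
    y: np.ndarray                # proportion of target zone filled
    auc: float
    target: str
    values: np.ndarray = None    # in-zone ranked statistic values
    is_target: np.ndarray = None
    source_id: int = 0


def select_and_rank(
    stat_map: StatMap,
    mask: Volume | np.ndarray,
    p_threshold: float = 0.01,
    label: str = "",
) -> RankedVoxelSet:
    """Threshold a map inside a search mask and rank survivors by statistic.

    The statistic cutoff is the one-sided critical value at ``p_threshold``
    for the map's distribution (Student t at the map's df, or normal for a z
    map).  Ties are broken deterministically by voxel linear index.
    """
    mdata = mask.data if isinstance(mask, Volume) else mask
    mdata = mdata.astype(bool)
    if mdata.shape != stat_map.shape:
        raise ValueError("mask and map are not aligned")
    if stat_map.kind == "t":
        if stat_map.df is None:
            raise ValueError("t map lacks degrees of freedom")
        crit = stats.t.isf(p_threshold, stat_map.df)
    else:
        crit = stats.norm.isf(p_threshold)
    sel = mdata & (stat_map.data > crit)
    idx = np.flatnonzero(sel.reshape(-1))
    if idx.size == 0:
        raise EmptySelectionError(
            f"no voxels exceed the p<{p_threshold} threshold inside the mask"
        )
    vals = stat_map.data.reshape(-1)[idx]
    order = np.lexsort((idx, -vals))  # descending value, stable by linear index
    idx = idx[order]
    ijk = np.column_stack(np.unravel_index(idx, stat_map.shape))
    coords = world_coordinates(stat_map.shape, stat_map.affine).reshape(-1, 3)[idx]
    return RankedVoxelSet(
        ijk, coords, vals[order], label=label, p_threshold=p_threshold, shape=stat_map.shape
    )


def _zone_flags(ranked: RankedVoxelSet, zone: Volume | np.ndarray) -> np.ndarray:
    zdata = zone.data if isinstance(zone, Volume) else zone
    return zdata.astype(bool)[ranked.ijk[:, 0], ranked.ijk[:, 1], ranked.ijk[:, 2]]


def roc_curve(
    ranked: RankedVoxelSet,
    target_zone: Volume | np.ndarray,
    other_zones: dict[str, Volume | np.ndarray] | list,
    target_label: str = "target",
) -> ROCCurve:
    """Walk the ranked voxels, accumulating target vs non-target proportions.

    Voxels outside every zone are excluded from the accumulation.  The AUC is
    computed by the trapezoidal rule and equals the probability that a
    randomly chosen in-target voxel outranks a randomly chosen non-target
    voxel (ties split evenly).
    """
    zdata = target_zone.data if isinstance(target_zone, Volume) else target_zone
    if not np.asarray(zdata).astype(bool).any():
        raise ZoneError("target zone is empty")
    others = other_zones.values() if isinstance(other_zones, dict) else other_zones
    in_target = _zone_flags(ranked, target_zone)
    in_other = np.zeros(len(ranked), dtype=bool)
    for z in others:
        flags = _zone_flags(ranked, z)
        if np.any(flags & in_target):
            raise ZoneError("zones are not disjoint on the ranked set")
        in_other |= flags
    keep = in_target | in_other
    n_t = int(in_target.sum())
    n_n = int(in_other.sum())
    if n_t == 0:
        raise ZoneError("no ranked voxel falls in the target zone")
    if n_n == 0:
        raise ZoneError("no ranked voxel falls in any non-target zone")
    steps_t = in_target[keep]
    x = np.concatenate([[0.0], np.cumsum(~steps_t) / n_n])
    y = np.concatenate([[0.0], np.cumsum(steps_t) / n_t])
    auc = float(np.trapezoid(y, x))
    return ROCCurve(
        x=x,
        y=y,
        auc=auc,
        target=target_label,
        values=ranked.values[keep],
        is_target=steps_t,
        source_id=id(ranked),
    )


def _rank_auc(values: np.ndarray, is_target: np.ndarray) -> float:
    """Mann-Whitney AUC with average ranks for ties."""
    r = stats.rankdata(values)
    n_t = int(is_target.sum())
    n_n = len(values) - n_t
    return float((r[is_target].sum() - n_t * (n_t + 1) / 2.0) / (n_t * n_n))


def auc_vs_chance(curve: ROCCurve, n_boot: int = 2000, seed: int = 0):
    """Bootstrap z test of the curve's AUC against the .5 chance level.

    Resamples the in-zone ranked voxels with replacement, recomputes the AUC
    each time, and returns (z, p, se) with z = (AUC - .5) / SE and a
    two-sided normal p value.
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    if curve.is_target.sum() < 2 or (~curve.is_target).sum() < 2:
        raise ZoneError("zone sizes too small to estimate AUC variance")
    rng = np.random.default_rng(seed)
    m = len(curve.values)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, m, m)
        t = curve.is_target[idx]
        if t.all() or not t.any():
            aucs[b] = 0.5
            continue
        aucs[b] = _rank_auc(curve.values[idx], t)
    se = float(aucs.std(ddof=1))
    if se == 0:
        z = np.inf if curve.auc != 0.5 else 0.0
    else:
        z = (curve.auc - 0.5) / se
    p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
    return float(z), float(p), se


def compare_aucs(c1: ROCCurve, c2: ROCCurve, n_boot: int = 2000, seed: int = 0):
    """Paired-bootstrap test of AUC difference for curves from one ranked set.

    Both curves must have been built from the same ranked voxel set (the same
    voxels walked with different target zones); each bootstrap draw resamples
    voxels once and evaluates both AUCs on the same resample.
    Returns (z, p, se) for AUC1 - AUC2.
    """
    if c1.source_id != c2.source_id or len(c1.values) != len(c2.values):
        raise ValueError("curves were not built from the same ranked voxel set")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    rng = np.random.default_rng(seed)
    m = len(c1.values)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, m, m)
        t1, t2 = c1.is_target[idx], c2.is_target[idx]
        a1 = _rank_auc(c1.values[idx], t1) if 0 < t1.sum() < m else 0.5
        a2 = _rank_auc(c2.values[idx], t2) if 0 < t2.sum() < m else 0.5
        diffs[b] = a1 - a2
    se = float(diffs.std(ddof=1))
    d = c1.auc - c2.auc
    if se == 0:
        z = 0.0 if d == 0 else np.inf * np.sign(d)
    else:
        z = d / se
    p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
    return float(z), float(p), se


@dataclass
class TrendFit:
    label: str
    coefficients: np.ndarray     # ascending powers
    axis: str
    grid: np.ndarray
    fitted: np.ndarray


def fit_spatial_trend(
    ranked_sets: dict[str, RankedVoxelSet],
    axis: str = "y",
    degree: int = 2,
) -> dict[str, TrendFit]:
    """Least-squares polynomial of mean-corrected statistic vs coordinate.

    For each contrast's ranked voxels, fits value - mean(value) as a
    polynomial in the chosen world axis, returning coefficients and fitted
    curves on a common coordinate grid (for lateral/anterior shift
    comparisons between contrasts).
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    ax = {"x": 0, "y": 1, "z": 2}[axis]
    fits: dict[str, TrendFit] = {}
    for label, rset in ranked_sets.items():
        coord = rset.coords_mm[:, ax]
        vals = rset.values - rset.values.mean()
        if len(vals) < degree + 1:
            raise ValueError(
                f"{label}: {len(vals)} voxels cannot determine a degree-{degree} fit"
            )
        poly = np.polynomial.Polynomial.fit(coord, vals, degree).convert()
        grid = np.linspace(coord.min(), coord.max(), 101)
        fits[label] = TrendFit(label, poly.coef, axis, grid, poly(grid))
    return fits
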