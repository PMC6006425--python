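"""Spatial ROC: ranking, curve/AUC oracle equivalence, bootstrap tests, trends."""

import itertools

import numpy as np
import pytest
from scipy import stats

from gradconn.spatial_roc import (
    EmptySelectionError,
    RankedVoxelSet,
    ZoneError,
    auc_vs_chance,
    compare_aucs,
    fit_spatial_trend,
    roc_curve,
    select_and_rank,
)
from gradconn.volumes import StatMap

AFFINE = np.diag([3.0, 3.0, 3.0, 1.0])


def make_map(data, df=150):
    return StatMap(np.asarray(data, float), AFFINE, kind="t", df=df)


def line_setup(values, target_flags):
    """1-D voxel row: a ranked set plus target/non-target zone masks."""
    n = len(values)
    data = np.zeros((n, 1, 1))
    data[:, 0, 0] = values
    m = make_map(data)
    mask = np.ones((n, 1, 1), bool)
    ranked = select_and_rank(m, mask, p_threshold=0.5)
    tgt = np.zeros((n, 1, 1), bool)
    tgt[np.asarray(target_flags), 0, 0] = True
    oth = np.ones((n, 1, 1), bool) & ~tgt
    return ranked, tgt, oth


def concordance_oracle(values, is_target):
    """Brute-force pairwise concordance count / (n_T * n_N)."""
    t_vals = [v for v, f in zip(values, is_target) if f]
    n_vals = [v for v, f in zip(values, is_target) if not f]
    num = 0.0
    for tv in t_vals:
        for nv in n_vals:
            num += 1.0 if tv > nv else (0.5 if tv == nv else 0.0)
    return num / (len(t_vals) * len(n_vals))


class TestSelectAndRank:
    def test_all_zero_map_is_empty_selection(self):
        with pytest.raises(EmptySelectionError):
            select_and_rank(make_map(np.zeros((5, 5, 5))), np.ones((5, 5, 5), bool), 0.01)

    def test_rank_order(self):
        data = np.zeros((3, 1, 1))
        data[:, 0, 0] = [4.0, 5.0, 3.0]
        ranked = select_and_rank(make_map(data), np.ones((3, 1, 1), bool), 0.05)
        assert list(ranked.values) == [5.0, 4.0, 3.0]
        assert list(ranked.ijk[:, 0]) == [1, 0, 2]
        assert ranked.percentiles[0] == 100.0

    def test_null_survivor_count_within_binomial_bounds(self):
        """1000 null t voxels at p < .01: survivors within the binomial 99%
        interval around 10."""
        rng = np.random.default_rng(0)
        df = 150
        data = rng.standard_t(df, size=(10, 10, 10))
        ranked = select_and_rank(make_map(data, df=df), np.ones((10, 10, 10), bool), 0.01)
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.01)
        assert lo <= len(ranked) <= hi

    def test_mask_misalignment(self):
        with pytest.raises(ValueError, match="aligned"):
            select_and_rank(make_map(np.ones((3, 3, 3))), np.ones((4, 3, 3), bool), 0.01)


class TestROCCurve:
    def test_perfect_separation(self):
        ranked, tgt, oth = line_setup([9, 8, 7, 3, 2, 1], [0, 1, 2])
        curve = roc_curve(ranked, tgt, [oth])
        assert curve.auc == pytest.approx(1.0)
        assert (curve.x[0], curve.y[0]) == (0.0, 0.0)
        assert (curve.x[-1], curve.y[-1]) == (1.0, 1.0)

    def test_worked_four_voxel_case(self):
        """Ranks T,N,T,N: AUC from the curve equals the brute-force pairwise
        concordance 3/4."""
        ranked, tgt, oth = line_setup([9, 8, 7, 6], [0, 2])
        curve = roc_curve(ranked, tgt, [oth])
        assert curve.auc == pytest.approx(0.75)
        assert curve.auc == pytest.approx(concordance_oracle([9, 8, 7, 6], [1, 0, 1, 0]))

    def test_oracle_equivalence_random_instances(self):
        """Trapezoidal AUC equals exhaustive pairwise concordance on every
        random instance up to 200 voxels."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(4, 201))
            values = rng.permutation(n).astype(float) + 1
            flags = np.zeros(n, bool)
            flags[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = True
            if flags.all() or not flags.any():
                continue
            ranked, tgt, oth = line_setup(values, np.flatnonzero(flags))
            curve = roc_curve(ranked, tgt, [oth])
            assert curve.auc == pytest.approx(concordance_oracle(values, flags), abs=1e-12)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        values = rng.permutation(30).astype(float) + 1
        flags = np.zeros(30, bool)
        flags[:12] = True
        rng.shuffle(flags)
        r1, t1, o1 = line_setup(values, np.flatnonzero(flags))
        r2, t2, o2 = line_setup(np.exp(values / 10.0), np.flatnonzero(flags))
        assert roc_curve(r1, t1, [o1]).auc == pytest.approx(roc_curve(r2, t2, [o2]).auc)

    def test_zone_errors(self):
        ranked, tgt, oth = line_setup([5, 4, 3, 2], [0, 1])
        with pytest.raises(ZoneError, match="empty"):
            roc_curve(ranked, np.zeros((4, 1, 1), bool), [oth])
        with pytest.raises(ZoneError, match="disjoint"):
            roc_curve(ranked, tgt, [tgt])


class TestAUCvsChance:
    def test_exactly_half_gives_zero_z(self):
        ranked, tgt, oth = line_setup([4, 3, 2, 1], [0, 3])  # T,N,N,T -> AUC .5
        curve = roc_curve(ranked, tgt, [oth])
        assert curve.auc == pytest.approx(0.5)
        z, p, se = auc_vs_chance(curve, n_boot=1000, seed=0)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_perfect_toy_set_direction(self):
        values = np.arange(40, 0, -1.0)
        ranked, tgt, oth = line_setup(values, list(range(20)))
        curve = roc_curve(ranked, tgt, [oth])
        z, p, _ = auc_vs_chance(curve, n_boot=1500, seed=1)
        assert z > 3 and p < 0.005

    def test_bootstrap_se_close_to_jackknife(self):
        """Independent oracle: exhaustive leave-one-out jackknife SE."""
        rng = np.random.default_rng(5)
        n = 60
        values = rng.normal(size=n) + np.where(np.arange(n) < 25, 0.8, 0.0)
        values = values - values.min() + 1.0  # keep every voxel suprathreshold
        flags = np.arange(n) < 25
        order = rng.permutation(n)
        values, flags = values[order], flags[order]
        ranked, tgt, oth = line_setup(values, np.flatnonzero(flags))
        curve = roc_curve(ranked, tgt, [oth])
        _, _, se_boot = auc_vs_chance(curve, n_boot=4000, seed=2)
        thetas = []
        for i in range(n):
            keep = np.ones(n, bool)
            keep[i] = False
            thetas.append(concordance_oracle(values[keep], flags[keep]))
        thetas = np.array(thetas)
        se_jack = np.sqrt((n - 1) / n * np.sum((thetas - thetas.mean()) ** 2))
        assert abs(se_boot - se_jack) / se_jack < 0.25

    def test_degenerate_zone_sizes(self):
        ranked, tgt, oth = line_setup([4, 3, 2], [0])
        curve = roc_curve(ranked, tgt, [oth])
        with pytest.raises(ZoneError):
            auc_vs_chance(curve, n_boot=1000, seed=0)
        with pytest.raises(ValueError, match="n_boot"):
            auc_vs_chance(curve, n_boot=10, seed=0)


class TestCompareAUCs:
    def test_identical_curves_give_zero(self):
        ranked, tgt, oth = line_setup([6, 5, 4, 3, 2, 1], [0, 2, 4])
        c1 = roc_curve(ranked, tgt, [oth])
        z, p, _ = compare_aucs(c1, c1, n_boot=1000, seed=0)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_direction_matches_zone_preference(self):
        values = np.arange(30, 0, -1.0)
        n = 30
        zone_a = np.zeros((n, 1, 1), bool)
        zone_a[:10] = True  # holds the strongest voxels
        zone_b = np.zeros((n, 1, 1), bool)
        zone_b[20:] = True  # holds the weakest
        data = np.zeros((n, 1, 1))
        data[:, 0, 0] = values
        ranked = select_and_rank(make_map(data), np.ones((n, 1, 1), bool), 0.5)
        c_a = roc_curve(ranked, zone_a, [zone_b], "a")
        c_b = roc_curve(ranked, zone_b, [zone_a], "b")
        z, p, _ = compare_aucs(c_a, c_b, n_boot=1500, seed=0)
        assert z > 0 and c_a.auc > c_b.auc

    def test_bootstrap_p_close_to_exact_permutation(self):
        """Oracle: exact permutation over all relabelings of a small set."""
        values = np.array([10.0, 9, 8, 7, 6, 5, 4, 3])
        flags_a = np.array([1, 1, 0, 1, 0, 0, 0, 0], bool)  # target A prefers top
        flags_b = ~flags_a
        ranked, tgt, oth = line_setup(values, np.flatnonzero(flags_a))
        c_a = roc_curve(ranked, tgt, [oth], "a")
        c_b = roc_curve(ranked, oth, [tgt], "b")
        z, p_boot, _ = compare_aucs(c_a, c_b, n_boot=4000, seed=3)
        observed = c_a.auc - c_b.auc
        count = 0
        total = 0
        for combo in itertools.combinations(range(8), int(flags_a.sum())):
            fa = np.zeros(8, bool)
            fa[list(combo)] = True
            d = concordance_oracle(values, fa) - concordance_oracle(values, ~fa)
            total += 1
            if abs(d) >= abs(observed) - 1e-12:
                count += 1
        p_exact = count / total
        assert abs(p_boot - p_exact) < 0.2

    def test_mismatched_sources_raise(self):
        r1, t1, o1 = line_setup([5, 4, 3, 2], [0, 1])
        r2, t2, o2 = line_setup([5, 4, 3, 2], [0, 1])
        c1 = roc_curve(r1, t1, [o1])
        c2 = roc_curve(r2, t2, [o2])
        with pytest.raises(ValueError, match="same ranked"):
            compare_aucs(c1, c2, n_boot=1000, seed=0)


class TestSpatialTrend:
    def _ranked_from(self, coords_y, values):
        n = len(values)
        ijk = np.column_stack([np.zeros(n, int), np.arange(n), np.zeros(n, int)])
        coords = np.column_stack([np.zeros(n), coords_y, np.zeros(n)])
        order = np.argsort(-np.asarray(values))
        return RankedVoxelSet(
            ijk[order], coords[order], np.asarray(values, float)[order], shape=(1, n, 1)
        )

    def test_linear_field_slope_recovered(self):
        y = np.linspace(-60, 0, 80)
        vals = 0.35 * y + 5.0
        fits = fit_spatial_trend({"c": self._ranked_from(y, vals)}, axis="y", degree=1)
        assert fits["c"].coefficients[1] == pytest.approx(0.35, rel=0.01)

    def test_constant_field_gives_zero_coefficients(self):
        y = np.linspace(-60, 0, 50)
        fits = fit_spatial_trend({"c": self._ranked_from(y, np.full(50, 3.3))}, "y", 2)
        assert np.allclose(fits["c"].coefficients, 0.0, atol=1e-8)

    def test_offset_contrasts_ordered(self):
        rng = np.random.default_rng(0)
        y = np.linspace(-60, 0, 100)
        a = -((y + 45) ** 2) / 100 + rng.normal(0, 0.1, 100)
        b = -((y + 15) ** 2) / 100 + rng.normal(0, 0.1, 100)
        fits = fit_spatial_trend(
            {"posterior": self._ranked_from(y, a), "anterior": self._ranked_from(y, b)},
            axis="y",
            degree=2,
        )
        peak_post = fits["posterior"].grid[np.argmax(fits["posterior"].fitted)]
        peak_ant = fits["anterior"].grid[np.argmax(fits["anterior"].fitted)]
        assert peak_post < peak_ant  # anterior shift recovered

    def test_underdetermined(self):
        with pytest.raises(ValueError, match="degree"):
            fit_spatial_trend({"c": self._ranked_from([0.0, 1.0], [1.0, 2.0])}, "y", 3)
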