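import numpy as np
import pytest

from ssmpca.imageio import BrainMask
from ssmpca.ssm import ZPattern, build_difference_matrix
from ssmpca.simulate import SimulationConfig, simulate_cohort
from ssmpca.stats import (
    ThresholdedMap,
    bootstrap_division_icc,
    cluster_filter,
    critical_t,
    dice,
    icc,
    pattern_similarity,
    threshold_match,
    two_sample_t,
    voxelwise_ttest,
)


class TestTwoSampleT:
    def test_hand_computed_pooled_t(self):
        """Groups (2,4) vs (1,3): pooled variance 2, t = 1/√2, df = 2."""
        res = two_sample_t(np.array([2.0, 4, 1, 3]), ["EC-EO"] * 2 + ["EO-EC"] * 2)
        assert abs(res.t - 1 / np.sqrt(2)) < 1e-12
        assert res.df == 2
        assert abs(res.d - 1 / np.sqrt(2)) < 1e-12
        assert res.group_means == (3.0, 2.0)

    def test_tail_probability_matches_printed_value(self):
        """A separation engineered to give t = 2.95 at n = 11/10 yields the
        two-tailed p = 0.0082."""
        base11 = np.arange(11) - 5.0
        base11 /= base11.std(ddof=1)
        base10 = np.arange(10) - 4.5
        base10 /= base10.std(ddof=1)
        delta = 2.95 * np.sqrt(1 / 11 + 1 / 10)
        values = np.concatenate([base11 + delta, base10])
        res = two_sample_t(values, ["EC-EO"] * 11 + ["EO-EC"] * 10)
        assert abs(res.t - 2.95) < 1e-12
        assert res.df == 19
        assert round(res.p, 4) == 0.0082

    def test_identical_means_give_t_zero_p_one(self):
        res = two_sample_t(np.array([1.0, 2, 1, 2]), ["EC-EO"] * 2 + ["EO-EC"] * 2)
        assert res.t == 0
        assert res.p == 1

    def test_label_swap_flips_sign_keeps_p(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(9)
        labels = ["EC-EO"] * 5 + ["EO-EC"] * 4
        flipped = ["EO-EC" if l == "EC-EO" else "EC-EO" for l in labels]
        a, b = two_sample_t(v, labels), two_sample_t(v, flipped)
        assert abs(a.t + b.t) < 1e-12
        assert abs(a.p - b.p) < 1e-12

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            two_sample_t(np.array([1.0, 2, 3]), ["EC-EO", "EO-EC", "EO-EC"])
        with pytest.raises(ValueError, match="pooled variance"):
            two_sample_t(np.array([1.0, 1, 2, 2]), ["EC-EO"] * 2 + ["EO-EC"] * 2)


def test_critical_t_df19():
    assert round(critical_t(19), 2) == 2.09


class TestIcc:
    def test_perfect_agreement(self):
        res = icc([1.0, 2, 3], [1.0, 2, 3])
        assert res.wms == 0
        assert res.icc == 1

    def test_hand_computed_anova(self):
        """Pairs (1,2),(2,1),(3,3): BMS = 1.5, WMS = 1/3, ICC = 7/11."""
        res = icc([1.0, 2, 3], [2.0, 1, 3])
        assert abs(res.bms - 1.5) < 1e-12
        assert abs(res.wms - 1 / 3) < 1e-12
        assert abs(res.icc - 7 / 11) < 1e-12

    def test_anticorrelated_ratings(self):
        res = icc([1.0, 2, 3], [3.0, 2, 1])
        assert res.bms == 0
        assert res.icc == -1

    def test_invariances(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(10), rng.standard_normal(10)
        base = icc(x, y).icc
        assert abs(icc(y, x).icc - base) < 1e-12  # swap ratings
        assert abs(icc(x + 5, y + 5).icc - base) < 1e-12  # shift
        assert abs(icc(3 * x, 3 * y).icc - base) < 1e-12  # positive scaling

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            icc([1.0, 2], [1.0, 2])
        with pytest.raises(ValueError, match="identical"):
            icc([2.0, 2, 2], [2.0, 2, 2])


class TestPatternSimilarity:
    def test_identity_and_flip(self):
        rng = np.random.default_rng(2)
        p = rng.standard_normal(100)
        same = pattern_similarity(p, p)
        assert same.r == pytest.approx(1.0) and not same.flipped
        anti = pattern_similarity(p, -p)
        assert anti.r == pytest.approx(1.0) and anti.flipped

    def test_noise_attenuation_matches_closed_form(self):
        """corr(p, p + n/SNR) → SNR/√(1+SNR²) for unit-variance p, n."""
        rng = np.random.default_rng(3)
        snr = 2.0
        p = rng.standard_normal(20000)
        q = p + rng.standard_normal(20000) / snr
        expected = snr / np.sqrt(1 + snr**2)
        assert abs(pattern_similarity(p, q).r - expected) < 0.02

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pattern_similarity(np.ones(5), np.arange(5.0))


class TestVoxelwiseT:
    @pytest.fixture
    def mask(self):
        return BrainMask(np.ones((4, 3, 2)))

    def test_equal_groups_give_zero_map(self, mask):
        from ssmpca.ssm import DataMatrix

        x = np.tile(np.array([1.0, 2, 1, 2]), (24, 1))
        data = DataMatrix(x, mask, list("abcd"), ["EC-EO"] * 2 + ["EO-EC"] * 2)
        t, df = voxelwise_ttest(data)
        assert np.allclose(t, 0)
        assert df == 2

    def test_matches_scalar_test_per_voxel(self, mask):
        from ssmpca.ssm import DataMatrix

        rng = np.random.default_rng(4)
        x = rng.standard_normal((24, 7))
        labels = ["EC-EO"] * 4 + ["EO-EC"] * 3
        data = DataMatrix(x, mask, [f"s{i}" for i in range(7)], labels)
        t, df = voxelwise_ttest(data)
        for i in (0, 11, 23):
            scalar = two_sample_t(x[i], labels)
            assert abs(t[i] - scalar.t) < 1e-12
            assert df == scalar.df

    def test_zero_variance_voxel_flagged(self, mask):
        from ssmpca.ssm import DataMatrix

        rng = np.random.default_rng(5)
        x = rng.standard_normal((24, 4))
        x[3] = 1.0
        data = DataMatrix(x, mask, list("abcd"), ["EC-EO"] * 2 + ["EO-EC"] * 2)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            t, _ = voxelwise_ttest(data)
        assert t[3] == 0


def brute_force_components(grid: np.ndarray, connectivity: int) -> list[set]:
    """Independent flood-fill over explicit neighbour offsets."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    seen = set()
    comps = []
    voxels = set(map(tuple, np.argwhere(grid)))
    for start in sorted(voxels):
        if start in seen:
            continue
        comp, queue = set(), [start]
        while queue:
            v = queue.pop()
            if v in comp:
                continue
            comp.add(v)
            for o in offsets:
                w = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
                if w in voxels and w not in comp:
                    queue.append(w)
        seen |= comp
        comps.append(comp)
    return comps


class TestClusterFilter:
    @pytest.fixture
    def mask(self):
        return BrainMask(np.ones((6, 6, 6)))

    def test_small_cluster_removed(self, mask):
        grid = np.zeros((6, 6, 6), bool)
        grid[0, 0, :5] = True  # 5-voxel line
        binary = grid.ravel(order="F")[mask._flat]
        out = cluster_filter(binary, mask, cluster_min=6)
        assert out.survivor_count == 0

    def test_cluster_min_one_is_identity(self, mask):
        rng = np.random.default_rng(6)
        binary = rng.random(mask.n_voxels) > 0.6
        out = cluster_filter(binary, mask, cluster_min=1)
        assert np.array_equal(out.binary, binary)

    def test_mixed_sizes_26_connectivity(self, mask):
        grid = np.zeros((6, 6, 6), bool)
        grid[0, 0, 0:3] = True  # size 3
        grid[3:5, 3:5, 3:5] = True  # size 8
        grid[5, 5, 5] = True  # touches the cube diagonally → size 9 + 1
        binary = grid.ravel(order="F")[mask._flat]
        out = cluster_filter(binary, mask, cluster_min=5, connectivity=26)
        survivors = mask.unflatten_indicator(out.binary)
        assert not survivors[0, 0, 0:3].any()
        assert survivors.sum() == 9

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, mask, connectivity):
        rng = np.random.default_rng(7)
        for _ in range(5):
            grid = rng.random((6, 6, 6)) > 0.7
            binary = grid.ravel(order="F")[mask._flat]
            out = cluster_filter(binary, mask, 4, connectivity)
            expected = set()
            for comp in brute_force_components(grid, connectivity):
                if len(comp) >= 4:
                    expected |= comp
            got = set(map(tuple, np.argwhere(mask.unflatten_indicator(out.binary))))
            assert got == expected


def make_zpattern(values: np.ndarray, mask: BrainMask) -> ZPattern:
    z = (values - values.mean()) / values.std(ddof=1)
    return ZPattern(z=z, source_component=0, mask=mask)


class TestThresholdMatch:
    @pytest.fixture
    def mask200(self):
        return BrainMask(np.ones((10, 5, 4)))  # 200 voxels

    def test_top_k_with_distinct_values(self, mask200):
        rng = np.random.default_rng(8)
        z = make_zpattern(rng.permutation(200).astype(float), mask200)
        out = threshold_match(z, cluster_min=1, target_count=10)
        assert out.survivor_count == 10
        top10 = np.argsort(np.abs(z.z))[-10:]
        assert set(np.flatnonzero(out.binary)) == set(top10)

    def test_target_all_voxels(self, mask200):
        rng = np.random.default_rng(9)
        z = make_zpattern(rng.standard_normal(200), mask200)
        out = threshold_match(z, cluster_min=1, target_count=200)
        assert out.survivor_count == 200
        assert out.threshold <= np.abs(z.z).min()

    def test_never_exceeds_target_and_matches_sweep(self, mask200):
        """Exhaustive sweep oracle: survivor count is monotone in the
        threshold, and the returned cut is the best feasible one."""
        rng = np.random.default_rng(10)
        for cluster_min in (1, 4):
            z = make_zpattern(np.round(rng.standard_normal(200), 1), mask200)
            counts = []
            for theta in np.unique(np.abs(z.z))[::-1]:
                counts.append(
                    cluster_filter(
                        np.abs(z.z) >= theta, mask200, cluster_min
                    ).survivor_count
                )
            assert np.all(np.diff(counts) >= 0)  # monotone as θ decreases
            for target in (0, 7, 50, 120, 200):
                out = threshold_match(z, cluster_min, target)
                assert out.survivor_count <= target
                feasible = [c for c in counts if c <= target]
                best = max(feasible) if feasible else 0
                assert out.survivor_count == best

    def test_overshoot_returns_empty(self, mask200):
        rng = np.random.default_rng(11)
        values = np.repeat(rng.standard_normal(20), 10)  # heavily tied
        z = make_zpattern(values, mask200)
        out = threshold_match(z, cluster_min=1, target_count=3)
        assert out.survivor_count <= 3


class TestDice:
    @pytest.fixture
    def mask(self):
        return BrainMask(np.ones((4, 4, 2)))

    def tmap(self, mask, binary):
        return ThresholdedMap(np.asarray(binary, bool), mask, 0.0, 1)

    def test_identity_symmetry_disjoint(self, mask):
        rng = np.random.default_rng(12)
        a = rng.random(32) > 0.5
        b = rng.random(32) > 0.5
        ta, tb = self.tmap(mask, a), self.tmap(mask, b)
        assert dice(ta, ta) == 1.0
        assert dice(ta, tb) == dice(tb, ta)
        disjoint = self.tmap(mask, ~a)
        assert dice(ta, disjoint) == 0.0

    def test_known_overlap(self, mask):
        a = np.zeros(32, bool)
        b = np.zeros(32, bool)
        a[:4] = True
        b[2:6] = True
        assert dice(self.tmap(mask, a), self.tmap(mask, b)) == 0.5

    def test_both_empty_is_zero_with_warning(self, mask):
        empty = self.tmap(mask, np.zeros(32, bool))
        with pytest.warns(RuntimeWarning, match="empty"):
            assert dice(empty, empty) == 0.0

    def test_dice_one_iff_equal(self, mask):
        rng = np.random.default_rng(13)
        a = rng.random(32) > 0.5
        b = a.copy()
        b[np.flatnonzero(a)[0]] = False
        assert dice(self.tmap(mask, a), self.tmap(mask, b)) < 1.0

    def test_mask_mismatch_rejected(self, mask):
        other = BrainMask(np.ones((4, 2, 2)))
        with pytest.raises(ValueError, match="mask"):
            dice(self.tmap(mask, np.ones(32, bool)),
                 ThresholdedMap(np.ones(16, bool), other, 0.0, 1))


@pytest.fixture(scope="module")
def diff_by_visit():
    cfg = SimulationConfig.from_targets(
        0.6, 1.2, grid_shape=(10, 12, 10), n_visits=2,
        scanner_gain=(1.0, 1.0), seed=21,
    )
    cohort = simulate_cohort(cfg)
    return {
        v: build_difference_matrix(
            cohort.manifest, v, cohort.mask, volumes=cohort.maps, signed=False
        )
        for v in ("V1", "V2")
    }, cfg


class TestBootstrap:
    def test_single_iteration_ci_collapses(self, diff_by_visit):
        diff, _ = diff_by_visit
        out = bootstrap_division_icc(diff, (11, 10), n_iter=1, seed=0)
        s = out[("V1", "V2")]
        assert len(s.values) == 1
        assert s.ci95 == (s.values[0], s.values[0])

    def test_seed_reproducibility(self, diff_by_visit):
        diff, _ = diff_by_visit
        a = bootstrap_division_icc(diff, (11, 10), n_iter=5, seed=42)
        b = bootstrap_division_icc(diff, (11, 10), n_iter=5, seed=42)
        assert np.array_equal(a[("V1", "V2")].values, b[("V1", "V2")].values)

    def test_recovers_planted_reliability(self, diff_by_visit):
        """Random-division bootstrap mean ICC within ±0.1 of the planted 0.6."""
        diff, cfg = diff_by_visit
        out = bootstrap_division_icc(diff, (11, 10), n_iter=200, seed=1)
        assert abs(out[("V1", "V2")].mean - cfg.true_icc) < 0.1

    def test_subject_mismatch_rejected(self, diff_by_visit):
        diff, _ = diff_by_visit
        from ssmpca.ssm import DataMatrix

        bad = diff["V2"]
        renamed = DataMatrix(bad.values, bad.mask, [s + "x" for s in bad.subject_ids])
        with pytest.raises(ValueError, match="subject"):
            bootstrap_division_icc({"V1": diff["V1"], "V2": renamed}, (11, 10), 2, 0)
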