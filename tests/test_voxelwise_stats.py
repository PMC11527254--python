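from itertools import combinations

import numpy as np
import pytest

from lesionmap.volume_core import UsageError, VoxelGrid
from lesionmap.voxelwise_stats import (
    CONTRAST_NAMES,
    ObservationSet,
    fstats_2x2,
    permutation_fmap,
    permutation_pmap,
    permutation_tmap,
    pooled_t,
    posthoc_contrasts,
    ttest_map,
)


def make_obs(cell_values: dict, n_voxels: int = 1) -> ObservationSet:
    """Build a tiny ObservationSet; cell_values maps (side, treatment) to a
    list of observation values (replicated across voxels)."""
    rows, sides, treats, ids = [], [], [], []
    counters = {"ipsi": 0, "contra": 0}
    for (side, treat), values in cell_values.items():
        for v in values:
            rows.append(np.full(n_voxels, float(v)))
            sides.append(side)
            treats.append(treat)
            # pair the j-th ipsi row with the j-th contra row (bookkeeping only)
            ids.append(f"s{counters[side]}")
            counters[side] += 1
    mask = np.zeros((n_voxels, 1, 1), dtype=bool)
    mask[:, 0, 0] = True
    grid = VoxelGrid((n_voxels, 1, 1), (1.0, 1.0, 1.0))
    return ObservationSet(np.array(rows), np.array(sides), np.array(treats),
                          np.array(ids), mask, grid)


def anova_2x2_oracle(cells: dict) -> dict:
    """Independent two-way ANOVA for a balanced 2x2 design via explicit
    sums of squares."""
    ys = {k: np.asarray(v, float) for k, v in cells.items()}
    n = len(next(iter(ys.values())))
    means = {k: v.mean() for k, v in ys.items()}
    grand = np.mean([v for y in ys.values() for v in y])
    a_levels = sorted({k[0] for k in ys})
    b_levels = sorted({k[1] for k in ys})
    mean_a = {a: np.mean([means[(a, b)] for b in b_levels]) for a in a_levels}
    mean_b = {b: np.mean([means[(a, b)] for a in a_levels]) for b in b_levels}
    ss_a = 2 * n * sum((mean_a[a] - grand) ** 2 for a in a_levels)
    ss_b = 2 * n * sum((mean_b[b] - grand) ** 2 for b in b_levels)
    ss_ab = n * sum(
        (means[(a, b)] - mean_a[a] - mean_b[b] + grand) ** 2
        for a in a_levels
        for b in b_levels
    )
    ss_err = sum(((ys[k] - means[k]) ** 2).sum() for k in ys)
    df_err = 4 * n - 4
    return {
        "A": ss_a / (ss_err / df_err),
        "B": ss_b / (ss_err / df_err),
        "AB": ss_ab / (ss_err / df_err),
    }


class TestFstats:
    def test_constant_data_gives_zero_f(self):
        obs = make_obs({
            ("ipsi", "lesion"): [3, 3], ("contra", "lesion"): [3, 3],
            ("ipsi", "vehicle"): [3, 3], ("contra", "vehicle"): [3, 3],
        })
        out = fstats_2x2(obs)
        for eff in ("side", "treatment", "interaction"):
            assert out[eff].values[0, 0, 0] == pytest.approx(0.0)

    def test_hand_computed_oracle(self):
        cells = {
            ("ipsi", "lesion"): [1, 2], ("contra", "lesion"): [5, 6],
            ("ipsi", "vehicle"): [1, 2], ("contra", "vehicle"): [5, 6],
        }
        obs = make_obs(cells)
        out = fstats_2x2(obs)
        oracle = anova_2x2_oracle(
            {(s, t): v for (s, t), v in cells.items()}
        )
        assert out["interaction"].values[0, 0, 0] == pytest.approx(0.0, abs=1e-9)
        assert out["side"].values[0, 0, 0] == pytest.approx(oracle["A"])
        assert out["treatment"].values[0, 0, 0] == pytest.approx(oracle["B"], abs=1e-9)

    def test_random_balanced_matches_oracle(self, rng):
        cells = {
            (s, t): rng.normal(size=3)
            for s in ("ipsi", "contra")
            for t in ("lesion", "vehicle")
        }
        obs = make_obs({k: list(v) for k, v in cells.items()})
        out = fstats_2x2(obs)
        oracle = anova_2x2_oracle(cells)
        assert out["side"].values[0, 0, 0] == pytest.approx(oracle["A"])
        assert out["treatment"].values[0, 0, 0] == pytest.approx(oracle["B"])
        assert out["interaction"].values[0, 0, 0] == pytest.approx(oracle["AB"])

    def test_unbalanced_matches_statsmodels_type3(self, rng):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rows = []
        data = {}
        counts = {("ipsi", "lesion"): 3, ("contra", "lesion"): 3,
                  ("ipsi", "vehicle"): 2, ("contra", "vehicle"): 2}
        for (s, t), k in counts.items():
            data[(s, t)] = list(rng.normal(size=k))
            for v in data[(s, t)]:
                rows.append(dict(side=s, treat=t, y=v))
        df = pd.DataFrame(rows)
        model = ols("y ~ C(side, Sum) * C(treat, Sum)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=3)

        # build the observation matrix directly (pairing invariant bypassed)
        from lesionmap.voxelwise_stats import _codes, _f_from_labels

        side = np.array([r["side"] for r in rows])
        treat = np.array([r["treat"] for r in rows])
        Y = np.array([[r["y"]] for r in rows])
        fs = _f_from_labels(Y, _codes(side, "ipsi"), _codes(treat, "lesion"))
        assert fs["side"][0] == pytest.approx(table.loc["C(side, Sum)", "F"])
        assert fs["treatment"][0] == pytest.approx(table.loc["C(treat, Sum)", "F"])
        assert fs["interaction"][0] == pytest.approx(
            table.loc["C(side, Sum):C(treat, Sum)", "F"]
        )

    def test_treatment_relabel_leaves_interaction_invariant(self, rng):
        cells = {
            (s, t): list(rng.normal(size=2))
            for s in ("ipsi", "contra")
            for t in ("lesion", "vehicle")
        }
        swapped = {
            (s, "lesion" if t == "vehicle" else "vehicle"): v
            for (s, t), v in cells.items()
        }
        f1 = fstats_2x2(make_obs(cells))["interaction"].values[0, 0, 0]
        f2 = fstats_2x2(make_obs(swapped))["interaction"].values[0, 0, 0]
        assert f1 == pytest.approx(f2)

    def test_small_cell_rejected(self):
        obs = make_obs({
            ("ipsi", "lesion"): [1, 2], ("contra", "lesion"): [1, 2],
            ("ipsi", "vehicle"): [1, 2], ("contra", "vehicle"): [1, 2],
        })
        obs.treatment[:] = "lesion"
        with pytest.raises(UsageError):
            fstats_2x2(obs)


class TestTtest:
    def test_closed_form(self):
        t = pooled_t(np.array([[1.0], [2.0], [3.0]]), np.array([[4.0], [5.0], [6.0]]))
        assert t[0] == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0))
        assert t[0] == pytest.approx(-3.6742, abs=1e-4)

    def test_identical_means_zero(self):
        t, sign = ttest_map(np.array([[1.0], [2.0]]), np.array([[2.0], [1.0]]))
        assert t[0] == pytest.approx(0.0)
        assert sign[0] == 0

    def test_location_invariance(self, rng):
        A = rng.normal(size=(4, 5))
        B = rng.normal(size=(3, 5))
        t1 = pooled_t(A, B)
        t2 = pooled_t(A + 7.3, B + 7.3)
        np.testing.assert_allclose(t1, t2, atol=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(UsageError):
            pooled_t(np.array([[1.0]]), np.array([[1.0], [2.0]]))


def brute_force_two_group_p(a, b):
    """Exact two-sided permutation p over all group assignments, computed
    with an independent t formula."""
    pooled = np.concatenate([a, b])
    na = len(a)
    idx = range(len(pooled))

    def abs_t(x, y):
        mx, my = np.mean(x), np.mean(y)
        vx = np.sum((x - mx) ** 2)
        vy = np.sum((y - my) ** 2)
        s2 = (vx + vy) / (len(x) + len(y) - 2)
        se = np.sqrt(s2 * (1 / len(x) + 1 / len(y)))
        if se == 0:
            return 0.0 if mx == my else np.inf
        return abs((mx - my) / se)

    observed = abs_t(a, b)
    count = 0
    total = 0
    for pos in combinations(idx, na):
        sel = np.zeros(len(pooled), bool)
        sel[list(pos)] = True
        stat = abs_t(pooled[sel], pooled[~sel])
        count += stat >= observed - 1e-12
        total += 1
    return count / total


class TestPermutation:
    def test_extreme_case_minimum_p(self, rng):
        # unequal groups: the mirror assignment is not reachable, so an
        # observed statistic exceeding all permutations attains the floor
        a = np.array([[10.0], [11.0], [12.0], [13.0]])
        b = np.array([[0.0], [1.0], [2.0]])
        sm = permutation_tmap(a, b, n_perm=1000, seed=0)
        n_used = sm.metadata["n_perm"]
        assert sm.p[0] == pytest.approx(1.0 / (1 + n_used))

    def test_exact_enumeration_matches_brute_force_3v3(self):
        a = np.array([1.0, 2.4, 3.1])
        b = np.array([4.0, 5.5, 6.2])
        sm = permutation_tmap(a[:, None], b[:, None], n_perm=1000, seed=0)
        assert sm.metadata["estimator"] == "exact"
        assert sm.p[0] == pytest.approx(brute_force_two_group_p(a, b))

    def test_exchangeable_null_p_one(self):
        a = np.array([[1.0], [2.0], [3.0]])
        b = np.array([[1.0], [2.0], [3.0]])
        sm = permutation_tmap(a, b, n_perm=1000, seed=0)
        assert sm.p[0] == pytest.approx(1.0)

    def test_monte_carlo_all_but_identity_equals_exact(self, rng):
        # sampled estimator with n_perm = N-1 must agree with enumeration
        a = rng.normal(size=3)
        b = rng.normal(size=3) + 2.0
        exact = permutation_tmap(a[:, None], b[:, None], n_perm=19, seed=0)
        assert exact.metadata["estimator"] == "exact"
        assert exact.p[0] == pytest.approx(brute_force_two_group_p(a, b))

    def test_fmap_exact_enumeration(self, rng):
        cells = {
            ("ipsi", "lesion"): [1.0, 2.0], ("contra", "lesion"): [5.0, 6.0],
            ("ipsi", "vehicle"): [1.5, 2.5], ("contra", "vehicle"): [5.5, 6.5],
        }
        obs = make_obs(cells)
        sm = permutation_fmap(obs, "side", n_perm=100, seed=0)
        assert sm.metadata["estimator"] == "exact"  # C(8,4)-1 = 69 <= 100

        # brute-force oracle over all C(8,4) side assignments
        from lesionmap.voxelwise_stats import _codes, _f_from_labels

        Y = obs.data
        treat_pm = _codes(obs.treatment, "lesion")
        side_pm = _codes(obs.side, "ipsi")
        observed = _f_from_labels(Y, side_pm, treat_pm)["side"][0]
        count = 0
        total = 0
        for pos in combinations(range(8), 4):
            assign = -np.ones(8)
            assign[list(pos)] = 1.0
            stat = _f_from_labels(Y, assign, treat_pm)["side"][0]
            count += stat >= observed - 1e-12
            total += 1
        assert sm.p[0] == pytest.approx(count / total)

    def test_determinism(self, rng):
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3))
        p1 = permutation_tmap(a, b, n_perm=200, seed=42).p
        p2 = permutation_tmap(a, b, n_perm=200, seed=42).p
        np.testing.assert_array_equal(p1, p2)

    def test_bad_n_perm(self):
        with pytest.raises(UsageError):
            permutation_tmap(np.zeros((2, 1)), np.zeros((2, 1)), n_perm=0)

    def test_dispatcher(self):
        obs = make_obs({
            ("ipsi", "lesion"): [1, 2], ("contra", "lesion"): [5, 6],
            ("ipsi", "vehicle"): [1, 2], ("contra", "vehicle"): [5, 6],
        })
        sm = permutation_pmap(obs, "F_interaction", n_perm=50, seed=1)
        assert sm.metadata["contrast"] == "F_interaction"
        with pytest.raises(UsageError):
            permutation_pmap(obs, "t_contrast", n_perm=50)


class TestPosthoc:
    def make_full_obs(self, rng, n_voxels=30, n_per_group=3, effect=0.0):
        rows, sides, treats, ids = [], [], [], []
        for t in ("lesion", "vehicle"):
            for i in range(n_per_group):
                base = rng.normal(size=n_voxels)
                for side in ("ipsi", "contra"):
                    shift = effect if (side == "ipsi" and t == "lesion") else 0.0
                    rows.append(base + rng.normal(size=n_voxels) + shift)
                    sides.append(side)
                    treats.append(t)
                    ids.append(f"{t}{i}")
        mask = np.zeros((n_voxels, 1, 1), bool)
        mask[:, 0, 0] = True
        grid = VoxelGrid((n_voxels, 1, 1), (1.0, 1.0, 1.0))
        return ObservationSet(np.array(rows), np.array(sides), np.array(treats),
                              np.array(ids), mask, grid)

    def test_four_contrasts_with_expected_names(self, rng):
        obs = self.make_full_obs(rng, effect=3.0)
        anova = {e: permutation_fmap(obs, e, n_perm=100, seed=0)
                 for e in ("side", "treatment", "interaction")}
        out = posthoc_contrasts(obs, anova, n_perm=100, seed=0)
        assert set(out) == set(CONTRAST_NAMES)

    def test_gating_excludes_nonsignificant_voxels(self, rng):
        obs = self.make_full_obs(rng, effect=0.0)
        anova = {e: permutation_fmap(obs, e, n_perm=100, seed=0)
                 for e in ("side", "treatment", "interaction")}
        out = posthoc_contrasts(obs, anova, alpha=1e-9, n_perm=100, seed=0)
        for sm in out.values():
            assert not sm.gate.any()
            np.testing.assert_array_equal(sm.p, 1.0)

    def test_support_subset_of_anova_significant(self, rng):
        obs = self.make_full_obs(rng, effect=2.0)
        anova = {e: permutation_fmap(obs, e, n_perm=100, seed=0)
                 for e in ("side", "treatment", "interaction")}
        union = np.logical_or.reduce([m.p < 0.05 for m in anova.values()])
        out = posthoc_contrasts(obs, anova, n_perm=100, seed=0)
        for sm in out.values():
            assert np.all(union[sm.gate])
            assert np.all(sm.p[~sm.gate] == 1.0)
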