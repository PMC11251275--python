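import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from rubikit.stats import (
    compare_groups,
    dunn_test,
    kruskal_wallis,
    mann_whitney_u,
    median_iqr,
    q10_correct,
)
from rubikit.synthetic import (
    FIG2_CARBOXYSOME,
    FIG2_CLADE,
    FIG2_TROPHIC,
    default_panel_groups,
    sample_group_rates,
    simulate_panel,
)


class TestMedianIqr:
    def test_simple(self):
        assert median_iqr([1, 2, 3, 4, 5]) == (3.0, 2.0, 4.0)

    def test_singleton(self):
        assert median_iqr([5]) == (5.0, 5.0, 5.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])

    def test_lognormal_roundtrip_alpha_group(self):
        # alpha-cyano spec: 9.8 [8.6-10.5]
        draws = sample_group_rates(9.8, 8.6, 10.5, 100_000, seed=0)
        med, q1, q3 = median_iqr(draws)
        assert abs(med - 9.8) / 9.8 < 0.03
        # IQR width (not individual quartiles) is what the sampler matches
        assert abs((q3 - q1) - 1.9) / 1.9 < 0.05


def enumerate_mw_p(x, y):
    """Brute-force two-sided exact p over all group assignments of ranks."""
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    n = len(x)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    total = lo = hi = 0
    for idx in combinations(range(len(pooled)), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2
        total += 1
        if u <= u_obs + 1e-9:
            lo += 1
        if u >= u_obs - 1e-9:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


class TestMannWhitney:
    def test_separated_samples(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u == 0.0
        assert res.method == "exact"
        np.testing.assert_allclose(res.p_value, 0.1)

    def test_identical_multisets(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney_u(x, x)
        assert res.u == len(x) ** 2 / 2
        assert res.p_value == 1.0

    def test_exact_matches_enumeration_random(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            nx, ny = rng.integers(2, 7, size=2)
            x = rng.normal(size=nx)
            y = rng.normal(size=ny)
            res = mann_whitney_u(x, y)
            assert res.method == "exact"
            np.testing.assert_allclose(res.p_value, enumerate_mw_p(x, y),
                                       atol=1e-12)

    def test_all_identical_warns_p_one(self):
        with pytest.warns(UserWarning):
            res = mann_whitney_u([2.0, 2.0], [2.0, 2.0, 2.0],
                                 mode="asymptotic")
        assert res.p_value == 1.0

    def test_asymptotic_close_to_scipy(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.7, 1, 45)
        res = mann_whitney_u(x, y, mode="asymptotic")
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="asymptotic")
        np.testing.assert_allclose(res.p_value, ref.pvalue, rtol=1e-8)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=6)
        y = rng.normal(size=5)
        r1 = mann_whitney_u(x, y)
        r2 = mann_whitney_u(np.exp(x), np.exp(y))
        assert r1.u == r2.u
        assert r1.p_value == r2.p_value

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_mode_validation(self):
        with pytest.raises(ValueError):
            mann_whitney_u([1], [2], mode="bogus")


def textbook_kw_h(groups):
    """Independent oracle: H = 12/(N(N+1)) sum R_i^2/n_i - 3(N+1), with
    the tie correction 1 - sum(t^3-t)/(N^3-N)."""
    pooled = np.concatenate(groups)
    ranks = scipy.stats.rankdata(pooled)
    N = len(pooled)
    h = 0.0
    pos = 0
    for g in groups:
        r = ranks[pos:pos + len(g)]
        h += r.sum() ** 2 / len(g)
        pos += len(g)
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    corr = 1 - np.sum(counts ** 3 - counts) / (N ** 3 - N)
    return h / corr


class TestKruskalWallis:
    def test_identical_groups(self):
        with pytest.warns(UserWarning):
            res = kruskal_wallis([[2, 2, 2], [2, 2, 2], [2, 2, 2]])
        assert res.h == 0.0
        assert res.p_value == 1.0

    def test_hand_checked_h(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        res = kruskal_wallis(groups)
        np.testing.assert_allclose(res.h, 7.2)
        np.testing.assert_allclose(res.h, textbook_kw_h(groups))
        np.testing.assert_allclose(res.p_value, scipy.stats.chi2.sf(7.2, 2))

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(4)
        groups = [rng.integers(0, 6, size=n).astype(float)
                  for n in (8, 11, 9)]
        res = kruskal_wallis(groups)
        ref = scipy.stats.kruskal(*groups)
        np.testing.assert_allclose(res.h, ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(res.p_value, ref.pvalue, rtol=1e-10)

    def test_group_order_invariance(self):
        groups = [[1.0, 5.0], [2.0, 7.0, 3.0], [9.0, 4.0]]
        r1 = kruskal_wallis(groups)
        r2 = kruskal_wallis(groups[::-1])
        np.testing.assert_allclose(r1.h, r2.h)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], [], [3]])


class TestDunn:
    def test_identical_groups_all_p_one(self):
        res = dunn_test([[3, 3, 3], [3, 3, 3], [3, 3, 3]])
        assert all(p == 1.0 for p in res.p_adjusted)
        assert all(z == 0.0 for z in res.z)

    def test_adjusted_p_in_unit_interval(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(m, 1, 10) for m in (0, 1, 3)]
        for method in ("holm", "bonferroni", "none"):
            res = dunn_test(groups, adjust=method)
            assert all(0.0 <= p <= 1.0 for p in res.p_adjusted)

    def test_single_pair_adjusted_equals_raw(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(0, 1, 8), rng.normal(1, 1, 9)]
        res = dunn_test(groups)
        assert res.p_adjusted == res.p_raw

    def test_two_group_direction_matches_mann_whitney(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 12)
        y = rng.normal(2, 1, 12)
        dunn = dunn_test([list(x), list(y)])
        mw = mann_whitney_u(x, y)
        # y stochastically larger: U_x small, mean rank of x lower -> z < 0
        assert dunn.z[0] < 0
        assert mw.u < len(x) * len(y) / 2

    def test_holm_dominates_bonferroni(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(m, 1, 10) for m in (0, 0.5, 2)]
        holm = dunn_test(groups, adjust="holm")
        bonf = dunn_test(groups, adjust="bonferroni")
        for ph, pb in zip(holm.p_adjusted, bonf.p_adjusted):
            assert ph <= pb + 1e-12

    def test_power_on_separated_clade_panel(self):
        # alpha vs beta strongly separated at published parameters
        hits = 0
        n_rep = 60
        for seed in range(n_rep):
            a = sample_group_rates(*FIG2_CLADE["alpha_cyano"][:3], 15, seed=seed)
            b = sample_group_rates(*FIG2_CLADE["beta_cyano"][:3], 19,
                                   seed=10_000 + seed)
            p = sample_group_rates(*FIG2_CLADE["ccm_proteo"][:3], 20,
                                   seed=20_000 + seed)
            res = dunn_test([a, b, p], names=["alpha", "beta", "proteo"])
            p_ab = res.p_adjusted[res.pairs.index(("alpha", "beta"))]
            hits += p_ab < 0.001
        assert hits / n_rep >= 0.95


class TestQ10:
    def test_identity_at_same_temperature(self):
        assert q10_correct(3.7, 25, 25) == 3.7

    def test_twenty_to_thirty(self):
        np.testing.assert_allclose(q10_correct(3.0, 20, 30, 2.2), 6.6)

    def test_half_decade(self):
        np.testing.assert_allclose(q10_correct(4.0, 25, 30, 2.2),
                                   4.0 * 2.2 ** 0.5)

    @given(st.floats(0.01, 50), st.floats(-5, 60), st.floats(-5, 60))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, rate, t1, t2):
        back = q10_correct(q10_correct(rate, t1, t2), t2, t1)
        np.testing.assert_allclose(back, rate, rtol=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            q10_correct(-1.0, 20, 30)


class TestCompareGroups:
    def _null_panel(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 60
        return pd.DataFrame({
            "variant_id": [f"v{i}" for i in range(n)],
            "kcat": np.exp(rng.normal(1.5, 0.3, n)),
            "trophic_mode": rng.choice(["photo", "chemo"], n),
            "carboxysome": rng.choice(["yes", "no"], n),
            "clade": rng.choice(["alpha_cyano", "beta_cyano", "ccm_proteo"], n),
        })

    def test_null_panel_fold_near_one(self):
        comps = compare_groups(self._null_panel())
        for comp in comps.values():
            assert comp.fold_median < 1.6
            assert comp.p_value > 0.001

    def test_parameterised_panel_carboxysome_fold(self):
        groups = default_panel_groups()
        panel, _ = simulate_panel(groups, seed=3)
        comps = compare_groups(panel)
        assert comps["carboxysome"].fold_median > 2.5
        assert comps["carboxysome"].p_value < 0.01
        assert comps["clade"].test == "kruskal_wallis+dunn"
        assert comps["clade"].pairwise is not None

    def test_only_active_variants_used(self):
        panel = self._null_panel()
        panel.loc[:29, "kcat"] = 0.1  # below threshold
        comps = compare_groups(panel)
        for comp in comps.values():
            assert sum(comp.group_sizes) == 30

    def test_subset_flag_restricts(self):
        panel = self._null_panel()
        panel["subset_trophic"] = False
        panel.loc[:19, "subset_trophic"] = True
        comps = compare_groups(panel, comparisons=("trophic",))
        assert sum(comps["trophic"].group_sizes) <= 20

    def test_missing_column_skipped_with_warning(self):
        panel = self._null_panel().drop(columns=["clade"])
        with pytest.warns(UserWarning, match="skipped"):
            comps = compare_groups(panel)
        assert "clade" not in comps

    def test_boxplot_whiskers_within_fences(self):
        comps = compare_groups(self._null_panel())
        for comp in comps.values():
            for stats in comp.boxplot.values():
                iqr = stats["q3"] - stats["q1"]
                assert stats["whisker_low"] >= stats["q1"] - 1.5 * iqr - 1e-12
                assert stats["whisker_high"] <= stats["q3"] + 1.5 * iqr + 1e-12


def test_published_group_parameters_are_consistent():
    # sanity on the hard-coded comparison targets: quartiles ordered
    for spec in (FIG2_TROPHIC, FIG2_CARBOXYSOME, FIG2_CLADE):
        for med, q1, q3, n in spec.values():
            assert q1 <= med <= q3
            assert n > 0
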