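import numpy as np
import pytest

from rubikit.assay import AssayConstants
from rubikit.selection import greedy_cluster, pairwise_identity
from rubikit.stats import median_iqr
from rubikit.synthetic import (
    FIG2_CLADE,
    GroupSpec,
    TruthRecord,
    default_panel_groups,
    lognormal_from_median_iqr,
    sample_group_rates,
    simulate_panel,
    simulate_sequence_family,
    simulate_titration_series,
    trace_noise_sd,
)


class TestSimulateTitrationSeries:
    def test_deterministic_under_seed(self, constants):
        truth = TruthRecord("v", 3.0, 40.0, noise_sd=0.003)
        s1 = simulate_titration_series(truth, constants, seed=11)
        s2 = simulate_titration_series(truth, constants, seed=11)
        for a, b in zip(s1.traces, s2.traces):
            np.testing.assert_array_equal(a.a340, b.a340)

    def test_different_seed_differs(self, constants):
        truth = TruthRecord("v", 3.0, 40.0, noise_sd=0.003)
        s1 = simulate_titration_series(truth, constants, seed=11)
        s2 = simulate_titration_series(truth, constants, seed=12)
        assert not np.array_equal(s1.traces[0].a340, s2.traces[0].a340)

    def test_zero_rate_all_flat_at_initial_level(self, constants):
        truth = TruthRecord("dead", 0.0, 50.0)
        series = simulate_titration_series(truth, constants, seed=0)
        expected = truth.baseline_a340 + constants.epsilon_l * constants.nadh0_nM * 1e-9
        for tr in series.traces:
            np.testing.assert_allclose(tr.a340, expected, rtol=1e-12)

    def test_full_inhibition_is_flat(self, constants):
        # 90 nM CABP vs 50 nM sites: no free enzyme
        truth = TruthRecord("v", 0.2, 50.0)
        series = simulate_titration_series(truth, constants, seed=0)
        tr90 = [t for t in series.traces if t.cabp_nM == 90][0]
        assert np.ptp(tr90.a340) == 0.0

    def test_uninhibited_slope_matches_hand_arithmetic(self, constants):
        # sites 50 nM, kcat 0.2 -> v = 10 nM/s, NADH rate 20 nM/s
        # slope = -eps*l*2*v = -6220*0.26*2*1e-8 A/s
        truth = TruthRecord("v", 0.2, 50.0)
        series = simulate_titration_series(truth, constants, seed=0)
        tr0 = series.traces[0]
        fd = np.diff(tr0.a340) / np.diff(tr0.times)
        expected = -6220 * 0.26 * 2.0 * 1e-8
        np.testing.assert_allclose(fd, expected, rtol=1e-9)

    @pytest.mark.parametrize("kcat,sites", [(0.2, 50.0), (2.0, 30.0), (8.0, 60.0)])
    def test_slope_magnitude_monotone_in_cabp(self, constants, kcat, sites):
        truth = TruthRecord("v", kcat, sites)
        series = simulate_titration_series(truth, constants, seed=0)
        mags = []
        for tr in series.traces:
            half = len(tr) // 8  # early window, before any depletion
            fd = (tr.a340[half] - tr.a340[0]) / (tr.times[half] - tr.times[0])
            mags.append((tr.cabp_nM, abs(fd)))
        mags.sort(key=lambda p: p[0])
        vals = [m for _, m in mags]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))

    def test_plateau_sticks_to_floor(self, constants):
        # fast enough to exhaust NADH well before the read ends
        truth = TruthRecord("v", 13.0, 60.0)
        series = simulate_titration_series(truth, constants, seed=0)
        tr0 = series.traces[0]
        # depletion at nadh0 / (2 * kcat * sites) = 2e5/1560 s
        t_dep = constants.nadh0_nM / (2 * 13.0 * 60.0)
        tail = tr0.a340[tr0.times > t_dep + 2 * constants.read_interval_s]
        assert np.ptp(tail) == 0.0
        np.testing.assert_allclose(tail, truth.baseline_a340, rtol=1e-12)

    def test_trace_slope_linearity_property(self, constants):
        # exact OLS slope equals -eps*l*2*v when nothing depletes
        for kcat, sites in [(0.5, 10.0), (1.0, 25.0), (3.3, 17.0)]:
            truth = TruthRecord("v", kcat, sites)
            series = simulate_titration_series(truth, constants, seed=0)
            tr = series.traces[0]
            slope = np.polyfit(tr.times, tr.a340, 1)[0]
            v = kcat * sites
            np.testing.assert_allclose(
                slope, -constants.epsilon_l * 2 * v * 1e-9, rtol=1e-9)

    def test_lag_delays_decline(self, constants):
        truth = TruthRecord("v", 2.0, 40.0, lag_time_s=30.0)
        series = simulate_titration_series(truth, constants, seed=0)
        tr = series.traces[0]
        early = tr.a340[tr.times <= 29]
        assert np.ptp(early) == 0.0

    def test_dilution_scales_flux(self, constants):
        truth = TruthRecord("v", 2.0, 40.0)
        s1 = simulate_titration_series(truth, constants, seed=0, dilution=1.0)
        s2 = simulate_titration_series(truth, constants, seed=0, dilution=2.0)
        fd1 = s1.traces[0].a340[1] - s1.traces[0].a340[0]
        fd2 = s2.traces[0].a340[1] - s2.traces[0].a340[0]
        np.testing.assert_allclose(fd1, 2 * fd2, rtol=1e-9)

    def test_invalid_configuration_rejected(self, constants):
        with pytest.raises(ValueError):
            AssayConstants(duration_s=-5)
        with pytest.raises(ValueError):
            AssayConstants(cabp_ladder_nM=())
        with pytest.raises(ValueError):
            TruthRecord("v", -1.0, 10.0)
        with pytest.raises(ValueError):
            simulate_titration_series(
                TruthRecord("v", 1.0, 10.0), constants, seed=0, dilution=0.5)


class TestLognormalParameterisation:
    def test_median_preserved(self):
        mu, sigma = lognormal_from_median_iqr(5.0, 3.0, 8.0)
        assert np.isclose(np.exp(mu), 5.0)

    def test_iqr_matches(self):
        for med, q1, q3 in [(6.5, 4.4, 7.9), (1.3, 1.1, 2.1), (9.8, 8.6, 10.5)]:
            mu, sigma = lognormal_from_median_iqr(med, q1, q3)
            from scipy.stats import lognorm
            dist = lognorm(s=sigma, scale=np.exp(mu))
            iqr = dist.ppf(0.75) - dist.ppf(0.25)
            np.testing.assert_allclose(iqr, q3 - q1, rtol=1e-10)

    def test_invalid_quartiles(self):
        with pytest.raises(ValueError):
            lognormal_from_median_iqr(5.0, 6.0, 4.0)
        with pytest.raises(ValueError):
            lognormal_from_median_iqr(-1.0, 0.5, 2.0)


class TestSimulatePanel:
    def test_degenerate_iqr_gives_constant_rates(self):
        g = GroupSpec("g", 10, 5.0, 5.0, 5.0, "photo", "yes", "other")
        panel, truths = simulate_panel([g], seed=0)
        assert (panel["kcat"] == 5.0).all()
        assert all(t.kcat_true == 5.0 for t in truths)

    def test_row_bookkeeping(self):
        groups = [
            GroupSpec("a", 9, 5.0, 4.0, 6.0, "photo", "yes", "alpha_cyano"),
            GroupSpec("b", 19, 2.0, 1.5, 3.0, "chemo", "no", "other"),
        ]
        panel, truths = simulate_panel(groups, seed=0)
        assert len(panel) == 28
        assert len(truths) == 28
        assert panel["variant_id"].is_unique

    def test_large_sample_medians_within_5pct(self):
        groups = [
            GroupSpec(name, 2000, med, q1, q3, "photo", "yes", name)
            for name, (med, q1, q3, _) in FIG2_CLADE.items()
        ]
        panel, _ = simulate_panel(groups, seed=123)
        for name, (med, _, _, _) in FIG2_CLADE.items():
            got = panel.loc[panel["group"] == name, "kcat"].median()
            assert abs(got - med) / med < 0.05

    def test_inactive_fraction(self):
        g = GroupSpec("g", 100, 5.0, 4.0, 6.0, "photo", "yes", "other")
        panel, truths = simulate_panel([g], seed=0, inactive_fraction=0.25)
        assert (panel["kcat"] == 0.0).sum() == 25
        assert (~panel["active"]).sum() == 25

    def test_unknown_group_label_rejected(self):
        with pytest.raises(ValueError, match="trophic"):
            GroupSpec("g", 5, 5.0, 4.0, 6.0, "mixo", "yes", "other")
        with pytest.raises(ValueError, match="clade"):
            GroupSpec("g", 5, 5.0, 4.0, 6.0, "photo", "yes", "gamma")

    def test_default_panel_shape(self):
        groups = default_panel_groups()
        assert sum(g.n for g in groups) == 82
        panel, _ = simulate_panel(groups, seed=1)
        assert set(panel["trophic_mode"]) == {"photo", "chemo"}
        assert set(panel["carboxysome"]) == {"yes", "no"}

    def test_deterministic(self):
        groups = default_panel_groups()
        p1, _ = simulate_panel(groups, seed=5)
        p2, _ = simulate_panel(groups, seed=5)
        assert p1.equals(p2)


class TestSampleGroupRates:
    def test_median_converges(self):
        rates = sample_group_rates(9.8, 8.6, 10.5, 100_000, seed=0)
        med, q1, q3 = median_iqr(rates)
        assert abs(med - 9.8) / 9.8 < 0.03


class TestSimulateSequenceFamily:
    def test_within_identity_one_gives_identical_members(self):
        recs = simulate_sequence_family(2, 4, 1.0, 0.6, 100, seed=0)
        by_fam = {}
        for r in recs:
            fam = r.id.split("_")[0]
            by_fam.setdefault(fam, []).append(r.residues)
        for fam, seqs in by_fam.items():
            assert len(set(seqs)) == 1

    def test_single_cluster_any_threshold(self):
        recs = simulate_sequence_family(1, 6, 0.95, 0.5, 150, seed=1)
        for thr in (0.5, 0.7, 0.85):
            asg = greedy_cluster(recs, thr)
            assert asg.n_clusters == 1

    def test_three_family_fixture_recovered_at_080(self):
        recs = simulate_sequence_family(3, 5, 0.95, 0.6, 300, seed=2)
        asg = greedy_cluster(recs, 0.8)
        assert asg.n_clusters == 3
        # families intact: all members of a family share a centroid
        for fam in ("fam0", "fam1", "fam2"):
            cents = {asg.member_to_centroid[r.id]
                     for r in recs if r.id.startswith(fam)}
            assert len(cents) == 1

    def test_identity_targets_approximately_met(self):
        recs = simulate_sequence_family(2, 3, 0.9, 0.6, 400, seed=3)
        fam0 = [r for r in recs if r.id.startswith("fam0")]
        anc = [r for r in fam0 if r.id.endswith("anc")][0]
        for member in fam0:
            if member.id == anc.id:
                continue
            ident = pairwise_identity(anc, member)
            assert abs(ident - 0.9) < 0.07
        anc1 = [r for r in recs if r.id == "fam1_anc"][0]
        cross = pairwise_identity(anc, anc1)
        assert abs(cross - 0.6) < 0.12

    def test_short_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            simulate_sequence_family(2, 3, 0.9, 0.6, 20, seed=0)

    def test_invalid_identity_ordering_rejected(self):
        with pytest.raises(ValueError):
            simulate_sequence_family(2, 3, 0.6, 0.9, 100, seed=0)

    def test_deterministic(self):
        r1 = simulate_sequence_family(2, 3, 0.9, 0.6, 100, seed=9)
        r2 = simulate_sequence_family(2, 3, 0.9, 0.6, 100, seed=9)
        assert [x.residues for x in r1] == [x.residues for x in r2]


def test_trace_noise_sd_scales_with_signal(constants):
    slow = trace_noise_sd(0.5, 10.0, constants)
    fast = trace_noise_sd(13.0, 60.0, constants)
    assert 0 < slow < fast
    # fast case is capped by full NADH depletion
    assert np.isclose(fast, 0.02 * constants.epsilon_l * constants.nadh0_nM * 1e-9)
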