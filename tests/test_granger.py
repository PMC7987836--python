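import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from phonoflux import (AnalysisConfig, GciSeries, bootstrap_edge,
                       compare_conditions, compare_edge_sets,
                       count_significant, detect_edges, fdr_correct, gci,
                       influence_report, scan_edges, simulate_mvar,
                       static_network)
from phonoflux.core_io import ValidationError


class TestGci:
    def test_equal_errors_give_zero(self):
        e = np.ones(10)
        np.testing.assert_array_equal(gci(e, e), 0.0)

    def test_two_to_one_ratio_gives_ln2(self):
        out = gci(np.array([1.0]), np.array([2.0]))
        assert out[0] == pytest.approx(np.log(2.0), abs=1e-12)

    def test_nonpositive_error_names_timepoint(self):
        with pytest.raises(ValidationError, match="3"):
            gci(np.array([1, 1, 1, 0.0]), np.ones(4))

    def test_matches_ols_granger_statistic_on_stationary_data(
            self, cfg, kalman, coupled_2ch):
        # classic Granger: ln(var_reduced / var_full) from OLS residuals
        from phonoflux import fit_counter_model, fit_target_model
        ts = simulate_mvar(coupled_2ch, 4000, seed=21)
        p = cfg.model_order
        y = ts.values[1, p:]
        Xf = np.column_stack([ts.values[j, p - k - 1:-k - 1]
                              for j in range(2) for k in range(p)])
        Xr = np.column_stack([ts.values[1, p - k - 1:-k - 1]
                              for k in range(p)])
        rf = y - Xf @ np.linalg.lstsq(Xf, y, rcond=None)[0]
        rr = y - Xr @ np.linalg.lstsq(Xr, y, rcond=None)[0]
        ols_gci = 0.5 * np.log(rr.var() / rf.var())
        full = fit_target_model(ts, "ch1", cfg, kalman)
        red = fit_counter_model(ts, "ch0", "ch1", cfg, kalman)
        kf_gci = gci(full.error_scale, red.error_scale)[500:].mean()
        assert kf_gci == pytest.approx(ols_gci, abs=0.02)


class TestCountSignificant:
    def _series(self, p):
        return GciSeries(source="a", target="b", condition="",
                         gci=np.zeros(len(p)), p=np.asarray(p),
                         alpha=0.05)

    def test_all_nonsignificant_counts_zero(self, cfg):
        assert count_significant(self._series(np.ones(401)), cfg) == 0

    def test_all_significant_counts_window_length(self, cfg):
        assert count_significant(self._series(np.zeros(401)), cfg) == 401

    def test_constructed_count_matches_enumeration(self, cfg):
        rng = np.random.default_rng(0)
        p = np.ones(401)
        hits = rng.choice(401, 40, replace=False)
        p[hits] = 0.01
        assert count_significant(self._series(p), cfg) == 40


class TestCompareConditions:
    def test_equal_counts_give_p_one(self):
        p, favored = compare_conditions(17, 17, 401)
        assert p == pytest.approx(1.0)
        assert favored is None

    def test_matches_exact_binomial_summation(self):
        p, favored = compare_conditions(40, 10, 401)
        # two-sided exact: 2 * P(X >= 40 | X ~ Bin(50, 1/2))
        expected = 2 * sum(stats.binom.pmf(k, 50, 0.5)
                           for k in range(40, 51))
        assert p == pytest.approx(expected, rel=1e-9)
        assert favored == "a"

    def test_zero_counts_degenerate(self):
        assert compare_conditions(0, 0, 401) == (1.0, None)

    @given(st.integers(0, 200), st.integers(0, 200))
    @settings(max_examples=100, deadline=None)
    def test_symmetry_under_condition_swap(self, a, b):
        p1, f1 = compare_conditions(a, b, 200)
        p2, f2 = compare_conditions(b, a, 200)
        assert p1 == pytest.approx(p2, rel=1e-12)
        assert {None: None, "a": "b", "b": "a"}[f1] == f2


class TestFdr:
    def test_uniform_small_p_all_rejected(self, cfg):
        assert fdr_correct([0.001] * 10, cfg).all()

    def test_step_up_hand_case(self, cfg):
        # BH at 0.05 over {0.01, 0.02, 0.03, 0.2, 0.9}: thresholds
        # k*0.05/5 = 0.01, 0.02, 0.03, 0.04, 0.05 -> first three rejected
        out = fdr_correct([0.01, 0.02, 0.03, 0.2, 0.9], cfg)
        np.testing.assert_array_equal(out, [True, True, True, False, False])

    def test_uniform_large_p_none_rejected(self, cfg):
        assert not fdr_correct([0.9] * 10, cfg).any()

    def test_empty_input_empty_output(self, cfg):
        assert fdr_correct([], cfg).size == 0


class TestBootstrap:
    def test_alpha_one_makes_every_timepoint_significant(self, kalman,
                                                         coupled_2ch):
        cfg = AnalysisConfig(alpha=0.999)
        ts = simulate_mvar(coupled_2ch, 600, seed=1)
        g = bootstrap_edge(ts, "ch0", "ch1", cfg, kalman, seed=0,
                           n_bootstrap=20)
        # the planted edge's GCi never trails the whole null ensemble,
        # so every p sits below the (near-unity) threshold
        assert count_significant(g, cfg) == len(g.gci)

    def test_planted_edge_significant_null_edge_not(self, cfg, kalman,
                                                    coupled_2ch):
        ts = simulate_mvar(coupled_2ch, 600, seed=300)
        strong = bootstrap_edge(ts, "ch0", "ch1", cfg, kalman, seed=1,
                                n_bootstrap=100)
        null = bootstrap_edge(ts, "ch1", "ch0", cfg, kalman, seed=2,
                              n_bootstrap=100)
        assert np.mean(strong.sig) > 0.9
        assert strong.edge_p < 0.05
        assert null.edge_p > 0.05

    def test_seeded_bootstrap_reproducible(self, cfg, kalman, coupled_2ch):
        ts = simulate_mvar(coupled_2ch, 600, seed=5)
        a = bootstrap_edge(ts, "ch0", "ch1", cfg, kalman, seed=3,
                           n_bootstrap=50)
        b = bootstrap_edge(ts, "ch0", "ch1", cfg, kalman, seed=3,
                           n_bootstrap=50)
        np.testing.assert_array_equal(a.p, b.p)

    def test_gci_unchanged_by_unrelated_channel_permutation(self, cfg,
                                                            kalman):
        # edge ch0 -> ch1 is computed from target-1 models; results only
        # reorder regressors when other channels are permuted
        from phonoflux import MultiTimeSeries, fit_counter_model, \
            fit_target_model
        net = static_network({(0, 1): 0.5}, n_channels=4, order=5,
                             self_coeff=0.3)
        ts = simulate_mvar(net, 600, seed=9)
        perm = [0, 1, 3, 2]
        ts_p = MultiTimeSeries(labels=[ts.labels[i] for i in perm],
                               values=ts.values[perm],
                               sampling_rate=ts.sampling_rate,
                               t0_ms=ts.t0_ms)
        def observed(t):
            full = fit_target_model(t, "ch1", cfg, kalman)
            red = fit_counter_model(t, "ch0", "ch1", cfg, kalman)
            return gci(full.error_scale, red.error_scale)
        np.testing.assert_allclose(observed(ts), observed(ts_p), rtol=1e-8)


class TestEdgeTables:
    def _fake_series(self, source, target, n_sig, n=401, edge_p=0.5):
        p = np.ones(n)
        p[:n_sig] = 0.001
        return GciSeries(source=source, target=target, condition="",
                         gci=np.zeros(n), p=p, edge_p=edge_p, alpha=0.05)

    def test_compare_edge_sets_counts_and_decisions(self, cfg):
        a = [self._fake_series("x", "y", 120), self._fake_series("y", "x", 10)]
        b = [self._fake_series("x", "y", 20), self._fake_series("y", "x", 12)]
        df = compare_edge_sets(a, b, cfg)
        row = df.set_index(["source", "target"]).loc[("x", "y")]
        assert row["count_a"] == 120 and row["count_b"] == 20
        assert row["favored_condition"] == "Trained"
        assert bool(row["fdr_significant"])
        row2 = df.set_index(["source", "target"]).loc[("y", "x")]
        assert not bool(row2["fdr_significant"])

    def test_influence_report_filters_and_sorts(self, cfg):
        a = [self._fake_series("u", "f", 150), self._fake_series("v", "f", 90),
             self._fake_series("f", "u", 10), self._fake_series("w", "v", 10)]
        b = [self._fake_series("u", "f", 10), self._fake_series("v", "f", 10),
             self._fake_series("f", "u", 10), self._fake_series("w", "v", 10)]
        df = compare_edge_sets(a, b, cfg)
        onto = influence_report(df, "f", "onto")
        assert list(onto["source"]) == ["u", "v"]
        assert abs(onto["diff"].iloc[0]) >= abs(onto["diff"].iloc[1])
        from_f = influence_report(df, "f", "from")
        assert len(from_f) == 0          # f -> u difference is null
        with pytest.raises(ValidationError):
            influence_report(df, "nope", "onto")

    def test_no_significant_edges_gives_empty_report(self, cfg):
        a = [self._fake_series("x", "y", 10)]
        b = [self._fake_series("x", "y", 11)]
        df = compare_edge_sets(a, b, cfg)
        assert len(influence_report(df, "y", "onto")) == 0


class TestScanEdges:
    def test_scan_covers_all_ordered_pairs(self, kalman):
        cfg = AnalysisConfig()
        net = static_network({(0, 1): 0.5}, n_channels=3, order=5,
                             self_coeff=0.3)
        ts = simulate_mvar(net, 600, seed=2)
        series = scan_edges(ts, cfg, kalman, seed=0, n_bootstrap=30)
        assert len(series) == 6
        df = detect_edges(series, cfg)
        assert set(zip(df["source"], df["target"])) == {
            (s, t) for s in ts.labels for t in ts.labels if s != t}
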