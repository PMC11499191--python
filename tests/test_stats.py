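import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gaitadapt.errors import DegenerateStatisticError, ValidationError
from gaitadapt.events import AsymmetrySeries
from gaitadapt.stats import (
    adaptation_window,
    friedman,
    normality_gate,
    post_window,
    run_battery,
    segment_stages,
    stage_means,
    wilcoxon_pairs,
)
from gaitadapt.synthetic import (
    SimulationTruth,
    simulate_asymmetry_series,
    simulate_decay_table,
)


def _series_at(times, values=None):
    times = np.asarray(times, dtype=float)
    if values is None:
        values = np.zeros_like(times)
    return AsymmetrySeries("step_length", times, values)


class TestSegmentation:
    def test_half_open_boundaries(self, ts_protocol):
        series = _series_at([100.0, 180.0, 630.0, 1080.0, 1379.9])
        labeled = segment_stages(series, ts_protocol)
        assert list(labeled.stage) == ["baseline", "adaptation1",
                                       "adaptation2", "post", "post"]

    def test_partition_covers_every_stride(self, ts_protocol):
        truth = SimulationTruth.for_protocol(ts_protocol, seed=1)
        series = simulate_asymmetry_series(ts_protocol, truth, "step_time")
        labeled = segment_stages(series, ts_protocol)
        counts = pd.Series(labeled.stage).value_counts()
        assert counts.sum() == len(series)
        assert set(counts.index) == {"baseline", "adaptation1",
                                     "adaptation2", "post"}

    def test_out_of_range_strides_rejected(self, ts_protocol):
        with pytest.raises(ValidationError):
            segment_stages(_series_at([10.0, 1380.0]), ts_protocol)


class TestAdaptationWindow:
    def test_control_trial_uses_first_half(self, ts_protocol):
        truth = SimulationTruth.for_protocol(ts_protocol, seed=2)
        series = simulate_asymmetry_series(ts_protocol, truth, "step_length")
        window = adaptation_window("TS", series, ts_protocol)
        assert window.t[0] == pytest.approx(0.0, abs=1.2)
        assert window.t[-1] < 450.0
        # re-zeroed: original first stride in [180, 630)
        assert len(window) == np.sum((series.t >= 180) & (series.t < 630))

    def test_sequential_trial_uses_second_half(self):
        from gaitadapt.protocol import build_protocol

        protocol = build_protocol("TCS", 1.1, 1.1)
        truth = SimulationTruth.for_protocol(protocol, seed=3)
        series = simulate_asymmetry_series(protocol, truth, "step_length")
        window = adaptation_window("TCS", series, protocol)
        assert len(window) == np.sum((series.t >= 630) & (series.t < 1080))
        assert window.t[0] < 1.5

    def test_post_window_rezeroed(self, ts_protocol):
        truth = SimulationTruth.for_protocol(ts_protocol, seed=4)
        series = simulate_asymmetry_series(ts_protocol, truth, "step_time")
        window = post_window(series, ts_protocol)
        assert window.t[0] < 1.5
        assert window.t[-1] < 300.0


class TestStageMeans:
    def test_noiseless_means_match_model(self, ts_protocol):
        truth = SimulationTruth.for_protocol(ts_protocol, noise_sd=0.0,
                                             seed=0)
        series = simulate_asymmetry_series(ts_protocol, truth, "step_length")
        means = stage_means(series, ts_protocol)
        curve = truth.curves["step_length"]["adaptation1"]
        # late adaptation: the curve has flattened near its steady state
        assert means["late_adaptation"] == pytest.approx(
            float(curve(890.0)), abs=0.1)
        assert means["baseline"] == pytest.approx(0.0, abs=1e-9)
        assert means["early_post"] < 0  # aftereffect of opposite sign

    def test_constant_series_has_equal_means(self, ts_protocol):
        t = np.arange(0.0, 1380.0, 1.1)
        means = stage_means(_series_at(t, np.full(len(t), 4.2)),
                            ts_protocol)
        assert all(v == pytest.approx(4.2) for v in means.values())

    def test_exactly_fifteen_post_strides_accepted(self, ts_protocol):
        t = np.concatenate([np.arange(0.0, 1080.0, 1.0),
                            1080.0 + np.arange(15.0)])
        means = stage_means(_series_at(t, np.ones(len(t))), ts_protocol)
        assert means["early_post"] == pytest.approx(1.0)

    def test_deficient_window_named_in_error(self, ts_protocol):
        t = np.concatenate([np.arange(0.0, 1080.0, 1.0), [1100.0]])
        with pytest.raises(ValidationError, match="post"):
            stage_means(_series_at(t, np.ones(len(t))), ts_protocol)


class TestNormalityGate:
    def test_skewed_condition_routes_nonparametric(self):
        rng = np.random.default_rng(0)
        values = {"a": rng.normal(size=10),
                  "b": rng.exponential(size=10) ** 3}
        branch, _ = normality_gate(values)
        assert branch == "nonparametric"

    def test_gaussian_conditions_usually_parametric(self):
        """With three Gaussian conditions of n=10 the joint pass rate is
        about 1 - (1 - 0.95^3) ~ 86%."""
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            values = {k: rng.normal(size=10) for k in "abc"}
            branch, _ = normality_gate(values)
            hits += branch == "parametric"
        assert 0.78 <= hits / n_rep <= 0.93

    def test_constant_condition_is_degenerate_nonparametric(self):
        values = {"a": np.zeros(5), "b": np.random.default_rng(1).normal(
            size=5)}
        branch, reports = normality_gate(values)
        assert branch == "nonparametric"
        assert any(r.context.get("degenerate") for r in reports)


class TestFriedman:
    def test_identical_ordering_reference_value(self):
        """Ten blocks ranking three conditions identically give the
        maximal chi-square 0.1 * (100 + 400 + 900) - 120 = 20."""
        blocks = np.tile([1.0, 2.0, 3.0], (10, 1)) \
            + np.arange(10)[:, None] * 10
        report = friedman(blocks, conditions=("x", "y", "z"))
        assert report.statistic == pytest.approx(20.0)
        assert report.df == 2
        assert report.p == pytest.approx(float(sps.chi2.sf(20.0, 2)))

    def test_fully_tied_blocks_give_zero(self):
        report = friedman(np.ones((5, 3)))
        assert report.statistic == 0.0
        assert report.p == 1.0

    def test_consistent_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        blocks = rng.normal(size=(8, 4))
        perm = [2, 0, 3, 1]
        assert friedman(blocks).statistic == pytest.approx(
            friedman(blocks[:, perm]).statistic)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_scipy_including_ties(self, seed):
        rng = np.random.default_rng(seed)
        blocks = np.round(rng.normal(size=(12, 4)), 1)  # induce ties
        ours = friedman(blocks)
        ref_stat, ref_p = sps.friedmanchisquare(*blocks.T)
        assert ours.statistic == pytest.approx(ref_stat)
        assert ours.p == pytest.approx(ref_p)

    def test_two_conditions_agree_with_sign_test(self):
        """At k=2 the Friedman decision matches the exact sign test at
        alpha=0.05 on continuous data."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            blocks = rng.normal(size=(10, 2))
            blocks[:, 1] += rng.uniform(-1.5, 1.5)
            ours = friedman(blocks).p < 0.05
            wins = int(np.sum(blocks[:, 0] > blocks[:, 1]))
            sign_p = sps.binomtest(wins, 10, 0.5).pvalue
            assert ours == (sign_p < 0.05)

    def test_incomplete_blocks_rejected(self):
        blocks = np.ones((4, 3))
        blocks[1, 2] = np.nan
        with pytest.raises(ValidationError):
            friedman(blocks)


class TestWilcoxon:
    def test_uniformly_signed_differences_give_extreme_statistic(self):
        a = np.arange(1.0, 11.0)
        b = a + np.linspace(1.0, 4.0, 10)  # distinct, all-positive shifts
        report = wilcoxon_pairs(a, b)
        # all-negative differences: Z = (0 - 27.5) / sqrt(96.25)
        assert report.statistic == pytest.approx(-2.803, abs=0.001)
        assert report.p == pytest.approx(0.00506, abs=0.0005)

    def test_swapping_sides_flips_sign_same_p(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=12)
        b = a + rng.normal(0.5, 1.0, size=12)
        r1 = wilcoxon_pairs(a, b)
        r2 = wilcoxon_pairs(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p == pytest.approx(r2.p)

    def test_balanced_ranks_give_null_pvalue(self):
        a = np.zeros(6)
        b = np.array([-1.0, 2.0, 3.0, -4.0, -5.0, 6.0])  # T+ = 11, T- = 10
        approx = wilcoxon_pairs(a, b)
        exact = wilcoxon_pairs(a, b, exact=True)
        assert approx.p > 0.8
        assert exact.p > 0.8
        assert abs(approx.p - exact.p) < 0.15

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateStatisticError):
            wilcoxon_pairs(np.ones(6), np.ones(6))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_pairs([1.0, 2.0], [1.0, 2.0, 3.0])


class TestRunBattery:
    def test_friedman_count_matches_plan(self):
        table = simulate_decay_table(n_subjects=6, seed=0)
        reports = run_battery(table)
        n_friedman = sum(r.test == "friedman" for r in reports)
        assert n_friedman == 3 * 2 * 2 * 2  # families x params x comps x stages

    def test_strong_effect_triggers_pairwise_followups(self):
        table = simulate_decay_table(
            n_subjects=10, seed=1,
            effects={("TCS", "adaptation", None, "explicit"): 8.0})
        reports = run_battery(table)
        wilcoxons = [r for r in reports if r.test == "wilcoxon"
                     and r.context["family"] == ("TS", "TCS", "TcS")
                     and r.context["component"] == "explicit"
                     and r.context["stage"] == "adaptation"]
        assert len(wilcoxons) == 2 * 3  # both parameters, 3 pairs each
        tcs_ts = [r for r in wilcoxons
                  if set(r.conditions) == {"TCS", "TS"}]
        assert all(r.p < 0.05 for r in tcs_ts)

    def test_single_condition_family_rejected(self):
        table = simulate_decay_table(n_subjects=4, seed=2)
        with pytest.raises(ValidationError):
            run_battery(table, families=[("TS",)])

    def test_missing_cells_enumerated(self):
        table = simulate_decay_table(n_subjects=4, seed=3)
        table = table[table["trial"] != "TcS"]
        with pytest.raises(ValidationError, match="TcS"):
            run_battery(table)

    def test_listwise_exclusion_of_incomplete_subjects(self):
        table = simulate_decay_table(n_subjects=6, seed=4)
        drop = (table["subject"] == "S00") & (table["trial"] == "TCS")
        reports = run_battery(table[~drop])
        sbt = [r for r in reports if r.test == "friedman"
               and r.context["family"] == ("TS", "TCS", "TcS")]
        assert sbt  # battery still runs on the five complete subjects

    def test_holm_adjustment_is_monotone(self):
        table = simulate_decay_table(
            n_subjects=10, seed=5,
            effects={("TCS", "adaptation", None, "explicit"): 8.0})
        reports = run_battery(table, holm=True)
        adjusted = [r.context["p_holm"] for r in reports
                    if r.test == "wilcoxon"]
        assert adjusted
        assert all(0 <= p <= 1 for p in adjusted)
        raw = [r.p for r in reports if r.test == "wilcoxon"]
        assert all(ph >= pr for ph, pr in zip(adjusted, raw))
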