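import numpy as np
import pytest

from gaitadapt.errors import ValidationError
from gaitadapt.fitting import PSOConfig, pso_fit
from gaitadapt.protocol import TrialType, build_protocol
from gaitadapt.stats import adaptation_window
from gaitadapt.synthetic import (
    SimulationTruth,
    StageCurve,
    simulate_asymmetry_series,
    simulate_decay_table,
    simulate_recording,
    simulate_strides,
)


class TestStageCurve:
    def test_scalar_evaluation(self):
        curve = StageCurve(10.0, 0.1, 5.0, 0.01, 2.0)
        assert curve(10.0) == pytest.approx(10.2030, abs=1e-4)

    def test_fast_slower_than_slow_rejected(self):
        with pytest.raises(ValidationError):
            StageCurve(1.0, 0.01, 1.0, 0.05, 0.0)
        with pytest.raises(ValidationError):
            StageCurve(1.0, 0.05, 1.0, -0.01, 0.0)


class TestSimulateAsymmetrySeries:
    def test_zero_noise_equals_stagewise_curve(self, ts_protocol):
        truth = SimulationTruth.for_protocol(ts_protocol, noise_sd=0.0,
                                             seed=0)
        series = simulate_asymmetry_series(ts_protocol, truth, "step_length")
        # control trial: one uninterrupted 900 s adaptation segment
        curve = truth.curves["step_length"]["adaptation1"]
        m = (series.t >= 180.0) & (series.t < 1080.0)
        assert np.allclose(series.asymmetry[m], curve(series.t[m] - 180.0),
                           atol=1e-9)
        base = series.asymmetry[series.t < 180.0]
        assert np.allclose(base, 0.0, atol=1e-9)

    def test_monte_carlo_mean_matches_curve(self, ts_protocol):
        """Per-stride averages over noise replicates stay within the
        standard Monte-Carlo band around the closed-form curve.

        Each replicate is paired with a zero-noise run on the same random
        stream, so stride onsets coincide and residuals isolate the
        additive noise."""
        noise_sd = 1.0
        n_rep = 200
        truth0 = SimulationTruth.for_protocol(ts_protocol, noise_sd=0.0,
                                              seed=0)
        truth1 = SimulationTruth.for_protocol(ts_protocol,
                                              noise_sd=noise_sd, seed=0)
        acc = None
        for rep in range(n_rep):
            clean = simulate_asymmetry_series(
                ts_protocol, truth0, "step_length",
                rng=np.random.default_rng(500 + rep))
            noisy = simulate_asymmetry_series(
                ts_protocol, truth1, "step_length",
                rng=np.random.default_rng(500 + rep))
            residual = noisy.asymmetry - clean.asymmetry
            n = len(residual) if acc is None else min(len(acc),
                                                      len(residual))
            acc = residual[:n] if acc is None else acc[:n] + residual[:n]
        mean_residual = acc / n_rep
        band = 3 * noise_sd / np.sqrt(n_rep)
        assert np.mean(np.abs(mean_residual) <= band) > 0.99

    def test_aftereffect_has_opposite_sign(self, ts_protocol):
        truth = SimulationTruth.for_protocol(ts_protocol, noise_sd=0.0,
                                             seed=0)
        series = simulate_asymmetry_series(ts_protocol, truth, "step_length")
        late = series.asymmetry[(series.t >= 1000) & (series.t < 1080)]
        early_post = series.asymmetry[(series.t >= 1080)][:5]
        assert late.mean() > 0
        assert np.all(early_post < 0)

    def test_right_dominant_target_gives_negative_asymmetry(self):
        """Mirrored cueing imposes larger right-side step times, so the
        simulated step-time asymmetry is negative during that half."""
        protocol = build_protocol(TrialType.TcS, 1.1, 1.1)
        truth = SimulationTruth.for_protocol(protocol, noise_sd=0.0, seed=0)
        series = simulate_asymmetry_series(protocol, truth, "step_time")
        half1 = series.asymmetry[(series.t >= 400) & (series.t < 630)]
        assert np.all(half1 < 0)

    def test_reproducible_under_fixed_seed(self, ts_protocol):
        truth = SimulationTruth.for_protocol(ts_protocol, noise_sd=1.0,
                                             seed=42)
        s1 = simulate_asymmetry_series(ts_protocol, truth, "step_time")
        s2 = simulate_asymmetry_series(ts_protocol, truth, "step_time")
        assert np.array_equal(s1.t, s2.t)
        assert np.array_equal(s1.asymmetry, s2.asymmetry)

    def test_invalid_truth_rejected(self, ts_protocol):
        with pytest.raises(ValidationError):
            SimulationTruth.for_protocol(ts_protocol, noise_sd=-1.0)
        with pytest.raises(ValidationError):
            SimulationTruth.for_protocol(ts_protocol, compliance=1.5)


class TestSavingsAndInterference:
    def test_savings_multiplier_scales_fitted_explicit_constant(self):
        """A >1 savings multiplier on the congruent second half yields a
        larger fitted explicit constant than the multiplier-free run."""
        explicit = {}
        for sm in (1.0, 2.0):
            protocol = build_protocol(TrialType.TCS, 1.1, 1.1)
            truth = SimulationTruth.for_protocol(
                protocol, noise_sd=0.0, savings_multiplier=sm, seed=0)
            series = simulate_asymmetry_series(protocol, truth,
                                               "step_length")
            window = adaptation_window(TrialType.TCS, series, protocol)
            fit = pso_fit(window, "double", PSOConfig(seed=5))
            explicit[sm] = fit.explicit_constant
        assert explicit[2.0] > explicit[1.0]
        assert explicit[2.0] == pytest.approx(2 * explicit[1.0], rel=0.05)

    def test_interference_multiplier_slows_incongruent_half(self):
        protocol = build_protocol(TrialType.TcS, 1.1, 1.1)
        slow = SimulationTruth.for_protocol(
            protocol, interference_multiplier=0.5, seed=0)
        base = SimulationTruth.for_protocol(protocol, seed=0)
        b_slow = slow.curves["step_length"]["adaptation2"].b
        b_base = base.curves["step_length"]["adaptation2"].b
        assert b_slow == pytest.approx(0.5 * b_base)


class TestSimulateStrides:
    def test_strides_realize_both_parameter_series(self, ts_protocol):
        truth = SimulationTruth.for_protocol(ts_protocol, noise_sd=1.0,
                                             seed=9)
        strides = simulate_strides(ts_protocol, truth)
        assert np.all(strides.sides[0::2] == "L")
        assert np.all(strides.sides[1::2] == "R")
        # stride duration equals the two step times
        durations = strides.step_times[0::2] + strides.step_times[1::2]
        onsets = strides.times[1::2]
        assert np.allclose(np.diff(onsets), durations[1:], atol=1e-9)


class TestSimulateRecording:
    def test_force_pulse_counts_match_steps(self, ts_protocol):
        truth = SimulationTruth.for_protocol(ts_protocol, noise_sd=0.5,
                                             seed=2)
        rec, strides = simulate_recording(ts_protocol, truth)
        threshold = 0.05 * rec.body_weight
        for side, force in (("L", rec.lgrf), ("R", rec.rgrf)):
            pulses = int(np.sum((force[:-1] < threshold)
                                & (force[1:] >= threshold)))
            n_steps = int(np.sum(strides.sides == side))
            # the bootstrap right contact at t=0 adds one right pulse
            expected = n_steps + (1 if side == "R" else 0)
            assert abs(pulses - expected) <= 1

    def test_too_short_stride_time_rejected(self):
        protocol = build_protocol(TrialType.TS, 1.1, 0.05)
        truth = SimulationTruth.for_protocol(protocol, noise_sd=0.0, seed=0)
        with pytest.raises(ValidationError):
            simulate_recording(protocol, truth)


class TestSimulateDecayTable:
    def test_shape_and_determinism(self):
        t1 = simulate_decay_table(n_subjects=4, seed=7)
        t2 = simulate_decay_table(n_subjects=4, seed=7)
        assert len(t1) == 4 * 6 * 2 * 2 * 2
        assert t1.equals(t2)
        assert (t1["value"] > 0).all()

    def test_effect_multiplies_targeted_cells(self):
        base = simulate_decay_table(n_subjects=6, seed=3)
        boosted = simulate_decay_table(
            n_subjects=6, seed=3,
            effects={("TCS", "adaptation", None, "explicit"): 2.0})
        mask = ((base["trial"] == "TCS") & (base["stage"] == "adaptation")
                & (base["component"] == "explicit"))
        ratio = boosted.loc[mask, "value"] / base.loc[mask, "value"]
        assert np.allclose(ratio, 2.0)
        assert base.loc[~mask, "value"].equals(boosted.loc[~mask, "value"])
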