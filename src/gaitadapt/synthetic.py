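"""Synthetic stride-level gait data with known adaptation ground truth.

The generator emulates the statistical structure the analysis assumes: a
per-stride symmetry-index series whose stage-wise mean follows a
double-exponential approach to an imposed asymmetry,

    %Asymmetry(t) = a * exp(-b t) + d * exp(-f t) + c,

with time re-zeroed at the onset of each curve segment, additive i.i.d.
Gaussian noise per stride, an aftereffect of opposite sign at perturbation
removal, and optional savings/interference modifiers that scale the fast
decay constant during the second adaptation half of sequential trials.
Stride timestamps are cumulative sums of jittered stride durations, so the
series is non-uniformly sampled in time.

A marker/force-level recording can be synthesized on top of the stride
series so the event-detection stage is testable end-to-end: heel-strike
ground truth is retained alongside the recording.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .errors import ValidationError
from .events import AsymmetrySeries, StrideSeries
from .protocol import (
    Intervention,
    TrialProtocol,
    imposed_asymmetry,
)

__all__ = [
    "StageCurve",
    "SimulationTruth",
    "GaitRecording",
    "simulate_asymmetry_series",
    "simulate_strides",
    "simulate_recording",
    "simulate_decay_table",
]

PARAMETERS = ("step_length", "step_time")

#: Default steady-state asymmetry reached under split-belt walking, %.
#: Free ground-truth parameters (the protocol does not fix them in closed
#: form); magnitudes are typical of healthy adults on 2:1 split belts.
DEFAULT_SBT_TARGETS = {"step_length": 15.0, "step_time": 10.0}

#: Default steady-state step-length asymmetry reached under asymmetric
#: cueing, %.  Cueing prescribes timing; the spatial response is smaller.
DEFAULT_ARAC_STEP_LENGTH_TARGET = 5.0

#: Fraction of the achieved cue-prescribed step-time asymmetry actually
#: reached (cue-following compliance is imperfect in real cohorts).
DEFAULT_ARAC_ATTAINMENT = 0.30

#: Fast/slow decay constants (1/s) used by the default truth builder.
DEFAULT_FAST_DECAY = 0.05
DEFAULT_SLOW_DECAY = 0.005

#: Fraction of the total approach carried by the fast component.
DEFAULT_FAST_FRACTION = 0.6

#: Aftereffect at perturbation removal: the post-adaptation series starts
#: at -AFTEREFFECT_FRACTION x (late-adaptation asymmetry).
DEFAULT_AFTEREFFECT_FRACTION = 0.6


@dataclass(frozen=True)
class StageCurve:
    """Double-exponential ground truth for one curve segment.

    ``a`` (%) and ``b`` (1/s) are the fast amplitude and decay, ``d`` (%)
    and ``f`` (1/s) the slow pair, ``c`` (%) the steady-state offset.  The
    fast component must decay strictly faster: b > f >= 0.
    """

    a: float
    b: float
    d: float
    f: float
    c: float

    def __post_init__(self) -> None:
        if not (self.b > self.f >= 0):
            raise ValidationError(
                f"need fast decay b > slow decay f >= 0, got b={self.b}, "
                f"f={self.f}"
            )

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return (self.a * np.exp(-self.b * t)
                + self.d * np.exp(-self.f * t) + self.c)


@dataclass
class SimulationTruth:
    """Ground truth for one simulated trial.

    ``curves[parameter][stage]`` maps each of the four stages to its
    :class:`StageCurve`; consecutive stages holding equal curves (the
    control trials' two adaptation halves) are treated as one segment, with
    time continuing rather than resetting at the internal boundary.
    """

    curves: Mapping[str, Mapping[str, StageCurve]]
    noise_sd: float = 1.0            # % per stride
    compliance: float = 1.0          # scales achieved ARAC asymmetry
    savings_multiplier: float = 1.0      # x on fast decay, congruent 2nd half
    interference_multiplier: float = 1.0  # x on fast decay, incongruent
    seed: int = 0
    timing_jitter_frac: float = 0.02  # sd of stride-duration jitter

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0 <= self.compliance <= 1:
            raise ValidationError("compliance must be in [0, 1]")
        if self.savings_multiplier <= 0 or self.interference_multiplier <= 0:
            raise ValidationError("decay multipliers must be positive")

    @classmethod
    def for_protocol(
        cls,
        protocol: TrialProtocol,
        *,
        sbt_targets: Optional[Mapping[str, float]] = None,
        arac_step_length_target: float = DEFAULT_ARAC_STEP_LENGTH_TARGET,
        arac_attainment: float = DEFAULT_ARAC_ATTAINMENT,
        fast_decay: float = DEFAULT_FAST_DECAY,
        slow_decay: float = DEFAULT_SLOW_DECAY,
        fast_fraction: float = DEFAULT_FAST_FRACTION,
        aftereffect_fraction: float = DEFAULT_AFTEREFFECT_FRACTION,
        noise_sd: float = 1.0,
        compliance: float = 1.0,
        savings_multiplier: float = 1.0,
        interference_multiplier: float = 1.0,
        seed: int = 0,
        timing_jitter_frac: float = 0.02,
    ) -> "SimulationTruth":
        """Build stage curves consistent with a protocol's interventions.

        Steady-state targets: split-belt stages use ``sbt_targets`` (free
        ground truth), cueing stages use the closed-form cue asymmetry
        scaled by ``arac_attainment`` and ``compliance`` for step time and
        ``arac_step_length_target`` (with the cue ratio's sign) for step
        length.  Each adaptation segment starts where the previous one
        ended; the post-adaptation segment starts from an aftereffect of
        opposite sign and decays to zero.  Savings/interference multipliers
        scale the fast decay constant of the second adaptation half of
        congruent/incongruent sequential trials respectively.
        """
        sbt_targets = dict(DEFAULT_SBT_TARGETS if sbt_targets is None
                           else sbt_targets)

        def target(stage, parameter):
            iv = stage.intervention
            if iv is Intervention.NONE:
                return 0.0
            if iv is Intervention.SBT:
                return sbt_targets[parameter]
            sign = 1.0 if iv is Intervention.ARAC_2_1 else -1.0
            if parameter == "step_time":
                closed = imposed_asymmetry(protocol, stage, "step_time")
                return closed * arac_attainment * compliance
            return sign * arac_step_length_target * compliance

        curves: dict[str, dict[str, StageCurve]] = {}
        for parameter in PARAMETERS:
            per_stage: dict[str, StageCurve] = {}
            y = 0.0  # running value at the end of the previous segment
            first, second = protocol.trial_type.sequence
            for stage in protocol.stages:
                name = stage.name
                if name == "baseline":
                    per_stage[name] = StageCurve(
                        0.0, fast_decay, 0.0, slow_decay, 0.0)
                    y = 0.0
                    continue
                if name == "post":
                    start = -aftereffect_fraction * y
                    per_stage[name] = StageCurve(
                        fast_fraction * start, fast_decay,
                        (1 - fast_fraction) * start, slow_decay, 0.0)
                    continue
                if (name == "adaptation2" and first == second
                        and per_stage.get("adaptation1") is not None):
                    # control trials: one uninterrupted 900 s segment
                    per_stage[name] = per_stage["adaptation1"]
                    curve = per_stage["adaptation1"]
                    y = float(curve(900.0))
                    continue
                tgt = target(stage, parameter)
                b = fast_decay
                if name == "adaptation2":
                    congruent = protocol.trial_type.congruent
                    if congruent is True:
                        b = fast_decay * savings_multiplier
                    elif congruent is False:
                        b = fast_decay * interference_multiplier
                gap = y - tgt
                curve = StageCurve(fast_fraction * gap, b,
                                   (1 - fast_fraction) * gap, slow_decay,
                                   tgt)
                per_stage[name] = curve
                y = float(curve(stage.window.duration))
            curves[parameter] = per_stage
        return cls(curves, noise_sd=noise_sd, compliance=compliance,
                   savings_multiplier=savings_multiplier,
                   interference_multiplier=interference_multiplier,
                   seed=seed, timing_jitter_frac=timing_jitter_frac)


@dataclass
class GaitRecording:
    """Marker + force recording sampled uniformly (default 100 Hz)."""

    sampling_rate: float       # Hz
    time: np.ndarray           # s
    lheel_ap: np.ndarray       # m, anterior-posterior left heel position
    rheel_ap: np.ndarray       # m
    lgrf: np.ndarray           # N, vertical ground reaction force
    rgrf: np.ndarray           # N
    body_weight: float         # N
    stride_time_hint: Optional[float] = None  # s, used for refractory window

    def __post_init__(self) -> None:
        arrays = (self.time, self.lheel_ap, self.rheel_ap,
                  self.lgrf, self.rgrf)
        n = len(self.time)
        if any(len(a) != n for a in arrays):
            raise ValidationError("recording channels differ in length")
        for a in arrays:
            if not np.all(np.isfinite(a)):
                raise ValidationError("recording contains non-finite values")
        dt = np.diff(self.time)
        if n >= 2 and np.any(np.abs(dt - 1.0 / self.sampling_rate) > 1e-6):
            raise ValidationError("recording must be uniformly sampled")
        if np.any(self.lgrf < 0) or np.any(self.rgrf < 0):
            raise ValidationError("forces must be non-negative")
        if self.body_weight <= 0:
            raise ValidationError("body weight must be positive")


def _segments(protocol: TrialProtocol, stage_curves: Mapping[str, StageCurve]):
    """Merge consecutive stages with equal curves into (start, end, curve)."""
    segs = []
    for stage in protocol.stages:
        curve = stage_curves[stage.name]
        if segs and segs[-1][2] == curve:
            start, _, _ = segs[-1]
            segs[-1] = (start, stage.window.end, curve)
        else:
            segs.append((stage.window.start, stage.window.end, curve))
    return segs


def _stride_onsets(protocol: TrialProtocol, truth: SimulationTruth,
                   rng: np.random.Generator):
    """Jittered stride durations and their onset times covering the trial."""
    T = protocol.comfortable_stride_time
    n_max = int(np.ceil(protocol.duration / (T * 0.5))) + 8
    jitter = truth.timing_jitter_frac * rng.standard_normal(n_max)
    durations = T * np.clip(1.0 + jitter, 0.5, 1.5)
    onsets = np.concatenate([[0.0], np.cumsum(durations)])[:-1]
    keep = onsets + durations <= protocol.duration
    return onsets[keep], durations[keep]


def _mean_curve(protocol: TrialProtocol, truth: SimulationTruth,
                parameter: str, onsets: np.ndarray) -> np.ndarray:
    out = np.empty_like(onsets)
    for start, end, curve in _segments(protocol, truth.curves[parameter]):
        m = (onsets >= start) & (onsets < end)
        out[m] = curve(onsets[m] - start)
    return out


def simulate_asymmetry_series(
    protocol: TrialProtocol,
    truth: SimulationTruth,
    parameter: str,
    rng: Optional[np.random.Generator] = None,
) -> AsymmetrySeries:
    """Simulate a per-stride symmetry-index series for one gait parameter.

    Stride onsets are cumulative sums of jittered stride durations; within
    each curve segment the mean trajectory is the segment's
    double-exponential evaluated at segment-relative time, with i.i.d.
    Gaussian noise (sd ``truth.noise_sd``) added per stride.  Reproducible
    under a fixed ``truth.seed``.
    """
    if parameter not in PARAMETERS:
        raise ValidationError(f"unknown parameter {parameter!r}")
    if rng is None:
        stream = {"step_length": 0, "step_time": 1}[parameter]
        rng = np.random.default_rng(
            np.random.SeedSequence([int(truth.seed), stream]))
    onsets, _ = _stride_onsets(protocol, truth, rng)
    mean = _mean_curve(protocol, truth, parameter, onsets)
    values = mean + truth.noise_sd * rng.standard_normal(len(onsets))
    return AsymmetrySeries(parameter, onsets, np.clip(values, -200.0, 200.0))


def simulate_strides(
    protocol: TrialProtocol, truth: SimulationTruth
) -> StrideSeries:
    """Simulate alternating step records realizing both parameters' series.

    Both gait parameters share one set of stride onsets.  Per stride, the
    left/right step times split the stride duration according to the
    step-time asymmetry, and the left/right step lengths split twice the
    mean step length (comfortable speed x stride duration / 2) according to
    the step-length asymmetry, so recomputing the symmetry index from the
    step records reproduces the simulated asymmetry series exactly.
    """
    root = np.random.SeedSequence(int(truth.seed))
    rng_t, rng_sl, rng_st = (np.random.default_rng(s)
                             for s in root.spawn(3))
    onsets, durations = _stride_onsets(protocol, truth, rng_t)
    n = len(onsets)

    asym = {}
    for parameter, rng in (("step_length", rng_sl), ("step_time", rng_st)):
        mean = _mean_curve(protocol, truth, parameter, onsets)
        vals = mean + truth.noise_sd * rng.standard_normal(n)
        asym[parameter] = np.clip(vals, -199.0, 199.0)

    mean_st = durations / 2.0
    st_l = mean_st * (1.0 + asym["step_time"] / 200.0)
    st_r = mean_st * (1.0 - asym["step_time"] / 200.0)
    mean_sl = protocol.comfortable_speed * durations / 2.0
    sl_l = mean_sl * (1.0 + asym["step_length"] / 200.0)
    sl_r = mean_sl * (1.0 - asym["step_length"] / 200.0)

    sides = np.empty(2 * n, dtype=object)
    times = np.empty(2 * n)
    lengths = np.empty(2 * n)
    step_times = np.empty(2 * n)
    sides[0::2], sides[1::2] = "L", "R"
    times[0::2] = onsets + st_l          # left heel strike completes L step
    times[1::2] = onsets + durations     # right heel strike completes stride
    lengths[0::2], lengths[1::2] = sl_l, sl_r
    step_times[0::2], step_times[1::2] = st_l, st_r
    return StrideSeries(sides, times, lengths, step_times)


def simulate_recording(
    protocol: TrialProtocol,
    truth: SimulationTruth,
    sampling_rate: float = 100.0,
    body_weight: float = 700.0,
    double_support_s: float = 0.11,
    ramp_s: float = 0.04,
) -> tuple[GaitRecording, StrideSeries]:
    """Synthesize a marker/force recording realizing a stride series.

    Heel AP trajectories are piecewise linear: at its heel strike a foot
    lands one step length anterior to the stance foot, translates backward
    with its belt during stance, and swings linearly to its next landing.
    A foot's stance ends ``double_support_s`` after the contralateral heel
    strike, so double support survives even strongly asymmetric step
    timing.  Vertical force is a trapezoidal body-weight pulse per stance
    whose ramps span several samples, so interpolated threshold crossings
    locate the heel strike to well within one sample.  The ground-truth
    stride series is returned alongside.
    """
    strides = simulate_strides(protocol, truth)
    if np.min(strides.step_times) < 4.0 / sampling_rate:
        raise ValidationError(
            "step time shorter than 4 samples at the requested rate")

    n_samples = int(np.floor(protocol.duration * sampling_rate)) + 1
    time = np.arange(n_samples) / sampling_rate
    pos = {"L": np.zeros(n_samples), "R": np.zeros(n_samples)}
    grf = {"L": np.zeros(n_samples), "R": np.zeros(n_samples)}

    def belt_speed(side: str, t: float) -> float:
        stage = protocol.stage_at(min(t, protocol.duration - 1e-9))
        return (stage.left_belt_speed if side == "L"
                else stage.right_belt_speed)

    # event list: (time, side, step_length); bootstrap right contact at t=0
    events = [(0.0, "R", strides.step_lengths[0])]
    events += list(zip(strides.times, strides.sides, strides.step_lengths))
    median_step = float(np.median(strides.step_times))

    # landing positions via the alternating-support recursion
    last = {}  # side -> (hs_time, landing_pos, belt_speed)
    knots = {"L": ([], []), "R": ([], [])}
    for k, (t, side, length) in enumerate(events):
        other = "R" if side == "L" else "L"
        if other in last:
            t0, p0, v0 = last[other]
            p_other = p0 - v0 * (t - t0)
            p_land = p_other + length
        else:
            p_land = length / 2.0
        v = belt_speed(side, t)
        last[side] = (t, p_land, v)
        # stance lasts until shortly after the contralateral heel strike
        t_next = events[k + 1][0] if k + 1 < len(events) \
            else t + median_step
        stance = (t_next - t) + double_support_s
        kt, kp = knots[side]
        kt.extend([t, t + stance])
        kp.extend([p_land, p_land - v * stance])
        # force pulse: up-ramp at heel strike, down-ramp before toe-off
        i0 = np.searchsorted(time, t)
        i1 = np.searchsorted(time, min(t + stance, time[-1]))
        seg = time[i0:i1]
        up = np.clip((seg - t) / ramp_s, 0.0, 1.0)
        down = np.clip((t + stance - seg) / ramp_s, 0.0, 1.0)
        grf[side][i0:i1] = np.maximum(grf[side][i0:i1],
                                      body_weight * np.minimum(up, down))

    for side in ("L", "R"):
        kt, kp = knots[side]
        pos[side] = np.interp(time, kt, kp)

    recording = GaitRecording(
        sampling_rate=sampling_rate,
        time=time,
        lheel_ap=pos["L"],
        rheel_ap=pos["R"],
        lgrf=grf["L"],
        rgrf=grf["R"],
        body_weight=body_weight,
        stride_time_hint=protocol.comfortable_stride_time,
    )
    return recording, strides


#: Log-normal spread of decay constants between subjects and between
#: trials within a subject.  0.3 / 0.4 reproduce the order-of-magnitude
#: heterogeneity seen in healthy-cohort adaptation rates while keeping a
#: doubled decay constant detectable in a ten-subject repeated-measures
#: design.
DEFAULT_BETWEEN_SUBJECT_SIGMA = 0.3
DEFAULT_WITHIN_SUBJECT_SIGMA = 0.4

#: Baseline decay constants used by the cohort-level generator, 1/s.
DEFAULT_COMPONENT_RATES = {"explicit": DEFAULT_FAST_DECAY,
                           "implicit": DEFAULT_SLOW_DECAY}


def simulate_decay_table(
    n_subjects: int = 10,
    trials: tuple[str, ...] = ("TS", "TC", "TSC", "TCS", "TSc", "TcS"),
    stages: tuple[str, ...] = ("adaptation", "post"),
    parameters: tuple[str, ...] = ("step_length", "step_time"),
    effects: Optional[Mapping[tuple, float]] = None,
    between_subject_sigma: float = DEFAULT_BETWEEN_SUBJECT_SIGMA,
    within_subject_sigma: float = DEFAULT_WITHIN_SUBJECT_SIGMA,
    component_rates: Optional[Mapping[str, float]] = None,
    seed: int = 0,
):
    """Simulate a cohort-level decay-constant table directly.

    Each cell is a log-normal perturbation of the component's baseline
    rate: a subject-level multiplier (sd ``between_subject_sigma`` on the
    log scale, shared across that subject's trials) times an independent
    trial-level multiplier (sd ``within_subject_sigma``), times any
    condition effect.  ``effects`` maps ``(trial, stage, parameter,
    component)`` keys — with ``None`` entries acting as wildcards — to
    multiplicative effects on the decay constant, e.g. a x2 facilitation
    of the explicit rate in one trial.  Returns a tidy table with columns
    subject, trial, stage, parameter, component, value.

    This generator exercises the statistics battery in isolation: the
    within-subject spread is what rank-based repeated-measures tests see,
    while the subject-level multiplier cancels within blocks.
    """
    import pandas as pd

    rates = dict(DEFAULT_COMPONENT_RATES if component_rates is None
                 else component_rates)
    effects = dict(effects or {})
    rng = np.random.default_rng(int(seed))
    rows = []
    for s in range(n_subjects):
        subject = f"S{s:02d}"
        subj_mult = {comp: float(np.exp(between_subject_sigma
                                        * rng.standard_normal()))
                     for comp in rates}
        for trial in trials:
            for stage in stages:
                for parameter in parameters:
                    for comp, base in rates.items():
                        mult = 1.0
                        for (et, es, ep, ec), m in effects.items():
                            if ((et is None or et == trial)
                                    and (es is None or es == stage)
                                    and (ep is None or ep == parameter)
                                    and (ec is None or ec == comp)):
                                mult *= m
                        value = (base * subj_mult[comp] * mult
                                 * float(np.exp(within_subject_sigma
                                                * rng.standard_normal())))
                        rows.append(dict(subject=subject, trial=trial,
                                         stage=stage, parameter=parameter,
                                         component=comp, value=value))
    return pd.DataFrame(rows)
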