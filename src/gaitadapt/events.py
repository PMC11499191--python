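"""Stride extraction and symmetry-index computation.

Step-level spatiotemporal parameters are extracted from heel-marker
anterior-posterior positions and vertical ground reaction forces: a heel
strike is an upward force crossing through a fraction of body weight, step
length is the heel-to-heel AP distance at the leading foot's heel strike,
and a step time is the interval from the contralateral heel strike to the
ipsilateral one.  Per-stride asymmetry of a gait parameter is the symmetry
index

    SI = (left - right) / mean(left, right) * 100   [%]

which is negative when the parameter is larger on the right leg, bounded in
(-200, 200) for positive inputs, and scale-invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import signal

from .errors import EmptySeriesError, ValidationError

__all__ = [
    "StrideSeries",
    "AsymmetrySeries",
    "symmetry_index",
    "detect_steps",
    "asymmetry_series",
    "filter_asymmetry",
    "eligibility_check",
    "summarize_baseline",
]

#: Default heel-strike detection threshold as a fraction of body weight.
DEFAULT_FORCE_THRESHOLD_FRACTION = 0.05

#: Eligibility bound on baseline symmetry index, % (inclusive).
ELIGIBILITY_LIMIT_PCT = 6.0


@dataclass
class StrideSeries:
    """Alternating per-step records (side, heel-strike time, length, time).

    ``times`` are heel-strike instants in seconds, strictly increasing with
    alternating ``sides``; ``step_lengths`` (m) and ``step_times`` (s) are
    positive.  ``stage`` holds per-step stage labels once assigned.
    """

    sides: np.ndarray          # array of "L"/"R"
    times: np.ndarray          # s
    step_lengths: np.ndarray   # m
    step_times: np.ndarray     # s
    stage: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.sides = np.asarray(self.sides, dtype=object)
        self.times = np.asarray(self.times, dtype=float)
        self.step_lengths = np.asarray(self.step_lengths, dtype=float)
        self.step_times = np.asarray(self.step_times, dtype=float)
        n = len(self.times)
        if not (len(self.sides) == len(self.step_lengths)
                == len(self.step_times) == n):
            raise ValidationError("stride series fields differ in length")
        if n == 0:
            raise EmptySeriesError("stride series is empty")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("heel-strike times must strictly increase")
        if np.any(self.sides[1:] == self.sides[:-1]):
            raise ValidationError("step sides must alternate")
        if np.any(self.step_lengths <= 0) or np.any(self.step_times <= 0):
            raise ValidationError("step lengths and times must be positive")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self):
        import pandas as pd

        data = {
            "side": self.sides,
            "time_s": self.times,
            "step_length_m": self.step_lengths,
            "step_time_s": self.step_times,
        }
        if self.stage is not None:
            data["stage"] = self.stage
        return pd.DataFrame(data)


@dataclass
class AsymmetrySeries:
    """Per-stride symmetry-index values for one gait parameter.

    ``t`` holds stride timestamps in seconds (generally non-uniform), and
    ``asymmetry`` the corresponding symmetry index in percent.  ``stage``
    carries per-stride stage labels once the series has been segmented.
    """

    parameter: str             # "step_length" | "step_time"
    t: np.ndarray              # s
    asymmetry: np.ndarray      # %
    filtered: bool = False
    stage: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.parameter not in ("step_length", "step_time"):
            raise ValidationError(f"unknown parameter {self.parameter!r}")
        self.t = np.asarray(self.t, dtype=float)
        self.asymmetry = np.asarray(self.asymmetry, dtype=float)
        if self.t.shape != self.asymmetry.shape or self.t.ndim != 1:
            raise ValidationError("t and asymmetry must be 1-D, same length")
        if len(self.t) == 0:
            raise EmptySeriesError("asymmetry series is empty")
        if not np.all(np.isfinite(self.asymmetry)):
            raise ValidationError("asymmetry values must be finite")
        if np.any(np.abs(self.asymmetry) > 200.0):
            raise ValidationError(
                "symmetry index outside [-200, 200]: not realizable from "
                "positive step parameters"
            )

    def __len__(self) -> int:
        return len(self.t)

    def restrict(self, start: float, end: float,
                 rezero: bool = False) -> "AsymmetrySeries":
        """Sub-series on [start, end); optionally re-zero the time axis."""
        m = (self.t >= start) & (self.t < end)
        if not np.any(m):
            raise EmptySeriesError(
                f"no strides in window [{start}, {end}) s"
            )
        t = self.t[m] - (start if rezero else 0.0)
        stage = self.stage[m] if self.stage is not None else None
        return AsymmetrySeries(self.parameter, t, self.asymmetry[m],
                               self.filtered, stage)


def symmetry_index(left, right):
    """Symmetry index in percent: (L - R) / mean(L, R) * 100.

    Accepts scalars or arrays of positive values.  Negative iff the
    right-side value is larger; antisymmetric under swapping sides and
    invariant to a common positive scaling.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if np.any(left <= 0) or np.any(right <= 0):
        raise ValidationError("symmetry_index requires positive inputs")
    out = (left - right) / ((left + right) / 2.0) * 100.0
    return float(out) if out.ndim == 0 else out


def _threshold_crossings(force: np.ndarray, time: np.ndarray,
                         threshold: float, refractory: float) -> np.ndarray:
    """Interpolated upward-crossing times of ``force`` through ``threshold``,
    separated by at least ``refractory`` seconds."""
    below = force[:-1] < threshold
    above = force[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    times = []
    last = -np.inf
    for i in idx:
        frac = (threshold - force[i]) / (force[i + 1] - force[i])
        t = time[i] + frac * (time[i + 1] - time[i])
        if t - last >= refractory:
            times.append(t)
            last = t
    return np.asarray(times)


def detect_steps(recording, force_threshold_fraction: float =
                 DEFAULT_FORCE_THRESHOLD_FRACTION) -> StrideSeries:
    """Extract alternating step records from a gait recording.

    Heel strikes are upward crossings of each side's vertical ground
    reaction force through ``force_threshold_fraction x body_weight``
    (crossing instants linearly interpolated between samples), with a
    refractory period of a quarter of the comfortable stride time.  Step
    length is the absolute heel-to-heel AP distance at the leading foot's
    heel strike; a step time is the interval since the contralateral heel
    strike.  Non-alternating contacts are dropped with a warning.

    Both heels translate with the belts during stance, so the heel-to-heel
    separation drifts linearly right after contact; step length is read by
    extrapolating the separation at the two samples following the event
    back to the event time, which cancels the belt-induced drift.
    """
    if not 0 < force_threshold_fraction < 1:
        raise ValidationError("force_threshold_fraction must be in (0, 1)")
    threshold = force_threshold_fraction * recording.body_weight
    stride_hint = recording.stride_time_hint or 1.0
    refractory = 0.25 * stride_hint

    events = []  # (time, side)
    for side, force in (("L", recording.lgrf), ("R", recording.rgrf)):
        for t in _threshold_crossings(force, recording.time,
                                      threshold, refractory):
            events.append((t, side))
    if not events:
        raise EmptySeriesError("no heel strikes detected in either channel")
    events.sort()

    # enforce side alternation by dropping the later duplicate contact
    cleaned = [events[0]]
    dropped = 0
    for t, side in events[1:]:
        if side == cleaned[-1][1]:
            dropped += 1
            continue
        cleaned.append((t, side))
    if dropped:
        warnings.warn(
            f"dropped {dropped} non-alternating contact(s) during "
            "resynchronization",
            stacklevel=2,
        )
    if len(cleaned) < 2:
        raise EmptySeriesError("fewer than two alternating heel strikes")

    separation = recording.lheel_ap - recording.rheel_ap
    n_samples = len(recording.time)
    sides, times, lengths, step_times = [], [], [], []
    for (t_prev, _), (t, side) in zip(cleaned[:-1], cleaned[1:]):
        i1 = int(np.searchsorted(recording.time, t)) + 1
        i1 = min(max(i1, 0), n_samples - 2)
        d1, d2 = separation[i1], separation[i1 + 1]
        slope = (d2 - d1) * recording.sampling_rate
        length = abs(d1 + slope * (t - recording.time[i1]))
        if length <= 0:
            continue
        sides.append(side)
        times.append(t)
        lengths.append(length)
        step_times.append(t - t_prev)
    return StrideSeries(np.array(sides, dtype=object), np.array(times),
                        np.array(lengths), np.array(step_times))


def asymmetry_series(strides: StrideSeries, parameter: str) -> AsymmetrySeries:
    """Per-stride symmetry index from alternating step records.

    Each left step is paired with the right step that completes the stride;
    the stride timestamp is the onset of the stride, i.e. the heel strike
    that begins the left step.
    """
    if parameter == "step_length":
        values = strides.step_lengths
    elif parameter == "step_time":
        values = strides.step_times
    else:
        raise ValidationError(f"unknown parameter {parameter!r}")

    # start pairing at the first left step
    start = 0 if strides.sides[0] == "L" else 1
    t_out, a_out = [], []
    for i in range(start, len(strides) - 1, 2):
        left, right = values[i], values[i + 1]
        t_out.append(strides.times[i] - strides.step_times[i])
        a_out.append(symmetry_index(left, right))
    if not t_out:
        raise EmptySeriesError("no complete left-right stride pairs")
    return AsymmetrySeries(parameter, np.array(t_out), np.array(a_out))


def filter_asymmetry(series: AsymmetrySeries, order: int = 1,
                     normalized_cutoff: float = 1.0) -> AsymmetrySeries:
    """Forward single-pass low-pass Butterworth filter on the stride series.

    ``normalized_cutoff`` is a fraction of the Nyquist frequency of the
    stride-indexed sequence.  The default 1.0 places the cutoff at Nyquist,
    which has unit gain everywhere and returns the series unchanged; 0.1 is
    a reasonable choice for visible stride-level smoothing.
    """
    if not 0 < normalized_cutoff <= 1:
        raise ValidationError("normalized_cutoff must be in (0, 1]")
    if len(series) < 4:
        raise ValidationError("series too short to filter (need >= 4)")
    if normalized_cutoff == 1.0:
        # Butterworth with cutoff at Nyquist is the identity
        return replace(series, asymmetry=series.asymmetry.copy(),
                       filtered=True)
    b, a = signal.butter(order, normalized_cutoff, btype="low")
    # steady-state initial conditions: no startup transient, exact DC gain
    zi = signal.lfilter_zi(b, a) * series.asymmetry[0]
    out, _ = signal.lfilter(b, a, series.asymmetry, zi=zi)
    return replace(series, asymmetry=out, filtered=True)


def eligibility_check(baseline_sla: float, baseline_sta: float,
                      limit: float = ELIGIBILITY_LIMIT_PCT) -> bool:
    """Baseline screen: eligible iff both |SLA| and |STA| are within the
    symmetry-index bound (inclusive, default +-6 %)."""
    if not (np.isfinite(baseline_sla) and np.isfinite(baseline_sta)):
        raise ValidationError("baseline asymmetries must be finite")
    return abs(baseline_sla) <= limit and abs(baseline_sta) <= limit


def summarize_baseline(values) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation of baseline
    asymmetries across a cohort."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("need at least two values to summarize")
    return float(values.mean()), float(values.std(ddof=1))
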