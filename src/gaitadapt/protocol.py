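"""Construction of the six walking-trial protocols.

Each trial is 23 min of uninterrupted treadmill walking: a 3 min tied-belt
baseline, a 15 min adaptation period, and a 5 min tied-belt post-adaptation
stage.  The adaptation period carries one of two asymmetric interventions,
or a sequential combination of both:

* **SBT** — split-belt treadmill at a 2:1 speed ratio.  The left belt runs
  at 4/3 of the subject's comfortable speed and the right at 2/3, so the
  belt-speed mean equals the comfortable speed.  Symmetric rhythmic cues
  (half the comfortable stride time each side) are played during SBT so the
  auditory load matches the cueing trials.
* **ARAC** — asymmetric rhythmic auditory cueing at a 2:1 (or mirrored 1:2)
  inter-cue ratio.  Left and right cue durations sum to the comfortable
  stride time, prescribing a step-time asymmetry while the belts stay tied.

The six trial codes are ``TS`` and ``TC`` (single intervention spanning the
whole adaptation period) plus four sequential combinations in which each
intervention occupies one 7.5 min adaptation half: ``TSC``/``TCS``
(congruent — both interventions push asymmetry toward the same side) and
``TSc``/``TcS`` (incongruent — the cueing ratio is mirrored so the imposed
asymmetries oppose each other).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .errors import ValidationError

__all__ = [
    "Intervention",
    "TrialType",
    "StageWindow",
    "Stage",
    "TrialProtocol",
    "build_protocol",
    "latin_square_orders",
    "imposed_asymmetry",
    "STAGE_DURATIONS_S",
]

#: Stage durations in seconds: baseline, adaptation half 1, half 2, post.
STAGE_DURATIONS_S = {
    "baseline": 180.0,
    "adaptation1": 450.0,
    "adaptation2": 450.0,
    "post": 300.0,
}

STAGE_ORDER = ("baseline", "adaptation1", "adaptation2", "post")


class Intervention(str, Enum):
    """What is imposed on the subject during one adaptation half."""

    NONE = "none"            # tied belts, no (or symmetric) cues
    SBT = "sbt"              # split belts 2:1 (left fast)
    ARAC_2_1 = "arac_2_1"    # left cue duration twice the right
    ARAC_1_2 = "arac_1_2"    # mirrored cueing (right cue twice the left)


class TrialType(str, Enum):
    """The six trial codes.

    ``S`` = split-belt treadmill, ``C`` = asymmetric cueing; a lowercase
    ``c`` marks the mirrored (incongruent) cueing ratio.
    """

    TS = "TS"
    TC = "TC"
    TSC = "TSC"
    TCS = "TCS"
    TSc = "TSc"
    TcS = "TcS"

    @property
    def sequence(self) -> tuple[Intervention, Intervention]:
        """Interventions for (adaptation1, adaptation2).

        Control trials repeat the same intervention in both halves so that
        downstream truncation logic is uniform across trial types.
        """
        return _SEQUENCES[self]

    @property
    def congruent(self) -> Optional[bool]:
        """True/False for sequential combinations, None for controls."""
        if self in (TrialType.TS, TrialType.TC):
            return None
        return self in (TrialType.TSC, TrialType.TCS)

    @property
    def is_control(self) -> bool:
        return self in (TrialType.TS, TrialType.TC)


_SEQUENCES = {
    TrialType.TS: (Intervention.SBT, Intervention.SBT),
    TrialType.TC: (Intervention.ARAC_2_1, Intervention.ARAC_2_1),
    TrialType.TSC: (Intervention.SBT, Intervention.ARAC_2_1),
    TrialType.TCS: (Intervention.ARAC_2_1, Intervention.SBT),
    TrialType.TSc: (Intervention.SBT, Intervention.ARAC_1_2),
    TrialType.TcS: (Intervention.ARAC_1_2, Intervention.SBT),
}


@dataclass(frozen=True)
class StageWindow:
    """Half-open time window [start, end) in seconds from recording start."""

    name: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.name not in STAGE_ORDER:
            raise ValidationError(f"unknown stage name {self.name!r}")
        if not self.end > self.start >= 0:
            raise ValidationError(
                f"stage {self.name}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class Stage:
    """One protocol stage: its window plus belt speeds and cue durations.

    Cue durations are ``None`` when no rhythmic cues are played (baseline
    and post-adaptation).
    """

    window: StageWindow
    intervention: Intervention
    left_belt_speed: float
    right_belt_speed: float
    left_cue_duration: Optional[float]
    right_cue_duration: Optional[float]

    @property
    def name(self) -> str:
        return self.window.name


@dataclass(frozen=True)
class TrialProtocol:
    """Fully resolved stage schedule for one trial of one subject."""

    trial_type: TrialType
    comfortable_speed: float          # m/s
    comfortable_stride_time: float    # s
    stages: tuple[Stage, ...]

    @property
    def duration(self) -> float:
        return self.stages[-1].window.end

    def stage(self, name: str) -> Stage:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)

    def stage_at(self, t: float) -> Stage:
        """Stage whose half-open window contains time ``t``."""
        for s in self.stages:
            if s.window.contains(t):
                return s
        raise ValidationError(
            f"t={t} s is outside the protocol [0, {self.duration}) s"
        )

    def windows(self) -> tuple[StageWindow, ...]:
        return tuple(s.window for s in self.stages)

    def to_dict(self) -> dict:
        """Config-document form (round-trips through YAML/JSON)."""
        return {
            "trial_type": self.trial_type.value,
            "comfortable_speed_mps": self.comfortable_speed,
            "comfortable_stride_time_s": self.comfortable_stride_time,
            "stage_durations_s": {
                s.name: s.window.duration for s in self.stages
            },
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "TrialProtocol":
        overrides = doc.get("stage_durations_s")
        return build_protocol(
            TrialType(doc["trial_type"]),
            doc["comfortable_speed_mps"],
            doc["comfortable_stride_time_s"],
            stage_durations=overrides,
        )


def _stage_intervention(
    trial_type: TrialType, stage_name: str
) -> Intervention:
    if stage_name in ("baseline", "post"):
        return Intervention.NONE
    first, second = trial_type.sequence
    return first if stage_name == "adaptation1" else second


def build_protocol(
    trial_type: TrialType,
    comfortable_speed: float,
    comfortable_stride_time: float,
    stage_durations: Optional[dict] = None,
) -> TrialProtocol:
    """Build the stage schedule, belt speeds and cue durations for one trial.

    Parameters
    ----------
    trial_type
        One of the six trial codes.
    comfortable_speed
        The subject's comfortable tied-belt speed in m/s (> 0).  The split
        belts are set to 4/3 and 2/3 of this value, preserving its mean.
    comfortable_stride_time
        The subject's comfortable stride time in s (> 0).  Asymmetric cue
        durations are 2/3 and 1/3 of this value; they always sum to it.
    stage_durations
        Optional per-stage duration overrides (seconds), keyed by stage
        name.  Defaults to 180 / 450 / 450 / 300 s.
    """
    if not comfortable_speed > 0:
        raise ValidationError("comfortable_speed must be > 0")
    if not comfortable_stride_time > 0:
        raise ValidationError("comfortable_stride_time must be > 0")
    trial_type = TrialType(trial_type)

    durations = dict(STAGE_DURATIONS_S)
    if stage_durations:
        unknown = set(stage_durations) - set(durations)
        if unknown:
            raise ValidationError(f"unknown stage names {sorted(unknown)}")
        durations.update(stage_durations)

    v, T = comfortable_speed, comfortable_stride_time
    stages = []
    t0 = 0.0
    for name in STAGE_ORDER:
        window = StageWindow(name, t0, t0 + durations[name])
        t0 = window.end
        iv = _stage_intervention(trial_type, name)
        if iv is Intervention.SBT:
            left_v, right_v = 4.0 / 3.0 * v, 2.0 / 3.0 * v
            # symmetric cues during SBT keep the auditory load consistent
            left_cue = right_cue = T / 2.0
        elif iv is Intervention.ARAC_2_1:
            left_v = right_v = v
            left_cue, right_cue = 2.0 / 3.0 * T, T / 3.0
        elif iv is Intervention.ARAC_1_2:
            left_v = right_v = v
            left_cue, right_cue = T / 3.0, 2.0 / 3.0 * T
        else:
            left_v = right_v = v
            left_cue = right_cue = None
        stages.append(
            Stage(window, iv, left_v, right_v, left_cue, right_cue)
        )
    return TrialProtocol(trial_type, v, T, tuple(stages))


def latin_square_orders(
    trial_types: Sequence[TrialType],
) -> list[list[TrialType]]:
    """Six trial orders forming a Latin square over the six trial types.

    Each trial appears exactly once per order (row) and exactly once per
    position (column) across orders.  The construction is cyclic, seeded by
    the input order; any permutation of the six codes yields a valid square.
    """
    types = [TrialType(t) for t in trial_types]
    if len(types) != 6 or len(set(types)) != 6:
        raise ValidationError(
            "latin_square_orders requires exactly the six distinct trial types"
        )
    return [types[i:] + types[:i] for i in range(6)]


def imposed_asymmetry(
    protocol: TrialProtocol, stage: Stage, parameter: str
) -> Optional[float]:
    """Closed-form symmetry index (%) imposed by a stage, when one exists.

    Asymmetric cueing prescribes step times directly, so for
    ``parameter="step_time"`` the imposed asymmetry follows from the cue
    durations via the symmetry index: a 2:1 cue split gives +66.67 %, the
    mirrored 1:2 split gives -66.67 %.  Baseline and post-adaptation impose
    0 %.  Split-belt stages (for either parameter) and step length under
    cueing have no closed-form imposed value: the achieved asymmetry is an
    emergent behavioural quantity, and ``None`` is returned rather than a
    guess.
    """
    if parameter not in ("step_length", "step_time"):
        raise ValidationError(f"unknown parameter {parameter!r}")
    if stage.intervention is Intervention.NONE:
        return 0.0
    if stage.intervention is Intervention.SBT:
        return None
    if parameter != "step_time":
        return None
    left, right = stage.left_cue_duration, stage.right_cue_duration
    return (left - right) / ((left + right) / 2.0) * 100.0
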