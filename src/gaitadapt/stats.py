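"""Stage segmentation, decay-constant tables, and the nonparametric battery.

The per-stride asymmetry series is segmented into the four protocol stages
by half-open windows.  Adaptation fits use the first 7.5 min of the
adaptation period for the single-intervention control trials (so their
steady state is comparable with the sequential trials) and the second
adaptation half for sequential trials; de-adaptation fits always use the
post-adaptation stage.  Decay constants are organized by subject x trial x
stage x parameter x component, then compared across three condition
families — SBT (TS, TCS, TcS), ARAC (TC, TSC, TSc), and TS vs TC — with
Friedman's test followed by pairwise Wilcoxon signed-rank tests when the
Friedman test rejects.  A Shapiro-Wilk gate decides between the parametric
and nonparametric branch; only the nonparametric branch is implemented and
the gate's decision is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateStatisticError,
    EmptySeriesError,
    ValidationError,
)
from .events import AsymmetrySeries
from .protocol import TrialProtocol, TrialType

__all__ = [
    "StatReport",
    "segment_stages",
    "adaptation_window",
    "post_window",
    "stage_means",
    "normality_gate",
    "friedman",
    "wilcoxon_pairs",
    "run_battery",
    "DEFAULT_FAMILIES",
    "DECAY_TABLE_COLUMNS",
]

#: Canonical column order of a decay table.
DECAY_TABLE_COLUMNS = ("subject", "trial", "stage", "parameter",
                       "component", "value")

#: The three comparison families: SBT adaptation, ARAC adaptation, and the
#: control-trial contrast.
DEFAULT_FAMILIES = (
    ("TS", "TCS", "TcS"),
    ("TC", "TSC", "TSc"),
    ("TS", "TC"),
)

#: Strides averaged for the late-adaptation and early-post summaries.
SUMMARY_STRIDES = 15


@dataclass
class StatReport:
    """One statistical test result within the battery."""

    test: str                       # "friedman" | "wilcoxon" | "shapiro"
    statistic: float
    df: Optional[int]
    p: float
    conditions: tuple[str, ...]
    gate: str = "nonparametric"     # branch decided by the normality gate
    context: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValidationError("p-value outside [0, 1]")


def segment_stages(series: AsymmetrySeries,
                   protocol: TrialProtocol) -> AsymmetrySeries:
    """Assign every stride to exactly one stage by the half-open windows.

    Returns a copy of the series with per-stride stage labels attached.
    Strides at or beyond the protocol's end are a contract violation.
    """
    t = series.t
    if np.any(t < 0) or np.any(t >= protocol.duration):
        raise ValidationError(
            "stride timestamps outside the protocol duration")
    labels = np.empty(len(t), dtype=object)
    for stage in protocol.stages:
        m = (t >= stage.window.start) & (t < stage.window.end)
        labels[m] = stage.name
    return AsymmetrySeries(series.parameter, t.copy(),
                           series.asymmetry.copy(), series.filtered, labels)


def adaptation_window(trial_type: TrialType,
                      series: AsymmetrySeries,
                      protocol: TrialProtocol) -> AsymmetrySeries:
    """Sub-series used for the adaptation fit, time re-zeroed at its start.

    Control trials (TS, TC) use the first 7.5 min of the adaptation period;
    sequential trials use the second adaptation half, where re-adaptation
    to the second intervention unfolds.
    """
    trial_type = TrialType(trial_type)
    if trial_type.is_control:
        w = protocol.stage("adaptation1").window
    else:
        w = protocol.stage("adaptation2").window
    try:
        return series.restrict(w.start, w.end, rezero=True)
    except EmptySeriesError as exc:
        raise ValidationError(
            f"adaptation window [{w.start}, {w.end}) s is empty") from exc


def post_window(series: AsymmetrySeries,
                protocol: TrialProtocol) -> AsymmetrySeries:
    """Post-adaptation sub-series, time re-zeroed at perturbation removal."""
    w = protocol.stage("post").window
    try:
        return series.restrict(w.start, w.end, rezero=True)
    except EmptySeriesError as exc:
        raise ValidationError(
            f"post-adaptation window [{w.start}, {w.end}) s is empty"
        ) from exc


def stage_means(series: AsymmetrySeries,
                protocol: TrialProtocol,
                n_strides: int = SUMMARY_STRIDES) -> dict[str, float]:
    """Late-adaptation, early-post-adaptation and baseline summary means.

    Late adaptation averages the last ``n_strides`` strides before the end
    of adaptation; early post-adaptation averages the first ``n_strides``
    strides after perturbation removal; baseline averages the whole
    baseline stage.
    """
    base_w = protocol.stage("baseline").window
    adapt_end = protocol.stage("adaptation2").window.end
    adapt_start = protocol.stage("adaptation1").window.start
    post_w = protocol.stage("post").window

    baseline = series.asymmetry[(series.t >= base_w.start)
                                & (series.t < base_w.end)]
    adapt = series.asymmetry[(series.t >= adapt_start)
                             & (series.t < adapt_end)]
    post = series.asymmetry[(series.t >= post_w.start)
                            & (series.t < post_w.end)]
    for name, values in (("baseline", baseline), ("adaptation", adapt),
                         ("post-adaptation", post)):
        need = n_strides if name != "baseline" else 2
        if len(values) < need:
            raise ValidationError(
                f"{name} window holds {len(values)} strides; "
                f"need at least {need}")
    return {
        "baseline": float(baseline.mean()),
        "late_adaptation": float(adapt[-n_strides:].mean()),
        "early_post": float(post[:n_strides].mean()),
    }


def normality_gate(values_by_condition: dict[str, Sequence[float]],
                   alpha: float = 0.05) -> tuple[str, list[StatReport]]:
    """Shapiro-Wilk screen deciding the statistical branch.

    Any condition with a normality p-value below ``alpha`` (or a
    degenerate, constant condition) routes the analysis to the
    nonparametric branch; otherwise a parametric flag is reported.  Only
    the nonparametric branch is implemented downstream.
    """
    reports = []
    branch = "parametric"
    for name, values in values_by_condition.items():
        values = np.asarray(values, dtype=float)
        if len(values) < 3:
            raise ValidationError(
                f"condition {name!r} needs >= 3 values for the gate")
        if np.ptp(values) == 0:
            reports.append(StatReport("shapiro", np.nan, None, 0.0,
                                      (name,), gate="nonparametric",
                                      context={"degenerate": True}))
            branch = "nonparametric"
            continue
        w, p = sps.shapiro(values)
        reports.append(StatReport("shapiro", float(w), None, float(p),
                                  (name,)))
        if p < alpha:
            branch = "nonparametric"
    for r in reports:
        r.gate = branch
    return branch, reports


def friedman(blocks: np.ndarray,
             conditions: Optional[Sequence[str]] = None) -> StatReport:
    """Friedman rank test over complete blocks (subjects x conditions).

    Within each block the k condition values are ranked with average-rank
    tie handling; the chi-square statistic (with the standard tie
    correction) is referred to a chi-square distribution on k - 1 degrees
    of freedom.
    """
    blocks = np.asarray(blocks, dtype=float)
    if blocks.ndim != 2:
        raise ValidationError("blocks must be a 2-D (subjects x k) array")
    n, k = blocks.shape
    if k < 2 or n < 2:
        raise ValidationError("need >= 2 conditions and >= 2 blocks")
    if not np.all(np.isfinite(blocks)):
        raise ValidationError("blocks must be complete (finite values)")
    ranks = np.apply_along_axis(sps.rankdata, 1, blocks)
    rank_sums = ranks.sum(axis=0)
    chi = (12.0 / (n * k * (k + 1))) * np.sum(rank_sums ** 2) \
        - 3.0 * n * (k + 1)
    # tie correction: per-block sum of (t^3 - t) over tie groups
    ties = 0.0
    for row in blocks:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts ** 3 - counts))
    correction = 1.0 - ties / (n * k * (k * k - 1))
    if correction <= 0:
        chi = 0.0  # every block fully tied: no evidence either way
    else:
        chi = chi / correction
    p = float(sps.chi2.sf(chi, k - 1))
    labels = tuple(conditions) if conditions is not None \
        else tuple(f"c{i}" for i in range(k))
    if len(labels) != k:
        raise ValidationError("condition labels do not match block width")
    return StatReport("friedman", float(chi), k - 1, p, labels)


def wilcoxon_pairs(values_a: Sequence[float], values_b: Sequence[float],
                   labels: tuple[str, str] = ("a", "b"),
                   continuity: bool = False,
                   exact: bool = False) -> StatReport:
    """Two-sided Wilcoxon signed-rank test on paired condition values.

    Zero differences are dropped; by default the p-value uses the normal
    approximation without continuity correction (the convention under
    which a uniformly signed n = 10 sample gives Z = -2.803).  ``exact``
    switches to the exact null distribution.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired samples must be equal-length 1-D")
    d = (a - b)[a != b]
    n = len(d)
    if n == 0:
        raise DegenerateStatisticError("all paired differences are zero")
    if n < 5 and not exact:
        raise ValidationError(
            "need >= 5 nonzero differences for the normal approximation")

    # signed z from the positive-rank sum, with average-rank tie handling
    ranks = sps.rankdata(np.abs(d))
    t_plus = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    for count in np.unique(ranks, return_counts=True)[1]:
        var -= (count ** 3 - count) / 48.0
    if var <= 0:
        raise DegenerateStatisticError("zero variance in signed ranks")
    shift = 0.5 * np.sign(t_plus - mean) if continuity else 0.0
    z = (t_plus - mean - shift) / np.sqrt(var)
    if exact:
        res = sps.wilcoxon(a, b, zero_method="wilcox",
                           alternative="two-sided", method="exact")
        p = float(res.pvalue)
    else:
        p = float(2.0 * sps.norm.sf(abs(z)))
    return StatReport("wilcoxon", float(z), None, p, labels,
                      context={"n_nonzero": int(n), "t_plus": t_plus,
                               "mode": "exact" if exact else "approx"})


def _pivot(decay_table: pd.DataFrame, trials: Sequence[str], stage: str,
           parameter: str, component: str) -> pd.DataFrame:
    sub = decay_table[
        (decay_table["trial"].isin(trials))
        & (decay_table["stage"] == stage)
        & (decay_table["parameter"] == parameter)
        & (decay_table["component"] == component)
    ]
    wide = sub.pivot_table(index="subject", columns="trial",
                           values="value", aggfunc="first")
    missing = [t for t in trials if t not in wide.columns]
    if missing:
        raise ValidationError(
            f"decay table missing cells for trials {missing} at "
            f"stage={stage}, parameter={parameter}, component={component}")
    wide = wide[list(trials)]
    # listwise exclusion: drop subjects with any absent cell in the family
    return wide.dropna(axis=0, how="any")


def run_battery(
    decay_table: pd.DataFrame,
    families: Sequence[Sequence[str]] = DEFAULT_FAMILIES,
    parameters: Sequence[str] = ("step_length", "step_time"),
    components: Sequence[str] = ("explicit", "implicit"),
    stages: Sequence[str] = ("adaptation", "post"),
    alpha: float = 0.05,
    holm: bool = False,
) -> list[StatReport]:
    """Run the full comparison battery over a decay-constant table.

    For each family x parameter x component x stage cell a Friedman test is
    run on the complete blocks; when it rejects at ``alpha``, all pairwise
    Wilcoxon signed-rank tests within the family follow.  Pairwise
    p-values are uncorrected by default; ``holm`` applies a Holm step-down
    adjustment within each family.
    """
    required = set(DECAY_TABLE_COLUMNS)
    if not required.issubset(decay_table.columns):
        raise ValidationError(
            f"decay table must have columns {sorted(required)}")
    reports: list[StatReport] = []
    for family in families:
        family = tuple(family)
        if len(family) < 2:
            raise ValidationError(
                f"comparison family {family} needs >= 2 conditions")
        for parameter in parameters:
            for component in components:
                for stage in stages:
                    wide = _pivot(decay_table, family, stage, parameter,
                                  component)
                    if len(wide) < 2:
                        raise ValidationError(
                            f"fewer than 2 complete blocks for family "
                            f"{family} ({parameter}, {component}, {stage})")
                    ctx = {"family": family, "parameter": parameter,
                           "component": component, "stage": stage}
                    rep = friedman(wide.to_numpy(), conditions=family)
                    rep.context = dict(ctx)
                    reports.append(rep)
                    if rep.p >= alpha:
                        continue
                    pair_reports = []
                    for i in range(len(family)):
                        for j in range(i + 1, len(family)):
                            a, b = wide[family[j]], wide[family[i]]
                            try:
                                pr = wilcoxon_pairs(
                                    a, b, labels=(family[j], family[i]))
                            except ValidationError:
                                # too few pairs for the normal
                                # approximation: use the exact null
                                pr = wilcoxon_pairs(
                                    a, b, labels=(family[j], family[i]),
                                    exact=True)
                            pr.context = dict(ctx)
                            pair_reports.append(pr)
                    if holm:
                        _holm_adjust(pair_reports)
                    reports.extend(pair_reports)
    return reports


def _holm_adjust(reports: list[StatReport]) -> None:
    m = len(reports)
    order = np.argsort([r.p for r in reports])
    running = 0.0
    for rank, idx in enumerate(order):
        adjusted = min(1.0, (m - rank) * reports[idx].p)
        running = max(running, adjusted)
        reports[idx].context["p_holm"] = running
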