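"""Weekly aggregation, missingness screening and the statistics surface.

The analysis pipeline mirrors a two-phase micro-trial evaluation: raw
time-series outcomes are averaged into weekly means per participant,
participant-variable series missing more than 75% of their possible data
are excluded, each outcome is fitted with a linear mixed model (week and
group as fixed factors, random intercept per participant), effect sizes are
reported as partial eta-squared, and p values are corrected with
Benjamini-Hochberg across the outcome family (Bonferroni for post hoc
pairwise contrasts).  Usability questionnaires are scored on the standard
0-100 System Usability Scale.

Mixed-model estimation is delegated to statsmodels' ``MixedLM`` (REML);
this module owns the design construction, the F/df conventions and the
effect-size and multiplicity layers on top of it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WeeklySeries",
    "ModelResult",
    "SUSResponse",
    "HarnessError",
    "weekly_aggregate",
    "missingness_filter",
    "partial_eta_squared",
    "bh_adjust",
    "bonferroni_adjust",
    "sus_score",
    "fit_lmm_harness",
    "evaluate_trial",
    "ALPHA",
    "MISSINGNESS_CUTOFF",
]

ALPHA = 0.05
MISSINGNESS_CUTOFF = 0.75
WEEKS = (1, 2, 3, 4, 5, 6)
SECONDS_PER_WEEK = 7 * 86400.0


class HarnessError(RuntimeError):
    """The mixed-model fit could not be carried out on this design."""


@dataclass(frozen=True)
class WeeklySeries:
    """Weekly means of one variable for one participant (weeks 1..6)."""

    participant_id: str
    variable: str
    values: dict[int, float]
    missing_fraction: float

    def __post_init__(self):
        bad = [w for w in self.values if w not in WEEKS]
        if bad:
            raise ValueError(f"week indices outside 1-6: {bad}")
        if not (0.0 <= self.missing_fraction <= 1.0):
            raise ValueError("missing_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ModelResult:
    """One fixed-effect test: F statistic, dfs, p values and effect size."""

    variable: str
    effect: str  # "time" | "group"
    F: float
    df_num: float
    df_den: float
    p_raw: float
    eta_p_sq: float
    p_adjusted: Optional[float] = None
    n_participants: int = 0
    df_method: str = "classical-rm"


@dataclass(frozen=True)
class SUSResponse:
    """The ten 1-5 items of the System Usability Scale, in order."""

    items: tuple[int, ...]

    def __post_init__(self):
        if len(self.items) != 10:
            raise ValueError("SUS has exactly 10 items")
        if any(not (1 <= int(v) <= 5) for v in self.items):
            raise ValueError("SUS items must be integers 1-5")


def weekly_aggregate(
    timestamps: Sequence[float],
    values: Sequence[float],
    study_start: float,
    participant_id: str = "",
    variable: str = "",
    n_weeks: int = 6,
    expected_per_week: Optional[float] = None,
) -> WeeklySeries:
    """Arithmetic weekly means of a timestamped value stream.

    Values outside the study window are excluded with a warning.  The
    missing fraction is the share of weeks with no data, or — when
    ``expected_per_week`` is given — the shortfall of observed entries
    relative to ``n_weeks * expected_per_week``.
    """
    t = np.asarray(timestamps, dtype=float)
    v = np.asarray(values, dtype=float)
    week_idx = np.floor((t - study_start) / SECONDS_PER_WEEK).astype(int) + 1
    inside = (week_idx >= 1) & (week_idx <= n_weeks)
    if np.any(~inside):
        warnings.warn(
            f"{(~inside).sum()} value(s) outside the {n_weeks}-week study window "
            "were excluded",
            stacklevel=2,
        )
    week_idx, v = week_idx[inside], v[inside]
    keep = ~np.isnan(v)
    week_idx, v = week_idx[keep], v[keep]
    means = {int(w): float(v[week_idx == w].mean()) for w in np.unique(week_idx)}
    if expected_per_week is not None and expected_per_week > 0:
        missing = 1.0 - min(1.0, len(v) / (n_weeks * expected_per_week))
    else:
        missing = 1.0 - len(means) / n_weeks
    return WeeklySeries(participant_id, variable, means, missing)


def missingness_filter(
    series: WeeklySeries, cutoff: float = MISSINGNESS_CUTOFF
) -> bool:
    """Keep decision: True iff the series is retained.

    Exclusion requires *more than* the cutoff fraction missing — a series
    missing exactly 75% of its data is kept.
    """
    return not (series.missing_fraction > cutoff)


def partial_eta_squared(F: float, df_num: float, df_den: float) -> float:
    """Partial eta-squared of a fixed effect: F*df1 / (F*df1 + df2)."""
    if F < 0:
        raise ValueError("F must be nonnegative")
    if df_num <= 0 or df_den <= 0:
        raise ValueError("degrees of freedom must be positive")
    return (F * df_num) / (F * df_num + df_den)


def _check_pvalues(p: np.ndarray) -> None:
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    _check_pvalues(p)
    m = len(p)
    if m == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def bonferroni_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni adjusted p values: min(1, p * m)."""
    p = np.asarray(p_values, dtype=float)
    _check_pvalues(p)
    return np.minimum(p * len(p), 1.0)


def sus_score(resp: SUSResponse) -> float:
    """Standard System Usability Scale score on the 0-100 scale.

    Odd items (positively keyed) contribute item-1, even items 5-item; the
    summed contributions are multiplied by 2.5.
    """
    total = 0
    for i, item in enumerate(resp.items, start=1):
        total += (item - 1) if i % 2 == 1 else (5 - item)
    return 2.5 * total


def fit_lmm_harness(
    weekly: Sequence[WeeklySeries],
    groups: Optional[Mapping[str, str]] = None,
    cutoff: float = MISSINGNESS_CUTOFF,
    alpha: float = ALPHA,
) -> dict[str, ModelResult]:
    """Fit the study LMM for one variable and return the fixed-effect tests.

    ``weekly`` holds one :class:`WeeklySeries` per participant (one
    variable); ``groups`` maps participant ids to arm labels and may be
    omitted for a within-subject-only model.  The model is
    ``value ~ C(week) [+ C(group)]`` with a random intercept per
    participant, fitted by REML via statsmodels MixedLM.  Each factor's F is
    the Wald chi-square of its contrasts divided by the contrast count;
    denominator dfs follow the classical repeated-measures convention
    (``df_num * (N - 1)`` for time, ``N - 2`` for group).  Partial
    eta-squared is derived from F and the dfs; ``p_adjusted`` is left for
    the family-level Benjamini-Hochberg pass.
    """
    import statsmodels.formula.api as smf

    kept = [s for s in weekly if missingness_filter(s, cutoff)]
    if not kept:
        raise HarnessError("no participants survive the missingness filter")
    variable = kept[0].variable
    rows = []
    for s in kept:
        for w, val in s.values.items():
            row = {"pid": s.participant_id, "week": w, "value": val}
            if groups is not None:
                row["group"] = groups[s.participant_id]
            rows.append(row)
    df = pd.DataFrame(rows)
    n_participants = df["pid"].nunique()
    week_levels = sorted(df["week"].unique())
    if n_participants < 2 or len(week_levels) < 2:
        raise HarnessError("need >= 2 participants and >= 2 time points")

    formula = "value ~ C(week)"
    if groups is not None:
        if df["group"].nunique() < 2:
            raise HarnessError("group factor requested but only one group present")
        formula += " + C(group)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, df, groups=df["pid"])
            res = model.fit(reml=True)
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise HarnessError(f"mixed-model fit failed: {exc}") from exc
        if not np.all(np.isfinite(res.params)):
            raise HarnessError("mixed-model fit produced non-finite estimates")

        results: dict[str, ModelResult] = {}
        names = list(res.params.index)  # fixed effects first, then variance terms

        def factor_test(prefix: str, effect: str, df_den: float) -> ModelResult:
            terms = [nm for nm in res.model.exog_names if nm.startswith(prefix)]
            if not terms:
                raise HarnessError(f"no design columns for factor {effect}")
            L = np.zeros((len(terms), len(names)))
            for r, nm in enumerate(terms):
                L[r, names.index(nm)] = 1.0
            wt = res.wald_test(L, scalar=False)
            chi2 = float(np.squeeze(wt.statistic))
            q = len(terms)
            F = max(chi2 / q, 0.0)
            p = float(stats.f.sf(F, q, df_den))
            return ModelResult(
                variable=variable,
                effect=effect,
                F=F,
                df_num=q,
                df_den=df_den,
                p_raw=p,
                eta_p_sq=partial_eta_squared(F, q, df_den) if F > 0 else 0.0,
                n_participants=n_participants,
            )

        q_time = len(week_levels) - 1
        results["time"] = factor_test("C(week)", "time", q_time * (n_participants - 1))
        if groups is not None:
            results["group"] = factor_test("C(group)", "group", n_participants - 2)
    return results


def evaluate_trial(
    weekly_by_variable: Mapping[str, Sequence[WeeklySeries]],
    groups: Optional[Mapping[str, str]] = None,
    cutoff: float = MISSINGNESS_CUTOFF,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Fit every outcome variable and apply BH across the within-subject family.

    Returns a tidy frame with one row per variable and effect, mirroring a
    mixed-model results table (F, dfs, raw and adjusted p, partial
    eta-squared, n).
    """
    fits: list[ModelResult] = []
    for variable, series in weekly_by_variable.items():
        try:
            res = fit_lmm_harness(series, groups=groups, cutoff=cutoff, alpha=alpha)
        except HarnessError:
            continue
        fits.extend(res.values())
    time_idx = [i for i, r in enumerate(fits) if r.effect == "time"]
    if time_idx:
        adj = bh_adjust([fits[i].p_raw for i in time_idx])
        for i, a in zip(time_idx, adj):
            fits[i] = replace(fits[i], p_adjusted=float(a))
    group_idx = [i for i, r in enumerate(fits) if r.effect == "group"]
    if group_idx:
        adj = bh_adjust([fits[i].p_raw for i in group_idx])
        for i, a in zip(group_idx, adj):
            fits[i] = replace(fits[i], p_adjusted=float(a))
    return pd.DataFrame(
        [
            {
                "variable": r.variable,
                "effect": r.effect,
                "F": r.F,
                "df_num": r.df_num,
                "df_den": r.df_den,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "eta_p_sq": r.eta_p_sq,
                "n": r.n_participants,
                "significant": (
                    r.p_adjusted is not None and r.p_adjusted < alpha
                ),
            }
            for r in fits
        ]
    )
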