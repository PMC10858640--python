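"""Study-shaped summary tables from pipeline outputs.

Four families of outputs:

* per-trial tallies of patients, patients with events, and events;
* baseline covariate comparisons between groups (Mann-Whitney U for
  continuous covariates, Pearson chi-square without continuity
  correction for categorical ones, percentages over non-missing
  denominators);
* trend-comparison tables: Week -12 / Week 0 weekly means (+/- SD) per
  group with nested-model intercept and slope contrast p-values, for
  the composite score and each component;
* component contribution summaries (share of the composite mean) and
  subgroup trend contrasts over dichotomized baseline covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import COMPONENTS
from .lmm import ModelSpec, fit_nested_lmm, wald_contrasts
from .synthetic import PatientRecord, WHFHEvent, patients_to_frame

__all__ = [
    "SubgroupSpec",
    "DEFAULT_SUBGROUPS",
    "ContributionSummary",
    "trial_tally",
    "contribution_summary",
    "subgroup_trend_report",
    "baseline_comparison",
    "trend_table",
]


@dataclass(frozen=True)
class SubgroupSpec:
    """A dichotomy of event-group patients over one baseline covariate."""

    name: str
    column: str
    #: maps the covariate value to True (second level) / False (first level)
    rule: Callable[[pd.Series], pd.Series]
    labels: tuple[str, str]


DEFAULT_SUBGROUPS: tuple[SubgroupSpec, ...] = (
    SubgroupSpec("age", "age", lambda s: s >= 75, ("<75 years", ">=75 years")),
    SubgroupSpec("sex", "male", lambda s: s.astype(bool), ("female", "male")),
    SubgroupSpec("bmi", "bmi", lambda s: s >= 30, ("<30 kg/m2", ">=30 kg/m2")),
    SubgroupSpec(
        "af_history", "af_history", lambda s: s.astype(bool), ("no", "yes")
    ),
    SubgroupSpec(
        "renal_insufficiency", "renal_insufficiency",
        lambda s: s.astype(bool), ("no", "yes"),
    ),
    SubgroupSpec(
        "aetiology", "ischaemic", lambda s: s.astype(bool),
        ("non-ischaemic", "ischaemic"),
    ),
)


@dataclass(frozen=True)
class ContributionSummary:
    """Per-component means and their shares of the composite mean."""

    means: Mapping[str, float]
    composite: float
    shares_pct: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.shares_pct:
            if self.composite <= 0:
                raise ValueError("composite mean must be positive")
            object.__setattr__(
                self,
                "shares_pct",
                {
                    name: 100.0 * v / self.composite
                    for name, v in self.means.items()
                },
            )

    @classmethod
    def from_means(cls, means: Mapping[str, float]) -> "ContributionSummary":
        return cls(means=dict(means), composite=float(sum(means.values())))

    def share(self, *components: str) -> float:
        """Cumulative share (%) of the given components."""
        return float(sum(self.shares_pct[c] for c in components))


def trial_tally(
    patients: Sequence[PatientRecord] | pd.DataFrame,
    events: Sequence[WHFHEvent] | pd.DataFrame,
) -> pd.DataFrame:
    """Per-trial patient/event counts with column percentages of totals.

    Returns one row per trial plus a ``Total`` row with columns
    ``patients``, ``patients_pct``, ``event_patients``,
    ``event_patients_pct``, ``events``, ``events_pct``.
    """
    pats = (
        patients if isinstance(patients, pd.DataFrame) else patients_to_frame(patients)
    )
    evs = (
        events
        if isinstance(events, pd.DataFrame)
        else pd.DataFrame([vars(e) for e in events])
    )
    if "trial_label" not in pats.columns:
        raise KeyError("patients need a trial_label column")
    ev_pids = set(evs["patient_id"]) if len(evs) else set()
    pats = pats.assign(has_event=pats["patient_id"].isin(ev_pids))
    trial_of = pats.set_index("patient_id")["trial_label"]
    rows = []
    for trial, sub in pats.groupby("trial_label", sort=False):
        n_ev = (
            int((trial_of.loc[evs["patient_id"]] == trial).sum()) if len(evs) else 0
        )
        rows.append(
            {
                "trial": trial,
                "patients": len(sub),
                "event_patients": int(sub["has_event"].sum()),
                "events": n_ev,
            }
        )
    out = pd.DataFrame(rows).sort_values(
        "patients", ascending=False, ignore_index=True
    )
    totals = {
        "trial": "Total",
        "patients": int(out["patients"].sum()),
        "event_patients": int(out["event_patients"].sum()),
        "events": int(out["events"].sum()),
    }
    out = pd.concat([out, pd.DataFrame([totals])], ignore_index=True)
    for col in ("patients", "event_patients", "events"):
        denom = totals[col]
        out[f"{col}_pct"] = 100.0 * out[col] / denom if denom else np.nan
    return out


def contribution_summary(
    weekly_observations: pd.DataFrame, group: str, week: int
) -> ContributionSummary:
    """Component means and composite shares at one (group, week)."""
    sel = weekly_observations[
        (weekly_observations["group"] == group)
        & (weekly_observations["week"] == week)
    ]
    if len(sel) == 0:
        raise ValueError(f"no observations for group={group!r}, week={week}")
    means = {c: float(sel[f"mean_{c}"].mean()) for c in COMPONENTS}
    return ContributionSummary.from_means(means)


def baseline_comparison(
    patients: Sequence[PatientRecord] | pd.DataFrame,
    continuous: Sequence[str] = ("age", "bmi", "lvef"),
    categorical: Sequence[str] = (
        "male", "nyha", "af_history", "renal_insufficiency", "ischaemic", "device",
    ),
) -> pd.DataFrame:
    """Between-group baseline table.

    Continuous covariates: median (IQR) per group, Mann-Whitney U with
    tie-corrected normal approximation (no continuity correction).
    Categorical covariates: n (%) of non-missing per group, Pearson
    chi-square without continuity correction.
    """
    pats = (
        patients if isinstance(patients, pd.DataFrame) else patients_to_frame(patients)
    )
    is_event = pats["group"] == "event"
    rows = []
    for col in continuous:
        a = pats.loc[is_event, col].dropna()
        b = pats.loc[~is_event, col].dropna()
        if a.empty and b.empty:
            raise ValueError(f"covariate {col!r} entirely missing")
        u, p = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic",
            use_continuity=False,
        )
        rows.append(
            {
                "covariate": col,
                "type": "continuous",
                "event": _median_iqr(a),
                "control": _median_iqr(b),
                "statistic": float(u),
                "test": "mann-whitney",
                "p": float(p),
            }
        )
    for col in categorical:
        sub = pats[[col, "group"]].dropna()
        if sub.empty:
            raise ValueError(f"covariate {col!r} entirely missing")
        table = pd.crosstab(sub[col], sub["group"])
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        ev = sub[sub["group"] == "event"][col]
        ct = sub[sub["group"] != "event"][col]
        rows.append(
            {
                "covariate": col,
                "type": "categorical",
                "event": _counts_pct(ev),
                "control": _counts_pct(ct),
                "statistic": float(chi2),
                "test": "chi-square",
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def _median_iqr(x: pd.Series) -> str:
    if x.empty:
        return "-"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}-{q3:.1f})"


def _counts_pct(x: pd.Series) -> str:
    n = len(x)
    if n == 0:
        return "-"
    parts = [
        f"{level}: {count} ({100.0 * count / n:.1f}%)"
        for level, count in x.value_counts().sort_index().items()
    ]
    return "; ".join(parts)


def trend_table(
    weekly_observations: pd.DataFrame,
    responses: Sequence[str] = ("score", *COMPONENTS),
    reml: bool = True,
    n_starts: int = 3,
) -> pd.DataFrame:
    """Weekly-trend comparison table for the composite and components.

    One row per response with Week -12 / Week 0 observed means +/- SD in
    each group and the nested-model intercept- and slope-contrast
    p-values.
    """
    rows = []
    for response in responses:
        col = "mean_score" if response == "score" else f"mean_{response}"
        fit = fit_nested_lmm(
            weekly_observations, ModelSpec(response=response, reml=reml, n_starts=n_starts)
        )
        con = wald_contrasts(fit)
        row: dict = {"response": response}
        for group in ("event", "control"):
            for week in (-12, 0):
                sel = weekly_observations[
                    (weekly_observations["group"] == group)
                    & (weekly_observations["week"] == week)
                ][col]
                row[f"{group}_week{week}_mean"] = float(sel.mean())
                row[f"{group}_week{week}_sd"] = float(sel.std())
        row["intercept_diff"] = con.intercept_diff
        row["intercept_p"] = con.intercept_p
        row["slope_diff"] = con.slope_diff
        row["slope_p"] = con.slope_p
        rows.append(row)
    return pd.DataFrame(rows)


def subgroup_trend_report(
    weekly_observations: pd.DataFrame,
    patients: Sequence[PatientRecord] | pd.DataFrame,
    specs: Sequence[SubgroupSpec] = DEFAULT_SUBGROUPS,
    response: str = "score",
    reml: bool = True,
    n_starts: int = 3,
    strict: bool = True,
) -> pd.DataFrame:
    """Trend contrasts between baseline subgroups of event patients.

    For each dichotomy the nested model is refit on event-group
    observations with the subgroup level as the grouping factor; one row
    per spec reports the Week -12 and slope contrasts (second level
    minus first).  A level with fewer than 2 patients is an error, or is
    skipped when ``strict`` is false.
    """
    pats = (
        patients if isinstance(patients, pd.DataFrame) else patients_to_frame(patients)
    )
    obs = weekly_observations[weekly_observations["group"] == "event"]
    rows = []
    for spec in specs:
        values = pats.set_index("patient_id")[spec.column]
        level = spec.rule(values)
        labels = level.map({False: spec.labels[0], True: spec.labels[1]})
        sub = obs.assign(subgroup=obs["patient_id"].map(labels))
        sub = sub.dropna(subset=["subgroup"])
        sparse = [
            lab
            for lab in spec.labels
            if sub.loc[sub["subgroup"] == lab, "patient_id"].nunique() < 2
        ]
        if sparse:
            if strict:
                raise ValueError(
                    f"subgroup {spec.name!r} level {sparse[0]!r} has fewer "
                    "than 2 patients"
                )
            continue
        fit = fit_nested_lmm(
            sub,
            ModelSpec(
                response=response, reml=reml, n_starts=n_starts,
                group_col="subgroup", reference=spec.labels[0],
            ),
        )
        con = wald_contrasts(fit)
        rows.append(
            {
                "subgroup": spec.name,
                "level0": spec.labels[0],
                "level1": spec.labels[1],
                "n_level0": sub.loc[sub["subgroup"] == spec.labels[0], "patient_id"].nunique(),
                "n_level1": sub.loc[sub["subgroup"] == spec.labels[1], "patient_id"].nunique(),
                "intercept_diff": con.intercept_diff,
                "intercept_p": con.intercept_p,
                "slope_diff": con.slope_diff,
                "slope_p": con.slope_p,
            }
        )
    return pd.DataFrame(rows)
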