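"""Cohort eligibility cascade, anchor selection, and weekly windowing.

The analysis compares 12-week trends of the daily composite score before
an anchor day: the hospital admission for patients with a worsening-HF
hospitalization (WHFH), or the last transmission for patients without
one.  Day offsets ``d = anchor_day - day`` with ``d in [0, 90]`` map to
weeks ``-floor(d/7)``: Week 0 covers offsets 0-6 and Week -12 offsets
84-90, partitioning the 91 in-window offsets into 13 bins of 7 days.

Gates applied before a window is admitted:

* events must occur at least 30 days post implant (after the run-in);
* the trailing-90-day transmission rate at the anchor must be >= 55%;
* repeat admissions less than 90 days apart truncate the second window
  to the inter-event interval, and a first admission within 90 days of
  the run-in truncates to the available interval;
* control anchors require at least 90 days of post-run-in follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import COMPONENTS, EngineConfig, transmission_rate
from .synthetic import PatientRecord, WHFHEvent, patients_to_frame

__all__ = [
    "Anchor",
    "ExclusionTally",
    "CASCADE_STAGES",
    "apply_eligibility_cascade",
    "select_anchors",
    "extract_weekly_series",
    "build_weekly_observations",
    "transmission_flags",
]

#: Ordered cascade stages: name -> (required column, predicate for *exclusion*).
CASCADE_STAGES: tuple[tuple[str, str], ...] = (
    ("unsuitable_device_or_hm", "device"),
    ("longstanding_af", "af"),
    ("lvef_gt_35", "lvef"),
    ("nyha_not_ii_iii", "nyha"),
    ("insufficient_hm_data", "hm_data"),
    ("short_follow_up", "follow_up"),
)


@dataclass(frozen=True)
class Anchor:
    """End day of one 13-week analysis window."""

    anchor_id: str
    patient_id: str
    anchor_day: int
    kind: str  # "event" | "last_transmission"
    window_start_day: int
    truncated: bool
    group: str  # "event" | "control"
    event_id: str | None = None

    def __post_init__(self) -> None:
        if self.anchor_day - self.window_start_day > 90:
            raise ValueError("anchor window spans more than 91 days")
        if self.window_start_day > self.anchor_day:
            raise ValueError("window_start_day exceeds anchor_day")


@dataclass
class ExclusionTally:
    """Ordered per-stage exclusion counts plus the final eligible count."""

    stages: dict[str, int] = field(default_factory=dict)
    eligible: int = 0

    @property
    def total(self) -> int:
        return sum(self.stages.values()) + self.eligible

    def to_frame(self) -> pd.DataFrame:
        rows = [{"stage": k, "excluded": v} for k, v in self.stages.items()]
        rows.append({"stage": "eligible", "excluded": self.eligible})
        return pd.DataFrame(rows)


def _stage_masks(records: pd.DataFrame) -> dict[str, pd.Series]:
    required = {
        "unsuitable_device_or_hm": ("device_ok", "hm_enabled"),
        "longstanding_af": ("longstanding_af",),
        "lvef_gt_35": ("lvef",),
        "nyha_not_ii_iii": ("nyha",),
        "insufficient_hm_data": ("sufficient_hm_data",),
        "short_follow_up": ("followup_post_runin_days", "has_whfh"),
    }
    for stage, cols in required.items():
        for col in cols:
            if col not in records.columns:
                raise KeyError(
                    f"eligibility stage {stage!r} requires column {col!r}"
                )
    return {
        "unsuitable_device_or_hm": ~(
            records["device_ok"].astype(bool) & records["hm_enabled"].astype(bool)
        ),
        "longstanding_af": records["longstanding_af"].astype(bool),
        "lvef_gt_35": records["lvef"] > 35,
        "nyha_not_ii_iii": ~records["nyha"].isin([2, 3]),
        "insufficient_hm_data": ~records["sufficient_hm_data"].astype(bool),
        "short_follow_up": (records["followup_post_runin_days"] < 90)
        & ~records["has_whfh"].astype(bool),
    }


def apply_eligibility_cascade(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, ExclusionTally]:
    """Apply the ordered eligibility stages, attributing each exclusion
    to the first failing stage.

    ``records`` must carry the attribute columns each stage tests (see
    :func:`hfscore.synthetic.make_filter_fixture`).  Returns the eligible
    records and the per-stage tally; the tally partitions the input
    (total = sum of stage counts + eligible).
    """
    tally = ExclusionTally()
    if len(records) == 0:
        tally.stages = {name: 0 for name, _ in CASCADE_STAGES}
        return records.copy(), tally
    masks = _stage_masks(records)
    remaining = pd.Series(True, index=records.index)
    for stage, _ in CASCADE_STAGES:
        hit = masks[stage] & remaining
        tally.stages[stage] = int(hit.sum())
        remaining &= ~hit
    eligible = records[remaining].copy()
    tally.eligible = len(eligible)
    return eligible, tally


def transmission_flags(
    patients: Sequence[PatientRecord], observed: pd.DataFrame
) -> dict[str, pd.Series]:
    """Per-patient daily transmission flags over the full follow-up grid.

    ``observed`` is any frame with ``patient_id`` and ``day`` columns; a
    day counts as transmitted if it appears there (with ``transmitted``
    honored when present).
    """
    if "transmitted" in observed.columns:
        observed = observed[observed["transmitted"].astype(bool)]
    days_by_pid = observed.groupby("patient_id")["day"].apply(set)
    flags: dict[str, pd.Series] = {}
    for pat in patients:
        grid = np.arange(pat.implant_day, pat.follow_up_end + 1)
        seen = days_by_pid.get(pat.patient_id, set())
        flags[pat.patient_id] = pd.Series(
            np.isin(grid, sorted(seen)) if seen else False, index=grid
        )
    return flags


def select_anchors(
    patients: Sequence[PatientRecord],
    events: Sequence[WHFHEvent],
    observed: pd.DataFrame,
    config: EngineConfig | None = None,
) -> list[Anchor]:
    """Select analysis anchors with run-in, transmission and repeat rules.

    Event anchors are admission days at least ``run_in_days`` post
    implant whose trailing transmission rate passes the gate; windows
    are truncated at the run-in boundary and at the previous admission.
    Patients without any qualifying event anchor receive a control
    anchor at their last transmitted day, provided at least 90 days of
    post-run-in follow-up and the same transmission gate.
    """
    cfg = config or EngineConfig()
    flags = transmission_flags(patients, observed)
    ev_by_patient: dict[str, list[WHFHEvent]] = {}
    for ev in events:
        ev_by_patient.setdefault(ev.patient_id, []).append(ev)

    anchors: list[Anchor] = []
    for pat in patients:
        pid = pat.patient_id
        run_in_end = pat.implant_day + cfg.run_in_days
        p_flags = flags[pid]
        p_events = sorted(
            ev_by_patient.get(pid, []), key=lambda e: e.admission_day
        )
        accepted: list[Anchor] = []
        prev_admission: int | None = None
        for ev in p_events:
            day = ev.admission_day
            if not pat.implant_day <= day <= pat.follow_up_end:
                raise ValueError(
                    f"event {ev.event_id} outside follow-up of {pid}"
                )
            if not ev.adjudicated:
                continue
            if day - pat.implant_day < cfg.run_in_days:
                continue
            rate = transmission_rate(p_flags, day, cfg.transmission_horizon_days)
            if rate < cfg.min_transmission_rate:
                prev_admission = day  # still bounds the next window
                continue
            lo_candidates = [day - 90, run_in_end]
            if prev_admission is not None:
                lo_candidates.append(prev_admission + 1)
            start = max(lo_candidates)
            accepted.append(
                Anchor(
                    anchor_id=ev.event_id,
                    patient_id=pid,
                    anchor_day=day,
                    kind="event",
                    window_start_day=start,
                    truncated=start > day - 90,
                    group="event",
                    event_id=ev.event_id,
                )
            )
            prev_admission = day
        if accepted:
            anchors.extend(accepted)
            continue
        # control anchor at the last transmitted day
        transmitted_days = p_flags[p_flags].index
        if len(transmitted_days) == 0:
            continue
        last = int(transmitted_days.max())
        if last - run_in_end < 90:
            continue
        rate = transmission_rate(p_flags, last, cfg.transmission_horizon_days)
        if rate < cfg.min_transmission_rate:
            continue
        anchors.append(
            Anchor(
                anchor_id=f"{pid}-LT",
                patient_id=pid,
                anchor_day=last,
                kind="last_transmission",
                window_start_day=max(last - 90, run_in_end),
                truncated=max(last - 90, run_in_end) > last - 90,
                # no qualifying admission: analysed with the no-event group
                group="control",
            )
        )
    return anchors


def extract_weekly_series(
    anchor: Anchor, daily_scores: pd.DataFrame
) -> pd.DataFrame:
    """Aggregate one anchor's daily scores into weekly observations.

    Day offsets ``d = anchor_day - day`` within the anchor window map to
    week ``-floor(d/7)``; each present week is the mean of its observed
    days.  Weeks with no observed day are omitted.  Raises if no day of
    the window was observed.

    ``daily_scores`` needs ``patient_id``, ``day``, ``score`` and the
    component columns; rows with ``valid == False`` are ignored.
    """
    return _weekly_from_patient_rows(
        anchor, daily_scores[daily_scores["patient_id"] == anchor.patient_id]
    )


def _weekly_from_patient_rows(anchor: Anchor, rows: pd.DataFrame) -> pd.DataFrame:
    if "valid" in rows.columns:
        rows = rows[rows["valid"].astype(bool)]
    rows = rows[
        (rows["day"] >= anchor.window_start_day)
        & (rows["day"] <= anchor.anchor_day)
    ]
    if len(rows) == 0:
        raise ValueError(f"anchor {anchor.anchor_id} has no observed day")
    offsets = anchor.anchor_day - rows["day"].to_numpy()
    weeks = -(offsets // 7)
    agg = rows.assign(week=weeks).groupby("week")
    comp_cols = [c for c in COMPONENTS if c in rows.columns]
    out = agg[["score", *comp_cols]].mean()
    out["n_days_observed"] = agg.size()
    out = out.reset_index().rename(
        columns={"score": "mean_score", **{c: f"mean_{c}" for c in comp_cols}}
    )
    out.insert(0, "patient_id", anchor.patient_id)
    out.insert(1, "anchor_id", anchor.anchor_id)
    out.insert(2, "group", anchor.group)
    return out


def build_weekly_observations(
    anchors: Sequence[Anchor], daily_scores: pd.DataFrame
) -> pd.DataFrame:
    """Weekly observations for every anchor, one row per (anchor, week)."""
    by_pid = {pid: sub for pid, sub in daily_scores.groupby("patient_id")}
    empty = daily_scores.iloc[0:0]
    frames = []
    for anchor in anchors:
        try:
            frames.append(
                _weekly_from_patient_rows(
                    anchor, by_pid.get(anchor.patient_id, empty)
                )
            )
        except ValueError:
            continue  # anchors without any observed day contribute nothing
    if not frames:
        return pd.DataFrame(
            columns=[
                "patient_id", "anchor_id", "group", "week", "mean_score",
                *[f"mean_{c}" for c in COMPONENTS], "n_days_observed",
            ]
        )
    return pd.concat(frames, ignore_index=True)
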