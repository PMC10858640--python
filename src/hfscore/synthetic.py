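"""Seeded synthetic cohorts, telemetry, and daily component scores.

Real device telemetry from pooled defibrillator trials is not publicly
distributable, so every downstream stage of the package is exercised on
synthetic cohorts with the statistical structure the analysis assumes:

* two groups of patients — with and without a worsening-heart-failure
  hospitalization (WHFH) — with group-specific covariate prevalences;
* daily component scores whose expected values follow linear 12-week
  trajectories ending at the group's anchor (hospital admission for the
  event group, last transmission for controls), on top of nested
  patient-level and anchor-level random intercepts and daily residual
  noise, floored at zero;
* raw telemetry channels in physiologic units with a pre-event drift
  (rising heart rate, falling heart-rate variability, impedance and
  activity, rising AHRE burden and PVC rate) and per-day transmission
  gaps.

Component values are non-negative by construction.  Because a plain
zero-floor would inflate small means with large spreads, the generator
solves for the pre-floor Gaussian location whose floored expectation
equals the requested mean, so configured trajectory means are recovered
exactly in expectation at any noise level.

All draws are split from one integer seed per patient, so any subset of
patients is reproducible independently of cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .engine import COMPONENTS

__all__ = [
    "CohortConfig",
    "TrajectorySpec",
    "TelemetrySpec",
    "PatientRecord",
    "WHFHEvent",
    "make_cohort",
    "simulate_component_scores",
    "simulate_telemetry",
    "make_filter_fixture",
    "make_trial_fixture",
    "TRIAL_PROFILES",
]

# ---------------------------------------------------------------------------
# Default study conditions

#: Component weekly means (score points) at the start (Week -12) and end
#: (Week 0) of the 12-week pre-anchor window, per group.  These are the
#: trajectory endpoints of the pooled-cohort analysis the simulator
#: emulates; the event-group sums are 42.3 (Week -12) and 51.6 (Week 0).
DEFAULT_EVENT_START: Mapping[str, float] = {
    "hr24": 13.7, "hrv": 9.3, "night_hr": 7.1, "ti": 7.1,
    "activity": 2.0, "ahre": 1.8, "pvc": 1.3,
}
DEFAULT_EVENT_END: Mapping[str, float] = {
    "hr24": 15.2, "hrv": 11.5, "night_hr": 8.4, "ti": 8.7,
    "activity": 2.5, "ahre": 3.0, "pvc": 2.3,
}
DEFAULT_CONTROL_START: Mapping[str, float] = {
    "hr24": 12.1, "hrv": 4.5, "night_hr": 6.4, "ti": 4.6,
    "activity": 1.9, "ahre": 0.9, "pvc": 0.4,
}
DEFAULT_CONTROL_END: Mapping[str, float] = {
    "hr24": 11.6, "hrv": 3.8, "night_hr": 6.6, "ti": 4.7,
    "activity": 1.6, "ahre": 1.0, "pvc": 0.3,
}
#: Cross-sectional standard deviation of weekly component values
#: (event group, Week -12), decomposed below into patient, anchor and
#: residual variance shares.
DEFAULT_WEEKLY_SD: Mapping[str, float] = {
    "hr24": 6.1, "hrv": 16.0, "night_hr": 5.4, "ti": 6.7,
    "activity": 5.5, "ahre": 4.9, "pvc": 8.0,
}

#: Binary covariate prevalences per group (event, control), matching the
#: baseline table of the pooled cohort.
DEFAULT_PREVALENCES: Mapping[str, tuple[float, float]] = {
    "male": (0.792, 0.764),
    "nyha_iii": (0.637, 0.538),
    "crtd": (0.707, 0.765),
    "ischaemic": (0.544, 0.482),
    "af_history": (0.454, 0.193),
    "renal_insufficiency": (0.335, 0.183),
}


@dataclass(frozen=True)
class CohortConfig:
    """Sizes, event allocation, follow-up and covariate structure."""

    n_event_patients: int
    n_control_patients: int
    #: probabilities of 1, 2 or 3 hospitalizations per event patient
    events_per_patient_probs: tuple[float, float, float] = (0.7, 0.2, 0.1)
    #: if set, event counts are adjusted so the cohort total is exact
    total_events: int | None = None
    follow_up_days: tuple[int, int] = (300, 1000)
    transmission_probability: float = 0.9
    #: earliest admission day (implant at day 0); the default leaves room
    #: for the 30-day run-in plus a full 91-day window
    min_event_day: int = 121
    min_event_gap_days: int = 45
    covariate_prevalences: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_event_patients < 0 or self.n_control_patients < 0:
            raise ValueError("patient counts must be non-negative")
        probs = np.asarray(self.events_per_patient_probs, dtype=float)
        if np.any(probs < 0) or np.any(probs > 1) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("events_per_patient_probs must be a distribution")
        if not 0.0 <= self.transmission_probability <= 1.0:
            raise ValueError("transmission_probability must lie in [0, 1]")
        for name, (pe, pc) in self.covariate_prevalences.items():
            if not (0 <= pe <= 1 and 0 <= pc <= 1):
                raise ValueError(f"prevalence for {name!r} outside [0, 1]")
        lo, hi = self.follow_up_days
        if lo <= 0 or hi < lo:
            raise ValueError("follow_up_days must be a positive range")


def _shares_to_sds(
    weekly_sd: Mapping[str, float],
    patient_share: float,
    anchor_share: float,
    days_per_week: int = 7,
) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """Split a weekly cross-sectional SD into patient/anchor/daily-residual SDs.

    The weekly variance of a weekly mean is
    ``sd_p**2 + sd_a**2 + sd_e**2 / days_per_week``; the shares allocate
    the total across the three terms.
    """
    resid_share = 1.0 - patient_share - anchor_share
    if min(patient_share, anchor_share, resid_share) < 0:
        raise ValueError("variance shares must be non-negative and sum to <= 1")
    sd_p, sd_a, sd_e = {}, {}, {}
    for name, sd in weekly_sd.items():
        var = float(sd) ** 2
        sd_p[name] = np.sqrt(patient_share * var)
        sd_a[name] = np.sqrt(anchor_share * var)
        sd_e[name] = np.sqrt(resid_share * var * days_per_week)
    return sd_p, sd_a, sd_e


@dataclass(frozen=True)
class TrajectorySpec:
    """Per-component trajectory endpoints and noise SDs (score points).

    ``*_start`` are Week -12 weekly means, ``*_end`` Week 0 means.  The
    expected daily value interpolates linearly between them over the 84
    days separating the two week midpoints (``shape == 'linear'``); a
    ``'plateau'`` component stays flat at its start mean until the final
    28 days and then ramps to the end mean.
    """

    event_start: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_EVENT_START))
    event_end: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_EVENT_END))
    control_start: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CONTROL_START))
    control_end: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CONTROL_END))
    patient_sd: Mapping[str, float] = field(default_factory=dict)
    anchor_sd: Mapping[str, float] = field(default_factory=dict)
    residual_sd: Mapping[str, float] = field(default_factory=dict)
    shape: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.patient_sd:
            sd_p, sd_a, sd_e = _shares_to_sds(DEFAULT_WEEKLY_SD, 0.5, 0.2)
            object.__setattr__(self, "patient_sd", sd_p)
            object.__setattr__(self, "anchor_sd", sd_a)
            object.__setattr__(self, "residual_sd", sd_e)
        for mapping in (self.event_start, self.event_end,
                        self.control_start, self.control_end):
            if any(v < 0 for v in mapping.values()):
                raise ValueError("trajectory means must be non-negative")
        for mapping in (self.patient_sd, self.anchor_sd, self.residual_sd):
            if any(v < 0 for v in mapping.values()):
                raise ValueError("noise SDs must be non-negative")
        for name, s in self.shape.items():
            if s not in ("linear", "plateau"):
                raise ValueError(f"unknown shape {s!r} for component {name!r}")

    @classmethod
    def noise_free(cls) -> "TrajectorySpec":
        zeros = {c: 0.0 for c in COMPONENTS}
        return cls(patient_sd=zeros, anchor_sd=dict(zeros), residual_sd=dict(zeros))


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    group: str  # "event" | "control"
    implant_day: int
    follow_up_end: int
    age: float
    male: bool
    bmi: float
    nyha: int
    lvef: float
    af_history: bool
    renal_insufficiency: bool
    ischaemic: bool
    device: str  # "CRT-D" | "ICD"
    trial_label: str = "SYNTH"

    def __post_init__(self) -> None:
        if self.follow_up_end <= self.implant_day:
            raise ValueError("follow_up_end must exceed implant_day")


@dataclass(frozen=True)
class WHFHEvent:
    event_id: str
    patient_id: str
    admission_day: int
    adjudicated: bool = True


def _patient_rng(seed: int, patient_index: int, stream: int) -> np.random.Generator:
    """Deterministic per-patient generator, independent of cohort size."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(patient_index, stream))
    )


def patients_to_frame(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in patients])


def events_to_frame(events: Sequence[WHFHEvent]) -> pd.DataFrame:
    if not events:
        return pd.DataFrame(
            columns=["event_id", "patient_id", "admission_day", "adjudicated"]
        )
    return pd.DataFrame([vars(e) for e in events])


def _allocate_event_counts(
    rng: np.random.Generator, n_patients: int, probs: tuple[float, float, float],
    total: int | None,
) -> np.ndarray:
    counts = rng.choice([1, 2, 3], size=n_patients, p=list(probs))
    if total is None or n_patients == 0:
        return counts
    if not n_patients <= total <= 3 * n_patients:
        raise ValueError(
            f"total_events={total} infeasible for {n_patients} event patients"
        )
    # nudge individual counts (deterministically via rng) until exact
    while counts.sum() > total:
        idx = rng.choice(np.flatnonzero(counts > 1))
        counts[idx] -= 1
    while counts.sum() < total:
        idx = rng.choice(np.flatnonzero(counts < 3))
        counts[idx] += 1
    return counts


def make_cohort(
    config: CohortConfig,
) -> tuple[list[PatientRecord], list[WHFHEvent]]:
    """Generate patients and adjudicated hospitalization events.

    Event patients receive 1-3 admissions each (exact cohort total when
    ``config.total_events`` is set), placed at least
    ``config.min_event_day`` days post implant; consecutive admissions
    are at least ``config.min_event_gap_days`` apart, so inter-event
    gaps shorter than the 91-day analysis window occur and exercise the
    truncation rules downstream.
    """
    n_total = config.n_event_patients + config.n_control_patients
    alloc_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(0xA110C,))
    )
    event_counts = _allocate_event_counts(
        alloc_rng, config.n_event_patients,
        config.events_per_patient_probs, config.total_events,
    )

    patients: list[PatientRecord] = []
    events: list[WHFHEvent] = []
    fu_lo, fu_hi = config.follow_up_days
    for i in range(n_total):
        is_event = i < config.n_event_patients
        group = "event" if is_event else "control"
        rng = _patient_rng(config.seed, i, 0)
        follow_up = int(rng.integers(fu_lo, fu_hi + 1))
        if is_event:
            k = int(event_counts[i])
            # keep room for k admissions with minimum spacing
            needed = config.min_event_day + (k - 1) * config.min_event_gap_days + 1
            follow_up = max(follow_up, needed)
        prev = {
            name: (pe if is_event else pc)
            for name, (pe, pc) in config.covariate_prevalences.items()
        }
        pid = f"P{i + 1:05d}"
        patients.append(
            PatientRecord(
                patient_id=pid,
                group=group,
                implant_day=0,
                follow_up_end=follow_up,
                age=float(round(np.clip(rng.normal(67.0, 11.0), 20.0, 95.0))),
                male=bool(rng.random() < prev.get("male", 0.77)),
                bmi=float(
                    round(np.clip(rng.lognormal(np.log(26.9), 0.18), 15.0, 55.0), 1)
                ),
                nyha=3 if rng.random() < prev.get("nyha_iii", 0.55) else 2,
                lvef=float(rng.integers(20, 36)),
                af_history=bool(rng.random() < prev.get("af_history", 0.21)),
                renal_insufficiency=bool(
                    rng.random() < prev.get("renal_insufficiency", 0.20)
                ),
                ischaemic=bool(rng.random() < prev.get("ischaemic", 0.49)),
                device="CRT-D" if rng.random() < prev.get("crtd", 0.758) else "ICD",
                trial_label="SYNTH",
            )
        )
        if is_event:
            k = int(event_counts[i])
            days = _draw_admission_days(rng, k, config, follow_up)
            for j, day in enumerate(days):
                events.append(
                    WHFHEvent(
                        event_id=f"{pid}-E{j + 1}",
                        patient_id=pid,
                        admission_day=int(day),
                    )
                )
    return patients, events


def _draw_admission_days(
    rng: np.random.Generator, k: int, config: CohortConfig, follow_up: int
) -> np.ndarray:
    lo, gap = config.min_event_day, config.min_event_gap_days
    hi = follow_up - 1
    for _ in range(50):
        days = np.sort(rng.integers(lo, hi + 1, size=k))
        if k == 1 or np.all(np.diff(days) >= gap):
            return days
    return np.linspace(lo, hi, k).astype(int)  # fallback: even spacing


# ---------------------------------------------------------------------------
# Component-score simulation


def _floored_normal_location(
    target_mean: np.ndarray, sd: float, tol: float = 1e-10
) -> np.ndarray:
    """Location ``mu`` with ``E[max(N(mu, sd^2), 0)] == target_mean``.

    ``g(mu) = mu * Phi(mu/sd) + sd * phi(mu/sd)`` is increasing and
    convex, so Newton iteration converges from any start.
    """
    m = np.asarray(target_mean, dtype=float)
    if sd <= 0:
        return m.copy()
    mu = m.copy()
    for _ in range(100):
        z = mu / sd
        phi = np.exp(-0.5 * z * z) / np.sqrt(2 * np.pi)
        g = mu * ndtr(z) + sd * phi
        step = (g - m) / np.maximum(ndtr(z), 1e-12)
        mu -= step
        if np.max(np.abs(g - m)) < tol:
            break
    return mu


def _mean_profile(
    offsets: np.ndarray, start: float, end: float, shape: str
) -> np.ndarray:
    """Expected weekly-mean trajectory evaluated at day offsets before the anchor.

    Offsets are ``anchor_day - day``.  The profile is anchored at the
    week midpoints: offset 87 (Week -12) maps to ``start`` and offset 3
    (Week 0) to ``end``, so weekly means over 7-day bins reproduce a
    trajectory linear in the week index with the configured endpoints.
    Offsets beyond the window hold the start value.
    """
    d = np.asarray(offsets, dtype=float)
    if shape == "plateau":
        # flat at start, ramping to the end mean over the final 4 weeks
        frac = np.clip((31.0 - d) / 28.0, 0.0, 1.0)
        frac = np.where(d > 90, 0.0, frac)
    else:
        # linear through the whole window (no clip at the Week -12
        # midpoint, so the Week -12 bin mean equals `start` exactly)
        frac = np.where(d > 90, 0.0, (87.0 - d) / 84.0)
    return start + (end - start) * frac


def simulate_component_scores(
    patients: Sequence[PatientRecord],
    events: Sequence[WHFHEvent],
    trajectory: TrajectorySpec | None = None,
    seed: int = 0,
    transmission_probability: float = 1.0,
) -> pd.DataFrame:
    """Simulate daily component scores (and their composite) per patient.

    For event patients, each day is attributed to the next upcoming
    admission; expected component values follow the event-group profile
    toward that admission and hold the Week -12 baseline outside any
    91-day window.  Controls follow the control-group profile toward
    their last follow-up day.  Patient- and anchor-level random
    intercepts and daily residual noise are added, and values are
    floored at zero with a mean-preserving location adjustment.

    Returns a frame with one row per *transmitted* patient-day:
    ``patient_id``, ``day``, the seven component columns, ``score``.
    """
    traj = trajectory or TrajectorySpec()
    if not 0.0 <= transmission_probability <= 1.0:
        raise ValueError("transmission_probability must lie in [0, 1]")
    ev_by_patient: dict[str, list[WHFHEvent]] = {}
    for ev in events:
        ev_by_patient.setdefault(ev.patient_id, []).append(ev)

    frames: list[pd.DataFrame] = []
    for idx, pat in enumerate(patients):
        rng = _patient_rng(seed, idx, 1)
        days = np.arange(pat.implant_day, pat.follow_up_end + 1)
        transmitted = rng.random(days.size) < transmission_probability
        obs_days = days[transmitted]
        if obs_days.size == 0:
            continue
        if pat.group == "event":
            p_events = sorted(
                ev_by_patient.get(pat.patient_id, []), key=lambda e: e.admission_day
            )
            anchors = np.array([e.admission_day for e in p_events], dtype=int)
            start_means, end_means = traj.event_start, traj.event_end
        else:
            anchors = np.array([pat.follow_up_end], dtype=int)
            start_means, end_means = traj.control_start, traj.control_end
        if anchors.size == 0:
            anchors = np.array([pat.follow_up_end], dtype=int)
            start_means, end_means = traj.control_start, traj.control_end

        # map each day to the next upcoming anchor (last anchor afterwards)
        anchor_idx = np.searchsorted(anchors, obs_days, side="left")
        trailing = anchor_idx >= anchors.size
        anchor_idx = np.minimum(anchor_idx, anchors.size - 1)
        offsets = anchors[anchor_idx] - obs_days
        offsets = np.where(trailing, 10_000, offsets)  # past last anchor: baseline

        comp_values: dict[str, np.ndarray] = {}
        for comp in COMPONENTS:
            shape = traj.shape.get(comp, "linear")
            mean = _mean_profile(
                offsets, start_means[comp], end_means[comp], shape
            )
            sd_p = traj.patient_sd.get(comp, 0.0)
            sd_a = traj.anchor_sd.get(comp, 0.0)
            sd_e = traj.residual_sd.get(comp, 0.0)
            s_tot = float(np.hypot(np.hypot(sd_p, sd_a), sd_e))
            mu = _floored_normal_location(mean, s_tot)
            u_p = rng.normal(0.0, sd_p) if sd_p > 0 else 0.0
            v_a = (
                rng.normal(0.0, sd_a, size=anchors.size)
                if sd_a > 0
                else np.zeros(anchors.size)
            )
            eps = (
                rng.normal(0.0, sd_e, size=obs_days.size)
                if sd_e > 0
                else np.zeros(obs_days.size)
            )
            anchor_term = np.where(trailing, 0.0, v_a[anchor_idx])
            comp_values[comp] = np.maximum(mu + u_p + anchor_term + eps, 0.0)

        frame = pd.DataFrame({"patient_id": pat.patient_id, "day": obs_days})
        for comp in COMPONENTS:
            frame[comp] = comp_values[comp]
        frame["score"] = sum(comp_values[comp] for comp in COMPONENTS)
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=["patient_id", "day", *COMPONENTS, "score"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Raw telemetry simulation


@dataclass(frozen=True)
class TelemetrySpec:
    """Baselines, daily noise SDs and pre-event drift rates per channel.

    Units are physiologic: bpm (heart rates), ms (HRV), ohm (impedance),
    % of day (activity, AHRE burden), events/h (PVC).  Drifts are per
    day and act over the ``drift_lead_days`` before an admission; they
    are calibrated so that, with the default engine weights, the mean
    trailing-window component values of event patients approximate the
    event-group Week -12 trajectory means.
    """

    drift_lead_days: int = 182
    hr24_baseline: float = 70.0
    hr24_sd: float = 1.5
    hr24_drift: float = 0.10615
    hrv_baseline: float = 95.0
    hrv_sd: float = 8.0
    hrv_drift: float = -0.27814
    ti_baseline: float = 72.0
    ti_sd: float = 1.2
    ti_drift: float = -0.04280
    activity_baseline: float = 12.0
    activity_sd: float = 2.0
    activity_drift: float = -0.02575
    pvc_baseline: float = 5.0
    pvc_sd: float = 3.0
    pvc_drift: float = 0.02469
    night_hr_baseline: float = 62.0
    night_hr_sd: float = 3.4
    night_hr_sd_at_event: float = 4.7
    ahre_level_control: float = 4.5
    ahre_level_start: float = 6.0
    ahre_level_at_event: float = 15.0


def simulate_telemetry(
    patients: Sequence[PatientRecord],
    events: Sequence[WHFHEvent],
    config: CohortConfig,
    seed: int = 0,
    spec: TelemetrySpec | None = None,
) -> pd.DataFrame:
    """Simulate raw daily telemetry with pre-event drift and gaps.

    Returns one row per patient-day with columns ``patient_id``,
    ``day``, ``hr24``, ``night_hr``, ``hrv``, ``ahre_pct``,
    ``pvc_per_h``, ``activity``, ``impedance``, ``transmitted``.
    Non-transmitted days keep their row (for transmission-rate
    accounting) but carry no measurements; HRV is additionally absent on
    days whose AHRE burden exceeds 20% of the day.
    """
    tspec = spec or TelemetrySpec()
    ev_by_patient: dict[str, list[int]] = {}
    for ev in events:
        ev_by_patient.setdefault(ev.patient_id, []).append(ev.admission_day)

    frames: list[pd.DataFrame] = []
    for idx, pat in enumerate(patients):
        rng = _patient_rng(config.seed if seed is None else seed, idx, 2)
        days = np.arange(pat.implant_day, pat.follow_up_end + 1)
        n = days.size
        transmitted = rng.random(n) < config.transmission_probability

        anchors = np.sort(np.array(ev_by_patient.get(pat.patient_id, []), dtype=int))
        if anchors.size:
            a_idx = np.searchsorted(anchors, days, side="left")
            trailing = a_idx >= anchors.size
            a_idx = np.minimum(a_idx, anchors.size - 1)
            offset = anchors[a_idx] - days
            offset = np.where(trailing, tspec.drift_lead_days + 1, offset)
        else:
            offset = np.full(n, tspec.drift_lead_days + 1)
        # drift progress in days since the lead window opened (0 outside it)
        progress = np.clip(tspec.drift_lead_days - offset, 0, None).astype(float)

        hr24 = tspec.hr24_baseline + tspec.hr24_drift * progress + rng.normal(
            0, tspec.hr24_sd, n
        )
        hrv = tspec.hrv_baseline + tspec.hrv_drift * progress + rng.normal(
            0, tspec.hrv_sd, n
        )
        ti = tspec.ti_baseline + tspec.ti_drift * progress + rng.normal(
            0, tspec.ti_sd, n
        )
        activity = (
            tspec.activity_baseline
            + tspec.activity_drift * progress
            + rng.normal(0, tspec.activity_sd, n)
        )
        pvc = tspec.pvc_baseline + tspec.pvc_drift * progress + rng.normal(
            0, tspec.pvc_sd, n
        )
        nhr_sd = tspec.night_hr_sd + (
            tspec.night_hr_sd_at_event - tspec.night_hr_sd
        ) * (progress / tspec.drift_lead_days)
        night_hr = tspec.night_hr_baseline + rng.normal(0, 1.0, n) * nhr_sd
        if anchors.size:
            ahre_level = tspec.ahre_level_start + (
                tspec.ahre_level_at_event - tspec.ahre_level_start
            ) * (progress / tspec.drift_lead_days)
        else:
            ahre_level = np.full(n, tspec.ahre_level_control)
        ahre = np.clip(ahre_level * rng.exponential(1.0, n), 0.0, 100.0)

        frame = pd.DataFrame(
            {
                "patient_id": pat.patient_id,
                "day": days,
                "hr24": np.clip(hr24, 30.0, 200.0),
                "night_hr": np.clip(night_hr, 30.0, 180.0),
                "hrv": np.clip(hrv, 5.0, None),
                "ahre_pct": ahre,
                "pvc_per_h": np.clip(pvc, 0.0, None),
                "activity": np.clip(activity, 0.0, 100.0),
                "impedance": np.clip(ti, 25.0, None),
                "transmitted": transmitted,
            }
        )
        measure_cols = [
            "hr24", "night_hr", "hrv", "ahre_pct",
            "pvc_per_h", "activity", "impedance",
        ]
        frame.loc[~frame["transmitted"], measure_cols] = np.nan
        frame.loc[frame["ahre_pct"] > 20.0, "hrv"] = np.nan
        frames.append(frame)
    if not frames:
        return pd.DataFrame(
            columns=[
                "patient_id", "day", "hr24", "night_hr", "hrv", "ahre_pct",
                "pvc_per_h", "activity", "impedance", "transmitted",
            ]
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Fixtures for the eligibility cascade and trial tallies

#: Per-stage exclusion counts of the pooled-cohort filtering cascade.
CASCADE_COUNTS = {
    "unsuitable_device_or_hm": 1654,
    "longstanding_af": 391,
    "lvef_gt_35": 232,
    "nyha_not_ii_iii": 221,
    "insufficient_hm_data": 1125,
    "short_follow_up": 314,
}
CASCADE_TOTAL = 5987


def make_filter_fixture() -> pd.DataFrame:
    """Eligibility-cascade fixture: 5987 records, one exclusion reason each.

    Each excluded record fails exactly one stage; the remaining 2050
    records pass all stages.  Columns carry the attributes the cascade
    tests: ``device_ok``, ``hm_enabled``, ``longstanding_af``, ``lvef``,
    ``nyha``, ``sufficient_hm_data``, ``followup_post_runin_days``,
    ``has_whfh``.
    """
    n = CASCADE_TOTAL
    df = pd.DataFrame(
        {
            "patient_id": [f"F{i + 1:05d}" for i in range(n)],
            "device_ok": True,
            "hm_enabled": True,
            "longstanding_af": False,
            "lvef": 30.0,
            "nyha": 3,
            "sufficient_hm_data": True,
            "followup_post_runin_days": 400,
            "has_whfh": False,
        }
    )
    pos = 0
    stage_cols = {
        "unsuitable_device_or_hm": ("device_ok", False),
        "longstanding_af": ("longstanding_af", True),
        "lvef_gt_35": ("lvef", 40.0),
        "nyha_not_ii_iii": ("nyha", 4),
        "insufficient_hm_data": ("sufficient_hm_data", False),
        "short_follow_up": ("followup_post_runin_days", 60),
    }
    for stage, count in CASCADE_COUNTS.items():
        col, bad = stage_cols[stage]
        df.loc[pos : pos + count - 1, col] = bad
        pos += count
    return df


#: Per-trial (patients, patients with events, events) of the pooled
#: nine-trial cohort the simulator emulates.
TRIAL_PROFILES: Mapping[str, tuple[int, int, int]] = {
    "SELENE HF": (691, 80, 112),
    "BIO|Stream.HF": (408, 24, 30),
    "EchoCRT": (269, 38, 64),
    "ECOST-CRT": (205, 22, 35),
    "HomeCARE II": (152, 38, 46),
    "J-HomeCARE II": (121, 16, 22),
    "DetectICI": (102, 9, 12),
    "CASTLE-AF": (66, 29, 44),
    "effecT": (36, 3, 4),
}


def make_trial_fixture() -> tuple[list[PatientRecord], list[WHFHEvent]]:
    """Patients and events reproducing the per-trial tallies exactly.

    Within each trial the first ``n_event`` patients carry events;
    extra events beyond one per patient are assigned round-robin.
    Deterministic (no randomness): intended for tally accounting, not
    for trajectory simulation.
    """
    patients: list[PatientRecord] = []
    events: list[WHFHEvent] = []
    i = 0
    for trial, (n_pat, n_ev_pat, n_ev) in TRIAL_PROFILES.items():
        extra = n_ev - n_ev_pat
        per_patient = [1] * n_ev_pat
        j = 0
        while extra > 0:
            if per_patient[j % n_ev_pat] < 3:
                per_patient[j % n_ev_pat] += 1
                extra -= 1
            j += 1
        for k in range(n_pat):
            pid = f"T{i + 1:05d}"
            is_event = k < n_ev_pat
            patients.append(
                PatientRecord(
                    patient_id=pid,
                    group="event" if is_event else "control",
                    implant_day=0,
                    follow_up_end=730,
                    age=67.0,
                    male=True,
                    bmi=26.9,
                    nyha=3,
                    lvef=29.0,
                    af_history=False,
                    renal_insufficiency=False,
                    ischaemic=False,
                    device="CRT-D",
                    trial_label=trial,
                )
            )
            if is_event:
                for m in range(per_patient[k]):
                    events.append(
                        WHFHEvent(
                            event_id=f"{pid}-E{m + 1}",
                            patient_id=pid,
                            admission_day=150 + 120 * m,
                        )
                    )
            i += 1
    return patients, events
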