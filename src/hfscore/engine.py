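"""Daily composite heart-failure score engine.

Each day, seven component scores are computed from the trailing 84-day
window of remotely transmitted device telemetry and summed into a single
HF Score.  The components capture, respectively:

* monotone increase of the 24-h mean heart rate,
* monotone decrease of heart-rate variability (assessed only on days
  without substantial atrial high-rate episode burden),
* instability (dispersion) of the nocturnal mean heart rate,
* monotone decrease of thoracic impedance (fluid accumulation),
* monotone decrease of physical activity,
* the level of atrial high-rate episode (AHRE) burden, and
* monotone increase of the hourly premature-ventricular-contraction rate.

Each component is a normalized statistic in [0, 1] scaled by a configurable
weight (its maximum attainable contribution), so the composite score lives
on a 0-to-sum-of-weights scale.  A convenience ``index`` equal to
``score / 10`` is carried alongside.  An alert state machine with a
nominal trigger threshold and a lower recovery threshold (hysteresis)
turns daily scores into contiguous in-alert episodes.

Monotone components use a Mann-Kendall-style pairwise concordance
statistic: shift-invariant, rank-based, and saturating at the weight for
a strictly monotone window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COMPONENTS",
    "DEFAULT_WEIGHTS",
    "EngineConfig",
    "ComponentScores",
    "HFScorePoint",
    "AlertEpisode",
    "mann_kendall",
    "compute_components",
    "compose_score",
    "transmission_rate",
    "update_alert_state",
    "score_telemetry",
]

#: Canonical component order (descending default contribution).
COMPONENTS = ("hr24", "hrv", "night_hr", "ti", "activity", "ahre", "pvc")

#: Default maximum contribution of each component, in score points.
DEFAULT_WEIGHTS: Mapping[str, float] = {
    "hr24": 20.0,
    "hrv": 20.0,
    "night_hr": 15.0,
    "ti": 15.0,
    "activity": 10.0,
    "ahre": 10.0,
    "pvc": 10.0,
}

#: Telemetry channel feeding each component.
_CHANNEL = {
    "hr24": "hr24",
    "hrv": "hrv",
    "night_hr": "night_hr",
    "ti": "impedance",
    "activity": "activity",
    "ahre": "ahre_pct",
    "pvc": "pvc_per_h",
}


@dataclass(frozen=True)
class EngineConfig:
    """Tunable parameters of the scoring engine.

    Attributes
    ----------
    weights
        Maximum contribution (score points) of each component.
    nominal_threshold
        Alert trigger level on the composite score scale.
    recovery_offset
        The alert clears when the score falls below
        ``nominal_threshold - recovery_offset`` (hysteresis).
    stable_exceed_days
        Number of consecutive valid days above the nominal threshold
        required to open an alert episode.
    window_days
        Length of the trailing window the components are computed on.
    min_transmission_rate
        Minimum fraction of transmitted days over the trailing
        ``transmission_horizon_days`` for a daily score to be valid.
    run_in_days
        Post-implant stabilization period; no scores are emitted before
        ``implant_day + run_in_days``.
    night_hr_ref_sd
        Reference dispersion (bpm) against which nocturnal-HR
        instability is normalized.
    night_hr_span_days
        Trailing span used for the nocturnal-HR standard deviation.
    ahre_saturation_pct
        AHRE burden (% of 24 h) at which the AHRE component saturates.
    ahre_hrv_exclusion_pct
        Days with AHRE burden above this cut-off are excluded from the
        HRV statistic.
    min_window_obs
        Windows with fewer measured days yield all-zero components and
        an invalid score.
    """

    weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    nominal_threshold: float = 45.0
    recovery_offset: float = 10.0
    stable_exceed_days: int = 2
    window_days: int = 84
    min_transmission_rate: float = 0.55
    transmission_horizon_days: int = 90
    run_in_days: int = 30
    night_hr_ref_sd: float = 8.0
    night_hr_span_days: int = 28
    ahre_saturation_pct: float = 50.0
    ahre_hrv_exclusion_pct: float = 20.0
    min_window_obs: int = 10

    def __post_init__(self) -> None:
        if self.nominal_threshold <= self.recovery_offset:
            raise ValueError("nominal_threshold must exceed recovery_offset")
        if self.window_days < 7:
            raise ValueError("window_days must be at least 7")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("component weights must be non-negative")
        if not 0.0 <= self.min_transmission_rate <= 1.0:
            raise ValueError("min_transmission_rate must lie in [0, 1]")
        missing = set(COMPONENTS) - set(self.weights)
        if missing:
            raise ValueError(f"weights missing for components: {sorted(missing)}")

    @property
    def recovery_threshold(self) -> float:
        return self.nominal_threshold - self.recovery_offset

    @property
    def max_score(self) -> float:
        return float(sum(self.weights.values()))

    def with_weights(self, **weights: float) -> "EngineConfig":
        merged = dict(self.weights)
        merged.update(weights)
        return replace(self, weights=merged)


@dataclass(frozen=True)
class ComponentScores:
    """The seven non-negative component values for one day."""

    hr24: float
    hrv: float
    night_hr: float
    ti: float
    activity: float
    ahre: float
    pvc: float

    def __post_init__(self) -> None:
        for name in COMPONENTS:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"component {name!r} is not finite")
            if v < 0:
                raise ValueError(f"component {name!r} is negative: {v}")

    def total(self) -> float:
        return float(sum(getattr(self, name) for name in COMPONENTS))

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in COMPONENTS}


@dataclass(frozen=True)
class HFScorePoint:
    """Composite score for one day; ``index`` is ``score / 10``."""

    day: int
    score: float
    index: float
    components: ComponentScores
    valid: bool = True


@dataclass(frozen=True)
class AlertEpisode:
    """A contiguous in-alert interval.

    ``end_day`` is the day the score first dropped below the recovery
    threshold, or ``None`` while the episode is still open.
    """

    start_day: int
    end_day: int | None
    threshold_at_start: float


def mann_kendall(values: Sequence[float] | np.ndarray) -> float:
    """Normalized Mann-Kendall concordance statistic in [-1, 1].

    Sum over all ordered pairs of ``sign(x_j - x_i)`` divided by the
    number of pairs.  +1 for a strictly increasing series, -1 for a
    strictly decreasing one, 0 in expectation for exchangeable noise
    and exactly 0 for a constant series.  Returns 0.0 for fewer than
    two observations.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        return 0.0
    diffs = np.sign(x[None, :] - x[:, None])
    s = np.sum(np.triu(diffs, k=1))
    return float(s / (n * (n - 1) / 2))


def _trend_up(x: np.ndarray) -> float:
    return max(mann_kendall(x), 0.0)


def _trend_down(x: np.ndarray) -> float:
    return max(-mann_kendall(x), 0.0)


def compute_components(
    window: pd.DataFrame, config: EngineConfig | None = None
) -> ComponentScores:
    """Compute the seven component scores from one trailing window.

    Parameters
    ----------
    window
        Daily telemetry rows for a single patient covering at most
        ``config.window_days`` days, in chronological order.  Expected
        columns: ``day``, ``hr24``, ``night_hr``, ``hrv``, ``ahre_pct``,
        ``pvc_per_h``, ``activity``, ``impedance``, ``transmitted``.
        Only transmitted rows carry measurements.
    config
        Engine configuration; defaults are used when omitted.

    Returns
    -------
    ComponentScores
        All zeros when fewer than ``config.min_window_obs`` transmitted
        days are available.
    """
    cfg = config or EngineConfig()
    if len(window) == 0:
        return ComponentScores(0, 0, 0, 0, 0, 0, 0)
    days = np.asarray(window["day"], dtype=float)
    if np.any(np.diff(days) <= 0):
        raise ValueError("window days must be strictly increasing")
    if days[-1] - days[0] >= cfg.window_days:
        raise ValueError(
            f"window spans {int(days[-1] - days[0]) + 1} days, "
            f"longer than window_days={cfg.window_days}"
        )
    if "transmitted" in window.columns:
        obs = window[window["transmitted"].astype(bool)]
    else:
        obs = window
    if len(obs) < cfg.min_window_obs:
        return ComponentScores(0, 0, 0, 0, 0, 0, 0)

    w = cfg.weights
    hr24 = w["hr24"] * _trend_up(obs["hr24"].to_numpy(dtype=float))
    ti = w["ti"] * _trend_down(obs["impedance"].to_numpy(dtype=float))
    activity = w["activity"] * _trend_down(obs["activity"].to_numpy(dtype=float))
    pvc = w["pvc"] * _trend_up(obs["pvc_per_h"].to_numpy(dtype=float))

    # HRV trend evaluated only on days essentially free of AHRE.
    ahre_vals = obs["ahre_pct"].to_numpy(dtype=float)
    hrv_mask = ~(ahre_vals > cfg.ahre_hrv_exclusion_pct)
    hrv = w["hrv"] * _trend_down(obs["hrv"].to_numpy(dtype=float)[hrv_mask])

    # Nocturnal-HR instability: trailing dispersion vs a reference SD.
    last_day = obs["day"].to_numpy(dtype=float)[-1]
    recent = obs[obs["day"] > last_day - cfg.night_hr_span_days]
    nhr = recent["night_hr"].to_numpy(dtype=float)
    nhr = nhr[np.isfinite(nhr)]
    if nhr.size >= 2 and cfg.night_hr_ref_sd > 0:
        instab = min(float(np.std(nhr, ddof=1)) / cfg.night_hr_ref_sd, 1.0)
    else:
        instab = 0.0
    night_hr = w["night_hr"] * instab

    # AHRE burden: saturating level statistic.
    finite_ahre = ahre_vals[np.isfinite(ahre_vals)]
    mean_ahre = float(np.mean(finite_ahre)) if finite_ahre.size else 0.0
    ahre = w["ahre"] * min(max(mean_ahre, 0.0) / cfg.ahre_saturation_pct, 1.0)

    return ComponentScores(
        hr24=hr24, hrv=hrv, night_hr=night_hr, ti=ti,
        activity=activity, ahre=ahre, pvc=pvc,
    )


def compose_score(
    components: ComponentScores, day: int = 0, valid: bool = True
) -> HFScorePoint:
    """Sum the seven components into the composite score.

    The composite is the exact sum of the component values; the
    companion ``index`` is the score divided by 10.
    """
    score = components.total()
    return HFScorePoint(
        day=day, score=score, index=score / 10.0, components=components, valid=valid
    )


def transmission_rate(
    transmitted_flags: pd.Series | Mapping[int, bool],
    day: int,
    horizon: int = 90,
) -> float:
    """Fraction of transmitted days in the trailing ``horizon`` window.

    ``transmitted_flags`` maps day index to a transmission flag; the
    series is assumed to start at its smallest index.  The denominator
    is ``min(horizon, day - series_start + 1)`` so that a young series
    is not penalized for days that predate it.
    """
    flags = pd.Series(transmitted_flags).astype(bool)
    if flags.empty:
        raise ValueError("empty transmission series")
    start = int(flags.index.min())
    if day < start:
        raise ValueError(f"day {day} precedes series start {start}")
    denom = min(horizon, day - start + 1)
    lo = day - horizon + 1
    in_window = flags.loc[(flags.index >= lo) & (flags.index <= day)]
    return float(in_window.sum()) / denom


def update_alert_state(
    score_series: pd.DataFrame, config: EngineConfig | None = None
) -> list[AlertEpisode]:
    """Run the threshold/recovery alert state machine over daily scores.

    An episode opens on the first day of ``stable_exceed_days``
    consecutive valid days with score above the nominal threshold while
    not already in alert, and closes on the first subsequent valid day
    with score below the recovery threshold (nominal minus the recovery
    offset).  Missing or invalid days pause the consecutive-day counter
    and never terminate an open episode.
    """
    cfg = config or EngineConfig()
    if len(score_series) == 0:
        return []
    days = score_series["day"].to_numpy()
    if np.any(np.diff(days) <= 0):
        raise ValueError("scores must be in chronological order")
    scores = score_series["score"].to_numpy(dtype=float)
    if "valid" in score_series.columns:
        valid = score_series["valid"].to_numpy(dtype=bool)
    else:
        valid = np.ones(len(score_series), dtype=bool)

    episodes: list[AlertEpisode] = []
    in_alert = False
    run_start: int | None = None
    run_len = 0
    start_day = 0
    for d, s, ok in zip(days, scores, valid):
        if not ok or not np.isfinite(s):
            continue  # gaps pause the counter and never clear an alert
        if in_alert:
            if s < cfg.recovery_threshold:
                episodes.append(
                    AlertEpisode(
                        start_day=int(start_day),
                        end_day=int(d),
                        threshold_at_start=cfg.nominal_threshold,
                    )
                )
                in_alert = False
                run_start, run_len = None, 0
        else:
            if s > cfg.nominal_threshold:
                if run_len == 0:
                    run_start = int(d)
                run_len += 1
                if run_len >= cfg.stable_exceed_days:
                    in_alert = True
                    start_day = run_start  # retroactive to run start
                    run_start, run_len = None, 0
            else:
                run_start, run_len = None, 0
    if in_alert:
        episodes.append(
            AlertEpisode(
                start_day=int(start_day),
                end_day=None,
                threshold_at_start=cfg.nominal_threshold,
            )
        )
    return episodes


def score_telemetry(
    telemetry: pd.DataFrame,
    config: EngineConfig | None = None,
    implant_days: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Score every patient-day of a telemetry table.

    Scores are emitted from ``implant_day + run_in_days`` onward.  The
    ``valid`` flag combines the transmission-rate gate with the
    minimum-observations rule of :func:`compute_components`.

    Returns a frame with one row per scored patient-day: ``patient_id``,
    ``day``, the seven component columns, ``score``, ``index``,
    ``valid``.
    """
    cfg = config or EngineConfig()
    implant_days = implant_days or {}
    rows: list[dict] = []
    for pid, group in telemetry.groupby("patient_id", sort=True):
        group = group.sort_values("day").reset_index(drop=True)
        flags = pd.Series(
            group["transmitted"].astype(bool).to_numpy(), index=group["day"].to_numpy()
        )
        day_values = group["day"].to_numpy()
        first = int(implant_days.get(pid, day_values.min()))
        for i, day in enumerate(day_values):
            if day < first + cfg.run_in_days:
                continue
            lo = day - cfg.window_days + 1
            window = group[(day_values >= lo) & (day_values <= day)]
            comps = compute_components(window, cfg)
            rate = transmission_rate(flags, int(day), cfg.transmission_horizon_days)
            n_obs = int(window["transmitted"].astype(bool).sum())
            valid = rate >= cfg.min_transmission_rate and n_obs >= cfg.min_window_obs
            point = compose_score(comps, day=int(day), valid=valid)
            rows.append(
                {
                    "patient_id": pid,
                    "day": int(day),
                    **comps.as_dict(),
                    "score": point.score,
                    "index": point.index,
                    "valid": valid,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "day", *COMPONENTS, "score", "index", "valid"],
    )
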