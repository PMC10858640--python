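"""CSV and config I/O.

All tables are plain CSV with an empty string for missing values:
``patients.csv``, ``events.csv``, ``telemetry.csv``,
``component_scores.csv``, ``weekly_observations.csv``,
``exclusion_tally.csv``.  Configuration is YAML with one section per
configurable object (``cohort``, ``trajectory``, ``engine``,
``telemetry``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from .engine import EngineConfig
from .synthetic import (
    CohortConfig,
    PatientRecord,
    TelemetrySpec,
    TrajectorySpec,
    WHFHEvent,
    events_to_frame,
    patients_to_frame,
)

__all__ = [
    "load_config",
    "write_patients", "read_patients",
    "write_events", "read_events",
    "write_table", "read_table",
]


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML config into the package's config objects.

    Returns a dict with whichever of ``cohort`` (:class:`CohortConfig`),
    ``trajectory`` (:class:`TrajectorySpec`), ``engine``
    (:class:`EngineConfig`) and ``telemetry`` (:class:`TelemetrySpec`)
    sections are present; unknown sections are passed through raw.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out: dict[str, Any] = {}
    for key, value in raw.items():
        if key == "cohort":
            value = dict(value)
            if "follow_up_days" in value:
                value["follow_up_days"] = tuple(value["follow_up_days"])
            if "events_per_patient_probs" in value:
                value["events_per_patient_probs"] = tuple(
                    value["events_per_patient_probs"]
                )
            if "covariate_prevalences" in value:
                value["covariate_prevalences"] = {
                    k: tuple(v) for k, v in value["covariate_prevalences"].items()
                }
            out[key] = CohortConfig(**value)
        elif key == "trajectory":
            out[key] = TrajectorySpec(**value)
        elif key == "engine":
            out[key] = EngineConfig(**value)
        elif key == "telemetry":
            out[key] = TelemetrySpec(**value)
        else:
            out[key] = value
    return out


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, na_rep="")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_patients(patients: Sequence[PatientRecord], path: str | Path) -> None:
    write_table(patients_to_frame(patients), path)


_PATIENT_CASTS = {
    "patient_id": str, "group": str, "implant_day": int, "follow_up_end": int,
    "age": float, "male": bool, "bmi": float, "nyha": int, "lvef": float,
    "af_history": bool, "renal_insufficiency": bool, "ischaemic": bool,
    "device": str, "trial_label": str,
}


def read_patients(path: str | Path) -> list[PatientRecord]:
    frame = pd.read_csv(path)
    return [
        PatientRecord(**{k: _PATIENT_CASTS[k](v) for k, v in row.items()})
        for row in frame.to_dict("records")
    ]


def write_events(events: Sequence[WHFHEvent], path: str | Path) -> None:
    write_table(events_to_frame(events), path)


def read_events(path: str | Path) -> list[WHFHEvent]:
    frame = pd.read_csv(path)
    return [
        WHFHEvent(
            event_id=str(row["event_id"]),
            patient_id=str(row["patient_id"]),
            admission_day=int(row["admission_day"]),
            adjudicated=bool(row["adjudicated"]),
        )
        for row in frame.to_dict("records")
    ]
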