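"""Session bundles on disk.

A bundle directory holds plain-text artifacts only: ``participants.csv``,
``schedule.json``, per-participant ``gaze_stream.csv`` / ``pupil_stream.csv``
(long format with a participant column), ``responses.csv``, and a ``truth/``
subdirectory (latent codes and calibration coefficients) intended for
testing, never for analysis.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from gazephen import EMOTIONS
from gazephen.synth.cohort import Participant, uniform_confusion_profile
from gazephen.synth.pupilsim import CalibrationGroundTruth
from gazephen.synth.schedule import StimulusSchedule


def participants_frame(cohort: list[Participant]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant": [p.participant_id for p in cohort],
            "group": [p.group for p in cohort],
            "age": [p.age for p in cohort],
            "gender": [p.gender for p in cohort],
            "latent_distraction": [p.latent_distraction for p in cohort],
            "latent_offtask": [p.latent_offtask for p in cohort],
            "scq": [p.clinical.get("scq", np.nan) for p in cohort],
            "srs": [p.clinical.get("srs", np.nan) for p in cohort],
            "abiq": [p.clinical.get("abiq", np.nan) for p in cohort],
        }
    )


def write_bundle(
    out_dir,
    cohort: list[Participant],
    schedule: StimulusSchedule,
    gaze: pd.DataFrame | None = None,
    pupil: pd.DataFrame | None = None,
    responses: pd.DataFrame | None = None,
    truth_codes: pd.DataFrame | None = None,
    calibration_truth: dict[str, CalibrationGroundTruth] | None = None,
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    participants_frame(cohort).to_csv(out / "participants.csv", index=False)
    (out / "schedule.json").write_text(schedule.to_json())
    if gaze is not None:
        gaze.to_csv(out / "gaze_stream.csv", index=False)
    if pupil is not None:
        pupil.to_csv(out / "pupil_stream.csv", index=False)
    if responses is not None:
        responses.to_csv(out / "responses.csv", index=False)
    truth_dir = out / "truth"
    if truth_codes is not None:
        truth_dir.mkdir(exist_ok=True)
        truth_codes.to_csv(truth_dir / "latent_codes.csv", index=False)
    if calibration_truth is not None:
        truth_dir.mkdir(exist_ok=True)
        payload = {
            pid: [
                {
                    "epoch_id": e.epoch_id,
                    "start_frame": e.start_frame,
                    "end_frame": e.end_frame,
                    "matrix": np.asarray(e.matrix).tolist(),
                    "offset": np.asarray(e.offset).tolist(),
                }
                for e in truth.epochs
            ]
            for pid, truth in calibration_truth.items()
        }
        (truth_dir / "calibration.json").write_text(json.dumps(payload, indent=1))
    return out


def read_bundle(path) -> dict:
    path = Path(path)
    out: dict = {
        "participants": pd.read_csv(path / "participants.csv"),
        "schedule": StimulusSchedule.from_json(
            (path / "schedule.json").read_text()
        ),
    }
    for name in ("gaze_stream", "pupil_stream", "responses"):
        f = path / f"{name}.csv"
        if f.exists():
            out[name] = pd.read_csv(f)
    return out


def cohort_from_frame(df: pd.DataFrame, accuracy: float = 0.75) -> list[Participant]:
    """Rebuild Participant objects from a participants.csv table.

    Confusion profiles are not stored in the bundle; a uniform profile with
    the given diagonal accuracy is substituted.
    """
    profile = uniform_confusion_profile(accuracy)
    return [
        Participant(
            participant_id=row["participant"],
            group=row["group"],
            age=int(row["age"]),
            gender=row["gender"],
            latent_distraction=float(row["latent_distraction"]),
            latent_offtask=float(row["latent_offtask"]),
            confusion_profile=profile,
        )
        for _, row in df.iterrows()
    ]
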