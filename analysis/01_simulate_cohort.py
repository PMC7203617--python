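"""Generate the synthetic study cohort and write a session bundle.

Draws 16 ASD / 17 NC participants with the default latent-distraction
moments, builds the 41/42/41 stimulus schedule, simulates one participant's
gaze/pupil/response streams as a worked example, and writes the bundle
(full streams under scratch/, small summaries under results/).
"""

import json
from pathlib import Path

import numpy as np

from gazephen import default_geometry
from gazephen.session_io import participants_frame, write_bundle
from gazephen.synth import (
    make_calibration_truth,
    make_cohort,
    make_schedule,
    simulate_gaze,
    simulate_pupil,
    simulate_responses,
)

SEED = 7
FRAME_RATE = 10

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    cohort = make_cohort(16, 17, seed=SEED)
    schedule = make_schedule(frame_rate=FRAME_RATE, seed=SEED)
    geometry = default_geometry()

    example = cohort[0]
    gaze, truth_codes = simulate_gaze(example, schedule, geometry, seed=SEED)
    calib = make_calibration_truth(schedule, seed=SEED)
    pupil = simulate_pupil(gaze, calib, pupil_noise=0.005, seed=SEED)
    responses = simulate_responses(example, schedule, seed=SEED)

    bundle = write_bundle(
        SCRATCH / "session_bundle", cohort, schedule,
        gaze=gaze, pupil=pupil, responses=responses, truth_codes=truth_codes,
        calibration_truth={example.participant_id: calib},
    )

    RESULTS.mkdir(exist_ok=True)
    pf = participants_frame(cohort)
    pf.to_csv(RESULTS / "participants.csv", index=False)
    summary = {
        "seed": SEED,
        "frame_rate": FRAME_RATE,
        "n_frames": schedule.n_frames,
        "n_stimuli": schedule.n_stimuli,
        "n_dot_events": len(schedule.dot_events),
        "latent_distraction_mean": {
            g: float(pf.loc[pf["group"] == g, "latent_distraction"].mean())
            for g in ("ASD", "NC")
        },
    }
    (RESULTS / "cohort_summary.json").write_text(json.dumps(summary, indent=1))
    print(f"cohort of {len(cohort)} written; bundle at {bundle}")
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
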