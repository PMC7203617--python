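"""End-to-end orchestration: generator -> calibration -> coding -> features.

Two routes through the gaze stage are provided:

- ``coordinate``: code the generator's emitted world-gaze stream directly
  (no calibration error) — the fast route for statistical experiments;
- ``full``: synthesize the pupil stream under the ground-truth epoch
  mappings, re-fit per-epoch polynomial models from the generator's
  calibration-point pairs, assign epochs from the validation dots, predict
  world coordinates, and code those — the faithful reconstruction route.

Per-participant seeds are derived from the master seed with a splittable
scheme, so results do not depend on execution order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from gazephen.calibration import assign_epochs, fit_calibration, predict_world
from gazephen.coding import (
    aggregate_participant,
    code_session,
    coded_frames,
    distraction_ratio,
    exclude_outliers,
    group_ttest,
)
from gazephen.features import assemble, build_trial_features
from gazephen.geometry import ScreenGeometry, default_geometry
from gazephen.synth import (
    calibration_point_pairs,
    make_calibration_truth,
    simulate_gaze,
    simulate_pupil,
    simulate_responses,
)
from gazephen.synth.cohort import Participant
from gazephen.synth.schedule import StimulusSchedule


def participant_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-participant substream seeds (uint32)."""
    return np.random.SeedSequence(seed).generate_state(n)


def run_participant(
    participant: Participant,
    schedule: StimulusSchedule,
    geometry: ScreenGeometry,
    seed: int,
    route: str = "coordinate",
    noise_sd: float = 0.01,
    dwell: float = 0.9,
    pupil_noise: float = 0.0,
    calib_noise: float = 0.0,
    degree: int = 2,
    feedback_boost: float = 0.15,
) -> dict:
    """Simulate and code one session; returns streams, counts, responses."""
    rng_seeds = np.random.SeedSequence(seed).generate_state(5)
    gaze, truth_codes = simulate_gaze(
        participant, schedule, geometry, seed=int(rng_seeds[0]),
        dwell=dwell, noise_sd=noise_sd,
    )
    responses = simulate_responses(
        participant, schedule, feedback_boost=feedback_boost,
        seed=int(rng_seeds[1]),
    )
    out = {"gaze": gaze, "truth_codes": truth_codes, "responses": responses}
    if route == "coordinate":
        world = gaze
        epochs = None
    elif route == "full":
        calib_truth = make_calibration_truth(schedule, seed=int(rng_seeds[2]))
        pupil = simulate_pupil(
            gaze, calib_truth, pupil_noise=pupil_noise, seed=int(rng_seeds[3])
        )
        pairs = calibration_point_pairs(
            calib_truth, pupil_noise=calib_noise, seed=int(rng_seeds[4])
        )
        models = [
            fit_calibration(p, w, degree=degree, epoch_id=eid)
            for eid, (p, w) in pairs.items()
        ]
        epochs = assign_epochs(
            pupil, models, list(schedule.dot_events),
            n_frames=schedule.n_frames,
        )
        by_id = {m.epoch_id: m for m in models}
        frames = pupil["frame"].to_numpy()
        coords = pupil[["x", "y"]].to_numpy(dtype=float)
        pred = np.full_like(coords, np.nan)
        eids = epochs.epoch_of(frames)
        finite = np.isfinite(coords).all(axis=1)
        for eid in np.unique(eids):
            if eid < 0:
                continue
            sel = (eids == eid) & finite
            if sel.any():
                pred[sel] = predict_world(by_id[int(eid)], coords[sel])
        world = pd.DataFrame(
            {
                "frame": frames,
                "x": pred[:, 0],
                "y": pred[:, 1],
                "missing": ~np.isfinite(pred).all(axis=1),
            }
        )
        out.update(pupil=pupil, models=models, epochs=epochs,
                   calibration_truth=calib_truth)
    else:
        raise ValueError(f"unknown route {route!r}")
    out["world"] = world
    out["counts"] = code_session(
        world, schedule, geometry, epochs=epochs,
        participant_id=participant.participant_id,
    )
    out["per_frame"] = coded_frames(world, geometry, epochs)
    return out


def stimulus_code_map(
    per_frame: pd.DataFrame, schedule: StimulusSchedule
) -> dict[str, np.ndarray]:
    """stimulus_id -> retained coded frame sequence of its window."""
    codes = per_frame.sort_values("frame")
    code_arr = codes["code"].to_numpy()
    kept = codes["kept"].to_numpy()
    result = {}
    for _, stim in schedule.iter_stimuli():
        sl = slice(stim.onset_frame, stim.onset_frame + stim.duration_frames)
        result[stim.stimulus_id] = code_arr[sl][kept[sl]]
    return result


def run_cohort(
    cohort: list[Participant],
    schedule: StimulusSchedule,
    seed: int,
    geometry: ScreenGeometry | None = None,
    route: str = "coordinate",
    min_trackable_fraction: float = 0.5,
    features: bool = True,
    **session_kwargs,
) -> dict:
    """Run every participant, pool counts/records, and build feature blocks.

    ``features=False`` skips feature-block construction (faster when only
    the distraction statistics are needed).
    """
    geometry = geometry or default_geometry()
    seeds = participant_seeds(seed, len(cohort))
    all_counts = []
    all_responses = []
    blocks: dict[str, dict[int, dict[str, pd.Series]]] = {}
    groups = {p.participant_id: p.group for p in cohort}
    for participant, pseed in zip(cohort, seeds):
        sess = run_participant(
            participant, schedule, geometry, seed=int(pseed),
            route=route, **session_kwargs,
        )
        all_counts.append(sess["counts"])
        all_responses.append(sess["responses"])
        if features:
            code_map = stimulus_code_map(sess["per_frame"], schedule)
            blocks[participant.participant_id] = {
                t.trial_index: build_trial_features(
                    participant, schedule, t.trial_index,
                    sess["responses"], code_map,
                )
                for t in schedule.trials
            }
    counts = pd.concat(all_counts, ignore_index=True)
    counts, exclusion_report = exclude_outliers(
        counts, min_fraction=min_trackable_fraction
    )
    records = distraction_ratio(counts)
    records["group"] = records["participant"].map(groups)
    d_p = aggregate_participant(records)
    return {
        "counts": counts,
        "records": records,
        "d_p": d_p,
        "responses": pd.concat(all_responses, ignore_index=True),
        "blocks": blocks,
        "groups": groups,
        "exclusion_report": exclusion_report,
    }


def h1_analysis(run: dict) -> dict:
    """Group tests on per-participant and per-stimulus distraction ratios."""
    d_p = run["d_p"]
    groups = run["groups"]
    asd = [v for pid, v in d_p.items() if groups[pid] == "ASD"]
    nc = [v for pid, v in d_p.items() if groups[pid] == "NC"]
    participant_level = group_ttest(asd, nc)
    rec = run["records"][run["records"]["valid"]]
    stim_level = group_ttest(
        rec.loc[rec["group"] == "ASD", "d"],
        rec.loc[rec["group"] == "NC", "d"],
    )
    stim_level["caveat"] = (
        "treats per-stimulus ratios within a participant as independent"
    )
    return {"participant_level": participant_level,
            "stimulus_level": stim_level}


def feature_table(run: dict, trials=None, families=None) -> pd.DataFrame:
    return assemble(run["blocks"], run["groups"], trials=trials,
                    families=families)
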