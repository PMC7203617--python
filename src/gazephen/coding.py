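"""Area-of-interest coding and distraction statistics.

Every frame with a world-gaze estimate is coded F (face), L (left
distractor), R (right distractor), or N ("nowhere in particular": outside
all regions, off-screen, or missing).  Per-stimulus counts feed the two
distraction ratios:

    d      = (nL + nR) / (nF + nL + nR + nN)      (N in the denominator)
    d_FLR  = (nL + nR) / (nF + nL + nR)           (N excluded; >= d)

d is averaged over all stimuli and trials to a per-participant d(p); d_FLR
is additionally averaged per (participant, trial, true emotion).  Group
comparisons use a one-tailed two-sample t-test (alternative: ASD > NC),
Welch by default since group variances are strongly unequal.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from gazephen.calibration import EpochAssignment
from gazephen.geometry import ScreenGeometry
from gazephen.synth.schedule import StimulusSchedule

MIN_TRACKABLE_FRACTION = 0.5


def code_frame(x, y, geometry: ScreenGeometry) -> np.ndarray:
    """Vectorized F/L/R/N coding; boundary-inclusive; NaN codes as N."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    codes = np.full(x.shape, "N", dtype="<U1")
    ok = np.isfinite(x) & np.isfinite(y)
    for name, rect in geometry.regions.items():
        inside = ok & rect.contains(x, y)
        codes[inside] = name
    return codes


def coded_frames(
    gaze: pd.DataFrame,
    geometry: ScreenGeometry,
    epochs: EpochAssignment | None = None,
) -> pd.DataFrame:
    """Per-frame codes with a ``kept`` flag (False in none-epochs)."""
    codes = code_frame(gaze["x"].to_numpy(), gaze["y"].to_numpy(), geometry)
    frames = gaze["frame"].to_numpy()
    if epochs is None:
        kept = np.ones(len(frames), dtype=bool)
    else:
        kept = epochs.epoch_of(frames) >= 0
    return pd.DataFrame({"frame": frames, "code": codes, "kept": kept})


def code_session(
    gaze: pd.DataFrame,
    schedule: StimulusSchedule,
    geometry: ScreenGeometry,
    epochs: EpochAssignment | None = None,
    participant_id: str = "",
) -> pd.DataFrame:
    """Per-stimulus (F, L, R, N) frame counts.

    Frames in none-epochs are dropped; dot-event frames never enter stimulus
    windows (windows are checked against dot events defensively).  Stimuli
    whose every frame was dropped keep an all-zero row.
    """
    frames = gaze["frame"].to_numpy()
    if frames.min() != 0 or frames.max() != schedule.n_frames - 1:
        raise ValueError(
            "gaze stream does not cover the schedule frame range "
            f"({frames.min()}..{frames.max()} vs 0..{schedule.n_frames - 1})"
        )
    per_frame = coded_frames(gaze, geometry, epochs)
    code_arr = per_frame["code"].to_numpy()
    kept = per_frame["kept"].to_numpy()
    frame_index = per_frame["frame"].to_numpy()
    order = np.argsort(frame_index)
    code_by_frame = np.full(schedule.n_frames, "N", dtype="<U1")
    kept_by_frame = np.zeros(schedule.n_frames, dtype=bool)
    code_by_frame[frame_index[order]] = code_arr[order]
    kept_by_frame[frame_index[order]] = kept[order]

    in_dot = np.zeros(schedule.n_frames, dtype=bool)
    for d in schedule.dot_events:
        in_dot[d.start_frame : d.end_frame] = True

    rows = []
    for trial, stim in schedule.iter_stimuli():
        sl = slice(stim.onset_frame, stim.onset_frame + stim.duration_frames)
        window_keep = kept_by_frame[sl] & ~in_dot[sl]
        window_codes = code_by_frame[sl][window_keep]
        counts = {c: int((window_codes == c).sum()) for c in "FLRN"}
        rows.append(
            {
                "participant": participant_id,
                "trial": trial.trial_index,
                "stimulus_id": stim.stimulus_id,
                "true_emotion": stim.true_emotion,
                "nF": counts["F"],
                "nL": counts["L"],
                "nR": counts["R"],
                "nN": counts["N"],
                "window_frames": stim.duration_frames,
            }
        )
    return pd.DataFrame(rows)


def exclude_outliers(
    counts: pd.DataFrame,
    min_fraction: float = MIN_TRACKABLE_FRACTION,
) -> tuple[pd.DataFrame, list[dict]]:
    """Drop whole participant-trials with a low trackable-frame fraction.

    The trackable fraction of a participant-trial is the number of frames
    retained in its stimulus windows divided by the total window frames.
    """
    report: list[dict] = []
    retained = counts["nF"] + counts["nL"] + counts["nR"] + counts["nN"]
    frac = (
        pd.DataFrame(
            {
                "participant": counts["participant"],
                "trial": counts["trial"],
                "retained": retained,
                "total": counts["window_frames"],
            }
        )
        .groupby(["participant", "trial"])
        .sum()
    )
    frac["fraction"] = frac["retained"] / frac["total"]
    bad = frac[frac["fraction"] < min_fraction]
    for (pid, trial), row in bad.iterrows():
        report.append(
            {
                "participant": pid,
                "trial": int(trial),
                "trackable_fraction": float(row["fraction"]),
                "reason": f"trackable fraction {row['fraction']:.3f} "
                          f"< {min_fraction}",
            }
        )
    drop_keys = set(bad.index)
    mask = [
        (p, t) not in drop_keys
        for p, t in zip(counts["participant"], counts["trial"])
    ]
    return counts[mask].reset_index(drop=True), report


def distraction_ratio(counts: pd.DataFrame) -> pd.DataFrame:
    """Add d, d_flr and validity flags to a counts table."""
    out = counts.copy()
    nF = out["nF"].to_numpy(dtype=float)
    nL = out["nL"].to_numpy(dtype=float)
    nR = out["nR"].to_numpy(dtype=float)
    nN = out["nN"].to_numpy(dtype=float)
    total = nF + nL + nR + nN
    flr = nF + nL + nR
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(total > 0, (nL + nR) / total, np.nan)
        d_flr = np.where(flr > 0, (nL + nR) / flr, np.nan)
    out["d"] = d
    out["d_flr"] = d_flr
    out["valid"] = total > 0
    out["d_flr_defined"] = flr > 0
    return out


def aggregate_participant(records: pd.DataFrame) -> pd.Series:
    """Unweighted mean of valid d(p,s,t) per participant -> d(p).

    Participants with no valid record are omitted with a warning.
    """
    valid = records[records["valid"]]
    dropped = set(records["participant"]) - set(valid["participant"])
    if dropped:
        warnings.warn(
            f"participants without any valid record omitted: {sorted(dropped)}",
            stacklevel=2,
        )
    return valid.groupby("participant")["d"].mean()


def per_emotion_flr(records: pd.DataFrame) -> pd.DataFrame:
    """Mean defined d_flr per (participant, trial, true emotion)."""
    defined = records[records["d_flr_defined"]]
    return (
        defined.groupby(["participant", "trial", "true_emotion"])["d_flr"]
        .mean()
        .reset_index()
    )


def group_ttest(
    values_asd,
    values_nc,
    equal_var: bool = False,
) -> dict:
    """One-tailed two-sample t-test with alternative ASD mean > NC mean."""
    a = np.asarray(values_asd, dtype=float)
    b = np.asarray(values_nc, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    result = {
        "mean_asd": float(a.mean()),
        "sd_asd": float(a.std(ddof=1)),
        "mean_nc": float(b.mean()),
        "sd_nc": float(b.std(ddof=1)),
        "n_asd": len(a),
        "n_nc": len(b),
        "alternative": "greater",
        "equal_var": equal_var,
        "degenerate": False,
    }
    if a.std() == 0 and b.std() == 0:
        result.update(
            t=0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean()),
            p=0.5 if a.mean() == b.mean() else (0.0 if a.mean() > b.mean() else 1.0),
            degenerate=True,
        )
        return result
    t, p = stats.ttest_ind(a, b, equal_var=equal_var, alternative="greater")
    result.update(t=float(t), p=float(p))
    return result
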