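"""Feature construction for the diagnosis classifier.

Four families per trial, giving 49 + S + 3S + 2 = 4S + 51 columns for a
trial of S stimuli (219 for S = 42):

- ``cm`` (49): the flattened row-normalized 7x7 emotion confusion matrix of
  the participant's responses over the trial; all-zero rows (emotion absent
  from the trial) stay zero and are flagged;
- ``conf`` (S): one binary correctness value per stimulus in presentation
  order;
- ``gaze`` (3S): per stimulus, the fraction of frames on the face versus
  the distractors (N excluded), the fraction of distinct-code gaze
  transitions directed toward the face, and the number of frames elapsed
  before first looking at the face (window length when the face is never
  fixated);
- ``pat`` (2): age in years and gender (male = 0, female = 1).

Undefined gaze cells are left as NaN; imputation is deliberately deferred
to the classifier, which fills them with training-fold medians to avoid
leakage across cross-validation folds.  When feature tables are
concatenated across trials, ``pat`` appears once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from gazephen import EMOTIONS
from gazephen.synth.cohort import Participant
from gazephen.synth.schedule import StimulusSchedule

FAMILIES = ("pat", "gaze", "cm", "conf")


def confusion_matrix_features(responses: pd.DataFrame) -> pd.Series:
    """49 row-normalized confusion-matrix entries, named cm_<true>_<resp>."""
    idx = {e: i for i, e in enumerate(EMOTIONS)}
    counts = np.zeros((7, 7))
    for true, resp in zip(responses["true_emotion"], responses["response"]):
        if true not in idx:
            raise ValueError(f"unknown true emotion {true!r}")
        if resp not in idx:
            raise ValueError(f"unknown response {resp!r}")
        counts[idx[true], idx[resp]] += 1
    sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        norm = np.where(sums > 0, counts / np.where(sums == 0, 1, sums), 0.0)
    names = [f"cm_{r}_{c}" for r in EMOTIONS for c in EMOTIONS]
    out = pd.Series(norm.ravel(), index=names)
    out.attrs["zero_rows"] = [EMOTIONS[i] for i in np.flatnonzero(sums.ravel() == 0)]
    return out


def confusion_detail_features(responses: pd.DataFrame) -> pd.Series:
    """S binary correctness values in stimulus presentation order."""
    if responses[["true_emotion", "response"]].isna().any().any():
        raise ValueError("missing response: responses must be complete")
    correct = (
        responses["true_emotion"].to_numpy() == responses["response"].to_numpy()
    ).astype(float)
    names = [f"conf_s{i + 1:02d}" for i in range(len(correct))]
    return pd.Series(correct, index=names)


def gaze_features_for_stimulus(
    codes: np.ndarray, window_frames: int
) -> tuple[float, float, float]:
    """(face_frac, toward_face_frac, latency) from one coded frame sequence.

    ``codes`` holds the retained frames of the stimulus window in temporal
    order.  face_frac = nF / (nF + nL + nR); toward_face_frac counts
    transitions between distinct consecutive codes (N included) whose
    destination is F, over all distinct-code transitions; latency is the
    index of the first F frame, or ``window_frames`` when F never occurs.
    Undefined values are NaN.
    """
    codes = np.asarray(codes, dtype="<U1")
    n_f = int((codes == "F").sum())
    n_l = int((codes == "L").sum())
    n_r = int((codes == "R").sum())
    denom = n_f + n_l + n_r
    face_frac = n_f / denom if denom > 0 else np.nan
    if len(codes) >= 2:
        changed = codes[1:] != codes[:-1]
        n_trans = int(changed.sum())
        toward = int((changed & (codes[1:] == "F")).sum())
        toward_face = toward / n_trans if n_trans > 0 else np.nan
    else:
        toward_face = np.nan
    f_idx = np.flatnonzero(codes == "F")
    latency = float(f_idx[0]) if len(f_idx) else float(window_frames)
    return face_frac, toward_face, latency


def gaze_features(
    stimulus_codes: list[np.ndarray],
    window_frames: int | list[int],
) -> pd.Series:
    """3 values per stimulus: gaze_s<idx>_{facefrac, toward, latency}."""
    if np.isscalar(window_frames):
        window_frames = [int(window_frames)] * len(stimulus_codes)
    values = []
    names = []
    for i, (codes, wf) in enumerate(zip(stimulus_codes, window_frames)):
        ff, tf, lat = gaze_features_for_stimulus(codes, wf)
        values += [ff, tf, lat]
        s = f"gaze_s{i + 1:02d}"
        names += [f"{s}_facefrac", f"{s}_toward", f"{s}_latency"]
    return pd.Series(values, index=names)


def metadata_features(participant: Participant) -> pd.Series:
    """Age in years and gender coded male = 0 / female = 1."""
    if participant.age is None or participant.gender not in ("male", "female"):
        raise ValueError("participant must carry age and gender")
    return pd.Series(
        {"pat_age": float(participant.age),
         "pat_gender": 0.0 if participant.gender == "male" else 1.0}
    )


def expected_trial_width(n_stimuli: int) -> int:
    """Per-trial column count 49 + S + 3S + 2 = 4S + 51."""
    return 4 * n_stimuli + 51


def build_trial_features(
    participant: Participant,
    schedule: StimulusSchedule,
    trial_index: int,
    responses: pd.DataFrame,
    stimulus_codes: dict[str, np.ndarray],
) -> dict[str, pd.Series]:
    """Family -> feature Series for one participant-trial.

    ``stimulus_codes`` maps stimulus_id to the retained coded frame sequence
    of that stimulus window; stimuli absent from the map contribute NaN gaze
    features (e.g. an excluded trial).
    """
    trial = next(t for t in schedule.trials if t.trial_index == trial_index)
    resp = responses[responses["trial"] == trial_index]
    resp = resp.set_index("stimulus_id").loc[
        [s.stimulus_id for s in trial.stimuli]
    ].reset_index()
    codes = [
        stimulus_codes.get(s.stimulus_id, np.array([], dtype="<U1"))
        for s in trial.stimuli
    ]
    windows = [s.duration_frames for s in trial.stimuli]
    gaze = gaze_features(codes, windows)
    # stimuli with no retained frames: latency is meaningless, not "never
    # looked"; mark all three features undefined
    for i, c in enumerate(codes):
        if len(c) == 0:
            gaze.iloc[3 * i : 3 * i + 3] = np.nan
    return {
        "cm": confusion_matrix_features(resp),
        "conf": confusion_detail_features(resp),
        "gaze": gaze,
        "pat": metadata_features(participant),
    }


def assemble(
    blocks: dict[str, dict[int, dict[str, pd.Series]]],
    groups: dict[str, str],
    trials: list[int] | None = None,
    families: list[str] | None = None,
) -> pd.DataFrame:
    """Column-wise concatenation into a participant x feature table.

    ``blocks`` maps participant -> trial -> family -> Series.  ``pat`` is
    included once regardless of the trial subset.  Column names are
    ``t<trial>_<family>_<name>`` (``pat_*`` unprefixed).  Participants
    missing every requested trial are dropped with a warning; a participant
    missing some requested trial gets NaN in that trial's columns (filled by
    the classifier's fold-internal imputation).
    """
    import warnings

    if families is None:
        families = list(FAMILIES)
    all_trials = sorted({t for b in blocks.values() for t in b})
    if trials is None:
        trials = all_trials
    unknown = set(families) - set(FAMILIES)
    if unknown:
        raise ValueError(f"unknown families: {sorted(unknown)}")

    rows = {}
    for pid, by_trial in blocks.items():
        if not any(t in by_trial for t in trials):
            warnings.warn(
                f"participant {pid} has no data in trials {trials}; dropped",
                stacklevel=2,
            )
            continue
        pieces = []
        if "pat" in families:
            some_trial = next(t for t in all_trials if t in by_trial)
            pieces.append(by_trial[some_trial]["pat"])
        for t in trials:
            for fam in families:
                if fam == "pat":
                    continue
                if t in by_trial:
                    part = by_trial[t][fam].copy()
                else:
                    ref_pid = next(p for p, b in blocks.items() if t in b)
                    part = pd.Series(
                        np.nan, index=blocks[ref_pid][t][fam].index
                    )
                part.index = [f"t{t}_{n}" for n in part.index]
                pieces.append(part)
        rows[pid] = pd.concat(pieces)
    table = pd.DataFrame(rows).T
    table.insert(0, "group", pd.Series({p: groups[p] for p in table.index}))
    table.index.name = "participant"
    return table


def select_columns(
    table: pd.DataFrame,
    families: list[str],
    trials: list[int] | str = "all",
) -> pd.DataFrame:
    """Subset an assembled table by family and trial for ablations."""
    cols = []
    for c in table.columns:
        if c == "group":
            continue
        if c.startswith("pat_"):
            if "pat" in families:
                cols.append(c)
            continue
        trial_tag, rest = c.split("_", 1)
        fam = rest.split("_", 1)[0]
        t = int(trial_tag[1:])
        if fam in families and (trials == "all" or t in trials):
            cols.append(c)
    return pd.concat([table[["group"]], table[cols]], axis=1)
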