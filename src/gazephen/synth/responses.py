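"""Emotion responses.

One response per stimulus, drawn from the row of the participant's
confusion profile indexed by the true emotion.  On the feedback trial the
correct-response probability is shifted toward 1 by ``feedback_boost``
(p -> p + boost * (1 - p)) and the off-diagonal mass rescaled, emulating the
effect of the device announcing the correct label.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from gazephen import EMOTIONS
from gazephen.synth.cohort import Participant
from gazephen.synth.schedule import StimulusSchedule


def boosted_row(row: np.ndarray, true_idx: int, boost: float) -> np.ndarray:
    """Shift diagonal mass toward 1 by ``boost`` and renormalize the rest."""
    row = np.asarray(row, dtype=float).copy()
    p = row[true_idx]
    p_new = p + boost * (1 - p)
    rest = 1 - p
    if rest > 0:
        row *= (1 - p_new) / rest
    else:
        row[:] = 0.0
    row[true_idx] = p_new
    return row


def simulate_responses(
    participant: Participant,
    schedule: StimulusSchedule,
    feedback_boost: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Responses table: participant, trial, stimulus_id, true_emotion, response."""
    rng = np.random.default_rng(seed)
    idx = {e: i for i, e in enumerate(EMOTIONS)}
    rows = []
    for trial, stim in schedule.iter_stimuli():
        r = idx[stim.true_emotion]
        probs = participant.confusion_profile[r]
        if trial.feedback and feedback_boost > 0:
            probs = boosted_row(probs, r, feedback_boost)
        response = EMOTIONS[rng.choice(len(EMOTIONS), p=probs)]
        rows.append(
            {
                "participant": participant.participant_id,
                "trial": trial.trial_index,
                "stimulus_id": stim.stimulus_id,
                "true_emotion": stim.true_emotion,
                "response": response,
            }
        )
    return pd.DataFrame(rows)
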