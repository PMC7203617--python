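"""Stimulus schedules.

A session consists of three trials of facial stimuli (default sizes 41, 42,
41) shown for 6 s each, with auditory feedback on trial 2 only, and a
central validation dot (5 s) inserted after every block of eight stimuli
within a trial.  Emotions are balanced within each trial up to remainder and
the presentation order is shuffled by the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from gazephen import EMOTIONS

DISTRACTOR_POOL = ("lego", "train", "car")

DEFAULT_TRIAL_SIZES = (41, 42, 41)
STIMULUS_SECONDS = 6.0
DOT_SECONDS = 5.0
DOT_BLOCK = 8  # a validation dot follows every block of this many stimuli


@dataclass(frozen=True)
class Stimulus:
    stimulus_id: str
    true_emotion: str
    onset_frame: int
    duration_frames: int
    left_distractor: str
    right_distractor: str


@dataclass(frozen=True)
class DotEvent:
    start_frame: int
    duration_frames: int

    @property
    def end_frame(self) -> int:
        return self.start_frame + self.duration_frames


@dataclass(frozen=True)
class Trial:
    trial_index: int
    feedback: bool
    stimuli: tuple[Stimulus, ...]


@dataclass(frozen=True)
class StimulusSchedule:
    trials: tuple[Trial, ...]
    frame_rate: float
    dot_events: tuple[DotEvent, ...]
    n_frames: int = field(default=0)

    def iter_stimuli(self):
        for trial in self.trials:
            for stim in trial.stimuli:
                yield trial, stim

    @property
    def n_stimuli(self) -> int:
        return sum(len(t.stimuli) for t in self.trials)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "StimulusSchedule":
        raw = json.loads(text)
        trials = tuple(
            Trial(
                trial_index=t["trial_index"],
                feedback=t["feedback"],
                stimuli=tuple(Stimulus(**s) for s in t["stimuli"]),
            )
            for t in raw["trials"]
        )
        dots = tuple(DotEvent(**d) for d in raw["dot_events"])
        return cls(trials=trials, frame_rate=raw["frame_rate"],
                   dot_events=dots, n_frames=raw["n_frames"])


def _balanced_emotions(n: int, rng: np.random.Generator) -> list[str]:
    """Each emotion appears floor(n/7) or ceil(n/7) times; order shuffled."""
    reps = -(-n // len(EMOTIONS))
    pool = np.array(list(EMOTIONS) * reps)[:n]
    rng.shuffle(pool)
    return list(pool)


def make_schedule(
    trial_sizes: tuple[int, ...] = DEFAULT_TRIAL_SIZES,
    frame_rate: float = 30.0,
    seed: int = 0,
    stimulus_seconds: float = STIMULUS_SECONDS,
    dot_seconds: float = DOT_SECONDS,
) -> StimulusSchedule:
    """Build a session timeline; deterministic given ``seed``.

    Stimuli within a trial are contiguous and non-overlapping; a dot event is
    inserted after every completed block of :data:`DOT_BLOCK` stimuli.  The
    feedback flag is true exactly on trial 2 (when present).
    """
    if not trial_sizes:
        raise ValueError("trial_sizes must be non-empty")
    if frame_rate < 1:
        raise ValueError("frame_rate must be >= 1")
    rng = np.random.default_rng(seed)
    stim_frames = int(round(frame_rate * stimulus_seconds))
    dot_frames = int(round(frame_rate * dot_seconds))

    cursor = 0
    trials: list[Trial] = []
    dots: list[DotEvent] = []
    for t_idx, size in enumerate(trial_sizes, start=1):
        emotions = _balanced_emotions(size, rng)
        stimuli: list[Stimulus] = []
        for s_idx in range(size):
            left, right = rng.choice(DISTRACTOR_POOL, size=2, replace=False)
            stimuli.append(
                Stimulus(
                    stimulus_id=f"t{t_idx}s{s_idx + 1:02d}",
                    true_emotion=emotions[s_idx],
                    onset_frame=cursor,
                    duration_frames=stim_frames,
                    left_distractor=str(left),
                    right_distractor=str(right),
                )
            )
            cursor += stim_frames
            if (s_idx + 1) % DOT_BLOCK == 0:
                dots.append(DotEvent(start_frame=cursor, duration_frames=dot_frames))
                cursor += dot_frames
        trials.append(
            Trial(trial_index=t_idx, feedback=(t_idx == 2), stimuli=tuple(stimuli))
        )
    return StimulusSchedule(
        trials=tuple(trials),
        frame_rate=frame_rate,
        dot_events=tuple(dots),
        n_frames=cursor,
    )
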