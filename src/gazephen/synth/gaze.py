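"""Latent gaze simulation.

Within each stimulus window the participant's gaze target follows a sticky
first-order Markov chain over {F, L, R, N} whose stationary distribution is
set by the participant's latent propensities: distractor mass (L + R) equals
``latent_distraction`` (split evenly), N mass equals ``latent_offtask``, and
the rest is on the face.  The chain restarts from its stationary
distribution at each stimulus onset, so frame-fraction statistics are exact
in expectation regardless of dwell.  During validation-dot events the target
is the screen center.

Emitted world-gaze coordinates are the target-region center plus isotropic
Gaussian noise; N frames emit a uniform point outside all regions (or a
missing value when ``offtask_missing`` is set).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gazephen import GAZE_CODES
from gazephen.geometry import ScreenGeometry
from gazephen.synth.cohort import Participant
from gazephen.synth.schedule import StimulusSchedule

DEFAULT_DWELL = 0.9
DEFAULT_NOISE_SD = 0.01


@dataclass(frozen=True)
class TrueGazeModel:
    """Sticky Markov chain over the four gaze codes."""

    stationary: np.ndarray  # (4,) over F, L, R, N
    dwell: float
    noise_sd: float

    def __post_init__(self) -> None:
        pi = np.asarray(self.stationary, dtype=float)
        if pi.shape != (4,) or not np.isclose(pi.sum(), 1.0, atol=1e-9):
            raise ValueError("stationary must be a length-4 distribution")
        if not 0 <= self.dwell < 1:
            raise ValueError("dwell must be in [0, 1)")

    @property
    def kernel(self) -> np.ndarray:
        """Row-stochastic transition matrix dwell*I + (1-dwell)*1 pi^T."""
        pi = np.asarray(self.stationary, dtype=float)
        return self.dwell * np.eye(4) + (1 - self.dwell) * np.tile(pi, (4, 1))

    @classmethod
    def for_participant(
        cls,
        participant: Participant,
        dwell: float = DEFAULT_DWELL,
        noise_sd: float = DEFAULT_NOISE_SD,
    ) -> "TrueGazeModel":
        d = participant.latent_distraction
        o = participant.latent_offtask
        pi = np.array([1 - d - o, d / 2, d / 2, o])
        return cls(stationary=pi, dwell=dwell, noise_sd=noise_sd)


def _sample_chain(
    rng: np.random.Generator, pi: np.ndarray, dwell: float,
    n_chains: int, length: int,
) -> np.ndarray:
    """States (n_chains, length) of independent stationary-start chains."""
    cum = np.cumsum(pi)
    states = np.empty((n_chains, length), dtype=np.int8)
    states[:, 0] = np.searchsorted(cum, rng.random(n_chains))
    for t in range(1, length):
        resample = rng.random(n_chains) >= dwell
        states[:, t] = states[:, t - 1]
        k = int(resample.sum())
        if k:
            states[resample, t] = np.searchsorted(cum, rng.random(k))
    return states


def _uniform_outside(
    rng: np.random.Generator, geometry: ScreenGeometry, n: int
) -> np.ndarray:
    """Uniform points on the unit square outside every region (rejection)."""
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        batch = rng.random((max(2 * (n - filled), 16), 2))
        inside = np.zeros(len(batch), dtype=bool)
        for rect in geometry.regions.values():
            inside |= rect.contains(batch[:, 0], batch[:, 1])
        keep = batch[~inside]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def simulate_gaze(
    participant: Participant,
    schedule: StimulusSchedule,
    geometry: ScreenGeometry,
    seed: int,
    dwell: float = DEFAULT_DWELL,
    noise_sd: float = DEFAULT_NOISE_SD,
    offtask_missing: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full-session world-gaze stream for one participant.

    Returns ``(gaze, truth)``: ``gaze`` has columns frame, x, y, missing;
    ``truth`` has columns frame, code with the latent per-frame gaze code
    (dot-event frames are targeted at the screen center, which lies inside
    the face region, so their latent code is F).
    """
    model = TrueGazeModel.for_participant(participant, dwell=dwell, noise_sd=noise_sd)
    rng = np.random.default_rng(seed)
    n = schedule.n_frames
    codes = np.full(n, 3, dtype=np.int8)  # N by default (unreached frames)
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    missing = np.zeros(n, dtype=bool)

    stimuli = [s for _, s in schedule.iter_stimuli()]
    dur = stimuli[0].duration_frames
    if any(s.duration_frames != dur for s in stimuli):
        # fall back to per-stimulus chains if durations ever differ
        groups = [[s] for s in stimuli]
    else:
        groups = [stimuli]
    for group in groups:
        states = _sample_chain(rng, model.stationary, model.dwell,
                               len(group), group[0].duration_frames)
        for row, stim in zip(states, group):
            sl = slice(stim.onset_frame, stim.onset_frame + stim.duration_frames)
            codes[sl] = row

    centers = np.array(
        [
            [geometry.face.cx, geometry.face.cy],
            [geometry.left.cx, geometry.left.cy],
            [geometry.right.cx, geometry.right.cy],
            [np.nan, np.nan],
        ]
    )
    on_region = codes < 3
    pts = centers[codes]
    x[on_region] = pts[on_region, 0]
    y[on_region] = pts[on_region, 1]

    n_idx = np.flatnonzero(codes == 3)
    if offtask_missing:
        missing[n_idx] = True
    else:
        outside = _uniform_outside(rng, geometry, len(n_idx))
        x[n_idx] = outside[:, 0]
        y[n_idx] = outside[:, 1]

    # dot events override: target is the screen center (inside the face)
    for dot in schedule.dot_events:
        sl = slice(dot.start_frame, dot.end_frame)
        codes[sl] = 0
        x[sl] = 0.5
        y[sl] = 0.5
        missing[sl] = False

    if noise_sd > 0:
        jitter = rng.normal(0, noise_sd, size=(n, 2))
        emit = ~missing
        x[emit] = x[emit] + jitter[emit, 0]
        y[emit] = y[emit] + jitter[emit, 1]

    frames = np.arange(n)
    gaze = pd.DataFrame({"frame": frames, "x": x, "y": y, "missing": missing})
    truth = pd.DataFrame(
        {"frame": frames, "code": np.array(GAZE_CODES)[codes]}
    )
    return gaze, truth
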