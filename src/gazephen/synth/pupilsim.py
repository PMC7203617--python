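"""Pupil-camera stream synthesis under known calibration ground truth.

A session is partitioned into four calibration epochs (one dedicated
calibration at the start and one after each trial in the protocol).  Each
epoch carries an affine pupil-to-world mapping; consecutive epochs differ by
a small drift, emulating headset slippage.  Pupil coordinates are obtained
by inverting the epoch mapping at each emitted world-gaze point and adding
Gaussian noise.  The generator also emits per-epoch calibration point pairs
(a 3x3 grid of known on-screen targets with their pupil projections), the
material the calibration stage fits on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gazephen.synth.schedule import StimulusSchedule


@dataclass(frozen=True)
class EpochMap:
    """Affine pupil->world mapping active on [start_frame, end_frame)."""

    epoch_id: int
    start_frame: int
    end_frame: int
    matrix: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)

    def world_from_pupil(self, pupil: np.ndarray) -> np.ndarray:
        return np.asarray(pupil) @ np.asarray(self.matrix).T + self.offset

    def pupil_from_world(self, world: np.ndarray) -> np.ndarray:
        m = np.asarray(self.matrix, dtype=float)
        det = np.linalg.det(m)
        if abs(det) < 1e-10:
            raise ValueError(
                f"epoch {self.epoch_id} mapping is not invertible (det={det:.2e})"
            )
        return (np.asarray(world) - self.offset) @ np.linalg.inv(m).T

    def poly_coefficients(self) -> tuple[np.ndarray, np.ndarray]:
        """Coefficients over the degree-1 monomial basis [1, x, y]."""
        m = np.asarray(self.matrix)
        o = np.asarray(self.offset)
        return (
            np.array([o[0], m[0, 0], m[0, 1]]),
            np.array([o[1], m[1, 0], m[1, 1]]),
        )


@dataclass(frozen=True)
class CalibrationGroundTruth:
    epochs: tuple[EpochMap, ...]
    n_frames: int

    def __post_init__(self) -> None:
        cursor = 0
        for e in self.epochs:
            if e.start_frame != cursor:
                raise ValueError("epochs must partition the session")
            cursor = e.end_frame
        if cursor != self.n_frames:
            raise ValueError("epochs must cover the full session")

    def epoch_of(self, frames: np.ndarray) -> np.ndarray:
        """Epoch id per frame."""
        bounds = [e.end_frame for e in self.epochs]
        idx = np.searchsorted(bounds, np.asarray(frames), side="right")
        return np.array([self.epochs[i].epoch_id for i in idx])


def _epoch_boundaries(schedule: StimulusSchedule, n_epochs: int) -> list[int]:
    """Interior boundaries snapped to validation-dot midpoints.

    Mapping switches happen at recalibrations, which the protocol places at
    dots/trial breaks; snapping keeps every stimulus window inside a single
    epoch so the dot-based epoch assignment can recover the truth exactly.
    """
    n = schedule.n_frames
    if len(schedule.trials) == 3 and n_epochs == 4:
        t1_end = schedule.trials[1].stimuli[0].onset_frame
        t2_end = schedule.trials[2].stimuli[0].onset_frame
        raw = [t1_end, t2_end, (t2_end + n) // 2]
    else:
        raw = list(np.linspace(0, n, n_epochs + 1).astype(int)[1:-1])
    mids = np.array(
        [d.start_frame + d.duration_frames // 2 for d in schedule.dot_events]
    )
    if len(mids):
        snapped = []
        for b in raw:
            m = int(mids[np.argmin(np.abs(mids - b))])
            if snapped and m <= snapped[-1]:  # keep boundaries increasing
                m = b
            snapped.append(m)
        raw = snapped
    return [0] + raw + [n]


def make_calibration_truth(
    schedule: StimulusSchedule,
    seed: int = 0,
    n_epochs: int = 4,
    drift: float = 0.03,
    base_scale_jitter: float = 0.1,
) -> CalibrationGroundTruth:
    """Random per-epoch affine maps: near-identity base plus epoch drift."""
    rng = np.random.default_rng(seed)
    bounds = _epoch_boundaries(schedule, n_epochs)
    base = np.eye(2) + rng.uniform(-base_scale_jitter, base_scale_jitter, (2, 2)) * np.array(
        [[1, 0.3], [0.3, 1]]
    )
    base_offset = rng.uniform(-0.05, 0.05, 2)
    epochs = []
    for e in range(n_epochs):
        offset = base_offset + e * rng.uniform(-drift, drift, 2)
        epochs.append(
            EpochMap(
                epoch_id=e + 1,
                start_frame=bounds[e],
                end_frame=bounds[e + 1],
                matrix=base.copy(),
                offset=offset,
            )
        )
    return CalibrationGroundTruth(epochs=tuple(epochs), n_frames=schedule.n_frames)


def simulate_pupil(
    gaze: pd.DataFrame,
    truth: CalibrationGroundTruth,
    pupil_noise: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Invert each epoch mapping at the emitted world-gaze coordinates.

    Frames with missing gaze emit missing pupil values.  Raises if any epoch
    mapping is not invertible.
    """
    frames = gaze["frame"].to_numpy()
    if frames.min() < 0 or frames.max() >= truth.n_frames:
        raise ValueError("gaze frames fall outside the calibration epochs")
    rng = np.random.default_rng(seed)
    world = gaze[["x", "y"]].to_numpy(dtype=float)
    pupil = np.full_like(world, np.nan)
    missing = gaze["missing"].to_numpy(dtype=bool)
    for e in truth.epochs:
        in_epoch = (frames >= e.start_frame) & (frames < e.end_frame) & ~missing
        if in_epoch.any():
            pupil[in_epoch] = e.pupil_from_world(world[in_epoch])
    if pupil_noise > 0:
        pupil[~missing] += rng.normal(0, pupil_noise, size=(int((~missing).sum()), 2))
    return pd.DataFrame(
        {
            "frame": frames,
            "x": pupil[:, 0],
            "y": pupil[:, 1],
            "missing": missing,
        }
    )


def calibration_point_pairs(
    truth: CalibrationGroundTruth,
    grid_n: int = 3,
    pupil_noise: float = 0.0,
    seed: int = 0,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Per-epoch (pupil, world) pairs from a grid of known screen targets."""
    rng = np.random.default_rng(seed)
    ticks = np.linspace(0.15, 0.85, grid_n)
    gx, gy = np.meshgrid(ticks, ticks)
    world = np.column_stack([gx.ravel(), gy.ravel()])
    pairs = {}
    for e in truth.epochs:
        pupil = e.pupil_from_world(world)
        if pupil_noise > 0:
            pupil = pupil + rng.normal(0, pupil_noise, pupil.shape)
        pairs[e.epoch_id] = (pupil, world.copy())
    return pairs
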