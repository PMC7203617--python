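"""Polynomial pupil-to-world calibration.

Each calibration epoch yields a separate bivariate polynomial regression
from eye-camera pupil coordinates to world-gaze (screen) coordinates: one
least-squares fit per output axis over the full monomial basis up to the
requested total degree (default 2).  Epoch applicability over the session is
decided automatically from the validation-dot events: each inter-dot
segment is assigned the candidate model whose median prediction error
against the central dot target — over the dot windows adjacent to the
segment — is smallest, or no model when even the best error exceeds a
geometry-derived threshold (half the face half-width, beyond which face and
distractor cannot be told apart).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gazephen.synth.schedule import DotEvent

DOT_TARGET = (0.5, 0.5)
# default "none" threshold: half the face-region half-width (0.49 / 4)
NONE_THRESHOLD = 0.49 / 4


def monomial_basis(points: np.ndarray, degree: int) -> np.ndarray:
    """Design matrix of bivariate monomials x^i y^j with i + j <= degree.

    Column order: (0,0), (1,0), (0,1), (2,0), (1,1), (0,2), ...
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x, y = pts[:, 0], pts[:, 1]
    cols = [
        x**i * y**(d - i)
        for d in range(degree + 1)
        for i in range(d, -1, -1)
    ]
    return np.column_stack(cols)


def n_coefficients(degree: int) -> int:
    return (degree + 1) * (degree + 2) // 2


@dataclass(frozen=True)
class CalibrationModel:
    epoch_id: int
    degree: int
    coef_x: np.ndarray
    coef_y: np.ndarray
    fit_residual: float
    n_points: int


@dataclass(frozen=True)
class EpochAssignment:
    """Disjoint, ordered frame intervals with an epoch id or None each."""

    intervals: tuple[tuple[int, int, int | None], ...]

    def __post_init__(self) -> None:
        prev_end = None
        for start, end, _ in self.intervals:
            if end <= start:
                raise ValueError("empty interval")
            if prev_end is not None and start != prev_end:
                raise ValueError("intervals must be contiguous and ordered")
            prev_end = end

    def epoch_of(self, frames: np.ndarray) -> np.ndarray:
        """Epoch id per frame (-1 encodes 'none')."""
        frames = np.asarray(frames)
        out = np.full(frames.shape, -1, dtype=int)
        for start, end, eid in self.intervals:
            sel = (frames >= start) & (frames < end)
            out[sel] = -1 if eid is None else eid
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.intervals, columns=["start_frame", "end_frame", "epoch_id"]
        )


def fit_calibration(
    pupil: np.ndarray,
    world: np.ndarray,
    degree: int = 2,
    epoch_id: int = 0,
) -> CalibrationModel:
    """Per-axis least squares over the full monomial basis up to ``degree``."""
    pupil = np.atleast_2d(np.asarray(pupil, dtype=float))
    world = np.atleast_2d(np.asarray(world, dtype=float))
    if pupil.shape != world.shape or pupil.shape[1] != 2:
        raise ValueError("pupil and world must be matching (n, 2) arrays")
    if not (np.isfinite(pupil).all() and np.isfinite(world).all()):
        raise ValueError("calibration pairs must be finite")
    k = n_coefficients(degree)
    if len(pupil) < k:
        raise ValueError(
            f"need at least {k} pairs for degree {degree}, got {len(pupil)}"
        )
    design = monomial_basis(pupil, degree)
    rank = np.linalg.matrix_rank(design)
    if rank < k:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {k} coefficients): "
            "pupil points do not span the polynomial basis "
            "(e.g. collinear points)"
        )
    coef, *_ = np.linalg.lstsq(design, world, rcond=None)
    pred = design @ coef
    residual = float(np.sqrt(np.mean(np.sum((pred - world) ** 2, axis=1))))
    return CalibrationModel(
        epoch_id=epoch_id,
        degree=degree,
        coef_x=coef[:, 0].copy(),
        coef_y=coef[:, 1].copy(),
        fit_residual=residual,
        n_points=len(pupil),
    )


def predict_world(model: CalibrationModel, pupil: np.ndarray) -> np.ndarray:
    """Evaluate both axis polynomials; output may lie outside the screen."""
    pupil = np.atleast_2d(np.asarray(pupil, dtype=float))
    if not np.isfinite(pupil).all():
        raise ValueError("pupil coordinates must be finite")
    design = monomial_basis(pupil, model.degree)
    return np.column_stack([design @ model.coef_x, design @ model.coef_y])


def _dot_frame_mask(frames: np.ndarray, dots: list[DotEvent]) -> np.ndarray:
    mask = np.zeros(len(frames), dtype=bool)
    for d in dots:
        mask |= (frames >= d.start_frame) & (frames < d.end_frame)
    return mask


def dot_residuals(
    model: CalibrationModel,
    pupil: pd.DataFrame,
    dot_events: list[DotEvent],
    dot_target: tuple[float, float] = DOT_TARGET,
) -> dict:
    """Per-dot median and overall median/mean prediction error at the dots."""
    if not dot_events:
        raise ValueError("dot_events must be non-empty")
    frames = pupil["frame"].to_numpy()
    coords = pupil[["x", "y"]].to_numpy(dtype=float)
    ok = np.isfinite(coords).all(axis=1)
    target = np.asarray(dot_target)
    per_dot = []
    all_err: list[np.ndarray] = []
    for d in dot_events:
        sel = (frames >= d.start_frame) & (frames < d.end_frame) & ok
        if not sel.any():
            per_dot.append(np.nan)
            continue
        err = np.linalg.norm(predict_world(model, coords[sel]) - target, axis=1)
        per_dot.append(float(np.median(err)))
        all_err.append(err)
    pooled = np.concatenate(all_err) if all_err else np.array([np.nan])
    return {
        "per_dot_median": per_dot,
        "median": float(np.nanmedian(pooled)),
        "mean": float(np.nanmean(pooled)),
        "n_frames": int(sum(len(e) for e in all_err)),
    }


def assign_epochs(
    pupil: pd.DataFrame,
    models: list[CalibrationModel],
    dot_events: list[DotEvent],
    dot_target: tuple[float, float] = DOT_TARGET,
    threshold: float = NONE_THRESHOLD,
    n_frames: int | None = None,
) -> EpochAssignment:
    """Assign each inter-dot segment the model that best predicts the dots.

    Segments are delimited by dot-event midpoints (so every frame, including
    dot frames, belongs to exactly one segment, and each segment contains
    the near half of each adjacent dot window).  A segment's score for a
    model is the median prediction error against ``dot_target`` over the dot
    frames the segment contains; the best model wins unless its score
    exceeds ``threshold``, in which case the segment is assigned None.
    """
    if not models:
        raise ValueError("at least one model required")
    frames = pupil["frame"].to_numpy()
    total = int(n_frames if n_frames is not None else frames.max() + 1)
    if not dot_events:
        warnings.warn(
            "no dot events: assigning the lowest-fit-residual model to the "
            "whole session", stacklevel=2,
        )
        best = min(models, key=lambda m: m.fit_residual)
        return EpochAssignment(intervals=((0, total, best.epoch_id),))

    dots = sorted(dot_events, key=lambda d: d.start_frame)
    mids = [d.start_frame + d.duration_frames // 2 for d in dots]
    boundaries = [0] + mids + [total]
    coords = pupil[["x", "y"]].to_numpy(dtype=float)
    ok = np.isfinite(coords).all(axis=1)
    target = np.asarray(dot_target)
    in_dot = np.zeros(len(frames), dtype=bool)
    for d in dots:
        in_dot |= (frames >= d.start_frame) & (frames < d.end_frame)

    intervals: list[tuple[int, int, int | None]] = []
    for start, end in zip(boundaries, boundaries[1:]):
        sel = in_dot & ok & (frames >= start) & (frames < end)
        if not sel.any():
            eid = None
        else:
            pts = coords[sel]
            scores = np.array([
                np.median(np.linalg.norm(predict_world(m, pts) - target, axis=1))
                for m in models
            ])
            mi = int(np.argmin(scores))
            eid = models[mi].epoch_id if scores[mi] <= threshold else None
        intervals.append((start, end, eid))
    return EpochAssignment(intervals=tuple(intervals))
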