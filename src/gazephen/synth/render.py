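"""Synthetic eye-camera frames.

Each frame is a bright iris/sclera field with a dark pupil disk at the
scaled pupil coordinate, a softened 1-pixel edge, and optional additive
Gaussian noise.  Ground-truth centers in pixel coordinates are returned
alongside the frames for detector validation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BACKGROUND = 0.85
PUPIL_DEPTH = 0.75  # background minus pupil intensity


def render_eye_frames(
    pupil: pd.DataFrame,
    image_size: tuple[int, int] = (48, 64),
    pupil_radius: float = 6.0,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render frames (n, h, w) in [0, 1] plus ground-truth centers (n, 2).

    ``pupil`` carries normalized coordinates in [0, 1]^2; they are scaled
    into the image with a margin so the disk stays inside.  Centers are
    (x, y) pixel coordinates; rows with missing pupil render a blank frame
    and a NaN center.
    """
    h, w = image_size
    if pupil_radius >= min(h, w) / 2:
        raise ValueError("pupil_radius must be smaller than half the image side")
    rng = np.random.default_rng(seed)
    margin = pupil_radius + 2
    xs = pupil["x"].to_numpy(dtype=float)
    ys = pupil["y"].to_numpy(dtype=float)
    missing = pupil["missing"].to_numpy(dtype=bool) | ~np.isfinite(xs) | ~np.isfinite(ys)
    cx = margin + np.clip(xs, 0, 1) * (w - 1 - 2 * margin)
    cy = margin + np.clip(ys, 0, 1) * (h - 1 - 2 * margin)

    yy, xx = np.mgrid[0:h, 0:w]
    frames = np.empty((len(xs), h, w), dtype=float)
    centers = np.column_stack([cx, cy])
    centers[missing] = np.nan
    for i in range(len(xs)):
        img = np.full((h, w), BACKGROUND)
        if not missing[i]:
            dist = np.hypot(xx - cx[i], yy - cy[i])
            # soft-edged disk: full depth inside, linear falloff over 1 px
            mask = np.clip(pupil_radius + 0.5 - dist, 0.0, 1.0)
            img -= PUPIL_DEPTH * mask
        if noise > 0:
            img = img + rng.normal(0, noise, (h, w))
        frames[i] = np.clip(img, 0.0, 1.0)
    return frames, centers
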