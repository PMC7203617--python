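"""Pupil-center detection in eye-camera frames.

Three detectors, mirroring the hybrid approach used for wearable trackers:

- :func:`detect_mser` — maximally stable extremal regions of the *dark*
  (lower-threshold) component tree, implemented as a threshold sweep with an
  area-stability criterion and area/eccentricity gates;
- :func:`detect_gradient` — the means-of-gradients objective: the pupil
  center maximizes the mean squared alignment between displacement
  directions and image gradients, weighted toward dark pixels, evaluated on
  a coarse grid and refined locally with sub-pixel interpolation;
- :func:`propagate_flow` — translation of the previous center by a local
  displacement estimated with windowed phase correlation.

:func:`fuse` combines per-frame candidates: when the gradient estimate and
an MSER candidate agree within a gate radius, their average is returned
(method ``fused``); otherwise the highest-confidence candidate; otherwise
the optical-flow propagation; a frame with no usable candidate is marked
untrackable (confidence 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.measure import label, regionprops
from skimage.registration import phase_cross_correlation

GATE_RADIUS = 4.0  # px agreement gate between gradient and MSER
MSER_MIN_AREA_FRAC = 0.005
MSER_MAX_AREA_FRAC = 0.20
MSER_MAX_ECCENTRICITY = 0.95


@dataclass(frozen=True)
class PupilEstimate:
    frame_index: int
    x: float
    y: float
    confidence: float
    method: str

    def __post_init__(self) -> None:
        if self.confidence > 0 and not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("positive-confidence estimate must carry a center")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x, self.y)


def _no_detection(frame_index: int, method: str) -> PupilEstimate:
    return PupilEstimate(frame_index, math.nan, math.nan, 0.0, method)


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    return image


# ---------------------------------------------------------------- MSER ----

def detect_mser(
    image: np.ndarray,
    frame_index: int = 0,
    n_levels: int = 24,
    delta: int = 2,
    min_area_frac: float = MSER_MIN_AREA_FRAC,
    max_area_frac: float = MSER_MAX_AREA_FRAC,
    max_eccentricity: float = MSER_MAX_ECCENTRICITY,
) -> list[PupilEstimate]:
    """Candidate centers from maximally stable dark extremal regions.

    Thresholds sweep the intensity range; a region at level *i* is scored by
    the relative area growth between levels *i - delta* and *i + delta*
    (smaller is stabler).  Candidates pass area and eccentricity gates and
    are ranked by stability (most stable first); duplicates within the gate
    radius keep only the stabler instance.
    """
    image = _check_image(image)
    lo, hi = float(image.min()), float(image.max())
    if hi - lo < 1e-12:
        return []
    levels = np.linspace(lo, hi, n_levels + 2)[1:-1]
    labelled = [label(image <= lv, connectivity=2) for lv in levels]
    area = image.size
    min_area = max(1, int(min_area_frac * area))
    max_area = int(max_area_frac * area)

    candidates: list[tuple[float, float, float]] = []  # (stability, x, y)
    for i in range(delta, len(levels) - delta):
        for region in regionprops(labelled[i]):
            if not (min_area <= region.area <= max_area):
                continue
            if region.eccentricity > max_eccentricity:
                continue
            ry, rx = region.coords[0]  # any pixel of the region as seed
            lab_lo = labelled[i - delta][ry, rx]
            lab_hi = labelled[i + delta][ry, rx]
            if lab_lo == 0 or lab_hi == 0:
                continue
            area_lo = np.count_nonzero(labelled[i - delta] == lab_lo)
            area_hi = np.count_nonzero(labelled[i + delta] == lab_hi)
            stability = (area_hi - area_lo) / region.area
            cy, cx = region.centroid
            candidates.append((stability, cx, cy))

    candidates.sort(key=lambda c: c[0])
    estimates: list[PupilEstimate] = []
    for stability, cx, cy in candidates:
        if any(np.hypot(e.x - cx, e.y - cy) < GATE_RADIUS for e in estimates):
            continue
        confidence = 1.0 / (1.0 + max(stability, 0.0))
        estimates.append(PupilEstimate(frame_index, cx, cy, confidence, "mser"))
    return estimates


# ------------------------------------------------------------- gradient ----

def detect_gradient(
    image: np.ndarray,
    frame_index: int = 0,
    search_region: tuple[int, int, int, int] | None = None,
    stride: int = 2,
    gradient_quantile: float = 0.95,
    smooth_sigma: float = 2.5,
) -> PupilEstimate:
    """Means-of-gradients pupil localization.

    Keeps the strongest-gradient pixels (top decile by magnitude), evaluates
    the alignment objective — weighted by inverted smoothed intensity at the
    candidate — over a strided pixel grid, then refines around the best cell
    at full resolution with quadratic sub-pixel interpolation.
    """
    image = _check_image(image)
    h, w = image.shape
    smoothed = gaussian_filter(image, smooth_sigma)
    gy, gx = np.gradient(smoothed)
    mag = np.hypot(gx, gy)
    if mag.max() < 1e-12:
        return _no_detection(frame_index, "gradient")
    thresh = np.quantile(mag, gradient_quantile)
    sel = mag >= max(thresh, 1e-12)
    if not sel.any():
        return _no_detection(frame_index, "gradient")
    pyx = np.argwhere(sel)
    py = pyx[:, 0].astype(float)
    px = pyx[:, 1].astype(float)
    ngx = (gx[sel] / mag[sel]).astype(float)
    ngy = (gy[sel] / mag[sel]).astype(float)

    inv = smoothed.max() - smoothed
    rng_span = inv.max() - inv.min()
    weight_img = (inv - inv.min()) / rng_span if rng_span > 0 else np.ones_like(inv)

    if search_region is not None:
        x0, y0, x1, y1 = search_region
        if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
            raise ValueError("search_region outside image bounds")
    else:
        x0, y0, x1, y1 = 0, 0, w, h

    def objective(cxs: np.ndarray, cys: np.ndarray) -> np.ndarray:
        dx = px[None, :] - cxs[:, None]
        dy = py[None, :] - cys[:, None]
        norm = np.hypot(dx, dy)
        norm[norm < 1e-9] = 1e-9
        dot = (dx * ngx[None, :] + dy * ngy[None, :]) / norm
        align = np.mean(np.clip(dot, 0, None) ** 2, axis=1)
        wvals = weight_img[
            np.clip(np.round(cys).astype(int), 0, h - 1),
            np.clip(np.round(cxs).astype(int), 0, w - 1),
        ]
        return wvals * align

    grid_y, grid_x = np.mgrid[y0:y1:stride, x0:x1:stride]
    gxs = grid_x.ravel().astype(float)
    gys = grid_y.ravel().astype(float)
    scores = objective(gxs, gys)
    best = int(np.argmax(scores))
    bx, by = gxs[best], gys[best]

    # full-resolution refinement in a small neighbourhood
    rx0, rx1 = max(x0, int(bx) - stride - 1), min(x1, int(bx) + stride + 2)
    ry0, ry1 = max(y0, int(by) - stride - 1), min(y1, int(by) + stride + 2)
    fy, fx = np.mgrid[ry0:ry1, rx0:rx1]
    fxs = fx.ravel().astype(float)
    fys = fy.ravel().astype(float)
    fscores = objective(fxs, fys).reshape(fy.shape)
    fi = np.unravel_index(np.argmax(fscores), fscores.shape)
    cx = float(fxs.reshape(fy.shape)[fi])
    cy = float(fys.reshape(fy.shape)[fi])
    score = float(fscores[fi])

    # quadratic sub-pixel interpolation along each axis
    iy, ix = fi
    if 0 < ix < fscores.shape[1] - 1:
        l, c, r = fscores[iy, ix - 1], fscores[iy, ix], fscores[iy, ix + 1]
        denom = l - 2 * c + r
        if abs(denom) > 1e-12:
            cx += float(np.clip(0.5 * (l - r) / denom, -0.5, 0.5))
    if 0 < iy < fscores.shape[0] - 1:
        u, c, d = fscores[iy - 1, ix], fscores[iy, ix], fscores[iy + 1, ix]
        denom = u - 2 * c + d
        if abs(denom) > 1e-12:
            cy += float(np.clip(0.5 * (u - d) / denom, -0.5, 0.5))

    confidence = float(np.clip(score, 0.0, 1.0))
    if confidence <= 0:
        return _no_detection(frame_index, "gradient")
    return PupilEstimate(frame_index, cx, cy, confidence, "gradient")


# ----------------------------------------------------------------- flow ----

def propagate_flow(
    prev_image: np.ndarray,
    prev_center: PupilEstimate,
    image: np.ndarray,
    frame_index: int | None = None,
    window: int = 24,
) -> PupilEstimate:
    """Translate the previous center by a windowed phase-correlation shift."""
    if prev_center.confidence <= 0:
        raise ValueError("propagate_flow requires a previous center with confidence > 0")
    prev_image = _check_image(prev_image)
    image = _check_image(image)
    if prev_image.shape != image.shape:
        raise ValueError("frame shapes differ")
    h, w = image.shape
    if frame_index is None:
        frame_index = prev_center.frame_index + 1
    half = window // 2
    cx0 = int(round(prev_center.x))
    cy0 = int(round(prev_center.y))
    x0 = np.clip(cx0 - half, 0, max(w - window, 0))
    y0 = np.clip(cy0 - half, 0, max(h - window, 0))
    x1 = min(x0 + window, w)
    y1 = min(y0 + window, h)
    ref = prev_image[y0:y1, x0:x1]
    mov = image[y0:y1, x0:x1]
    if ref.size == 0 or ref.std() < 1e-12:
        return _no_detection(frame_index, "flow")
    try:
        shift, error, _ = phase_cross_correlation(ref, mov, upsample_factor=10)
    except Exception:
        return _no_detection(frame_index, "flow")
    # shift registers `mov` onto `ref`: content moved by -shift, so the
    # center moved by -shift (row, col) -> (dy, dx)
    dy, dx = -shift
    nx = float(prev_center.x + dx)
    ny = float(prev_center.y + dy)
    if not (0 <= nx <= w - 1 and 0 <= ny <= h - 1):
        return _no_detection(frame_index, "flow")
    confidence = float(prev_center.confidence * np.clip(1.0 - error, 0.0, 1.0))
    if confidence <= 0:
        return _no_detection(frame_index, "flow")
    return PupilEstimate(frame_index, nx, ny, confidence, "flow")


# ----------------------------------------------------------------- fuse ----

def fuse(
    candidates: list[PupilEstimate],
    prev: PupilEstimate | None = None,
    gate_radius: float = GATE_RADIUS,
) -> PupilEstimate:
    """Combine per-frame candidates into a single estimate."""
    frame_index = candidates[0].frame_index if candidates else (
        prev.frame_index + 1 if prev is not None else 0
    )
    live = [c for c in candidates if c.confidence > 0]
    gradient = next((c for c in live if c.method == "gradient"), None)
    msers = [c for c in live if c.method == "mser"]
    flow = next((c for c in live if c.method == "flow"), None)

    if gradient is not None and msers:
        agreeing = [
            m for m in msers
            if np.hypot(m.x - gradient.x, m.y - gradient.y) <= gate_radius
        ]
        if agreeing:
            m = max(agreeing, key=lambda c: c.confidence)
            conf = min(1.0, 0.5 * (gradient.confidence + m.confidence) + 0.25)
            return PupilEstimate(
                frame_index,
                0.5 * (gradient.x + m.x),
                0.5 * (gradient.y + m.y),
                conf,
                "fused",
            )
    non_flow = [c for c in live if c.method != "flow"]
    if non_flow:
        return max(non_flow, key=lambda c: c.confidence)
    if flow is not None:
        return flow
    return _no_detection(frame_index, "fused")


def track_frames(
    frames: np.ndarray,
    method: str = "fused",
) -> pd.DataFrame:
    """Run a detector over a frame stack; returns frame, x, y, confidence, method.

    ``method`` is one of fused, gradient, mser, flow.  The flow-only mode
    bootstraps its first frame with the gradient detector.
    """
    rows = []
    prev_est: PupilEstimate | None = None
    prev_img: np.ndarray | None = None
    for i, img in enumerate(frames):
        if method == "gradient":
            est = detect_gradient(img, frame_index=i)
        elif method == "mser":
            cands = detect_mser(img, frame_index=i)
            est = cands[0] if cands else _no_detection(i, "mser")
        elif method == "flow":
            if prev_est is None or prev_est.confidence <= 0:
                est = detect_gradient(img, frame_index=i)
            else:
                est = propagate_flow(prev_img, prev_est, img, frame_index=i)
        elif method == "fused":
            cands = detect_mser(img, frame_index=i)
            cands.append(detect_gradient(img, frame_index=i))
            if prev_est is not None and prev_est.confidence > 0:
                cands.append(propagate_flow(prev_img, prev_est, img, frame_index=i))
            est = fuse(cands, prev=prev_est)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append(
            {
                "frame": i,
                "x": est.x,
                "y": est.y,
                "confidence": est.confidence,
                "method": est.method,
            }
        )
        prev_est = est if est.confidence > 0 else prev_est
        prev_img = img
    return pd.DataFrame(rows)
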