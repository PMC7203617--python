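"""Screen layout of the stimulus display.

All coordinates are normalized to [0, 1] x [0, 1] with the origin at the
top-left corner, x increasing rightward and y downward.  The display holds a
central facial stimulus flanked by two non-social distractor images; the
region sizes follow the study layout (face ~49% x 87% of the screen,
distractors ~17% x 31%) with regions vertically centered and the distractors
horizontally centered in the strips left and right of the face.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle given by center, width and height."""

    cx: float
    cy: float
    width: float
    height: float

    @property
    def x0(self) -> float:
        return self.cx - self.width / 2

    @property
    def x1(self) -> float:
        return self.cx + self.width / 2

    @property
    def y0(self) -> float:
        return self.cy - self.height / 2

    @property
    def y1(self) -> float:
        return self.cy + self.height / 2

    def contains(self, x, y):
        """Boundary-inclusive membership test (vectorized)."""
        x = np.asarray(x)
        y = np.asarray(y)
        return (
            (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)
        )

    def overlaps(self, other: "Rect") -> bool:
        return not (
            self.x1 < other.x0
            or other.x1 < self.x0
            or self.y1 < other.y0
            or other.y1 < self.y0
        )


@dataclass(frozen=True)
class ScreenGeometry:
    """Face and distractor regions on the normalized screen."""

    face: Rect
    left: Rect
    right: Rect

    def __post_init__(self) -> None:
        regions = {"face": self.face, "left": self.left, "right": self.right}
        for name, r in regions.items():
            if not (0 <= r.x0 and r.x1 <= 1 and 0 <= r.y0 and r.y1 <= 1):
                raise ValueError(f"region {name!r} extends outside the unit square")
        pairs = [("face", "left"), ("face", "right"), ("left", "right")]
        for a, b in pairs:
            if regions[a].overlaps(regions[b]):
                raise ValueError(f"regions {a!r} and {b!r} overlap")

    @property
    def regions(self) -> dict[str, Rect]:
        return {"F": self.face, "L": self.left, "R": self.right}


# Default layout: face region sizes from the study protocol; distractors sit
# centered in the vertical strips remaining on each side of the face.
_FACE_W, _FACE_H = 0.49, 0.87
_DIST_W, _DIST_H = 0.17, 0.31
_STRIP_W = (1 - _FACE_W) / 2


def default_geometry() -> ScreenGeometry:
    return ScreenGeometry(
        face=Rect(0.5, 0.5, _FACE_W, _FACE_H),
        left=Rect(_STRIP_W / 2, 0.5, _DIST_W, _DIST_H),
        right=Rect(1 - _STRIP_W / 2, 0.5, _DIST_W, _DIST_H),
    )
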