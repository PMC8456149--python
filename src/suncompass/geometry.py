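"""Fly-silhouette geometry shared by the renderer and the tracker.

A tethered fly seen from below is modelled as the union of an ellipse over
the abdomen and a circle over the thorax. The tether point (rotation
centre) is the thorax-circle centre; the abdomen trails behind it along
the body axis, which is what makes the silhouette head/tail asymmetric and
lets a rotation search resolve the 180-degree ambiguity.

Image convention: origin top-left, x = column, y = row. Body angles are
measured clockwise from image-up, so a heading of 0 points the thorax->head
axis up the image and the abdomen hangs below the tether point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BodyShape", "silhouette_mask"]


@dataclass(frozen=True)
class BodyShape:
    """Silhouette dimensions in pixels.

    ``ellipse_a``/``ellipse_b`` are the abdomen semi-axes (a along the body
    axis), ``circle_r`` the thorax radius and ``offset`` the distance from
    the thorax centre back to the abdomen centre.
    """

    ellipse_a: float = 14.0
    ellipse_b: float = 6.0
    circle_r: float = 7.0
    offset: float = 16.0

    def __post_init__(self):
        if min(self.ellipse_a, self.ellipse_b, self.circle_r) <= 0:
            raise ValueError("shape dimensions must be positive")
        if self.offset < 0:
            raise ValueError("offset must be non-negative")
        if self.offset > self.ellipse_a + self.circle_r:
            raise ValueError(
                "ellipse and circle are disjoint: offset exceeds "
                "ellipse_a + circle_r (the body must be connected)"
            )

    @property
    def max_extent(self) -> float:
        """Largest distance from the rotation centre to any silhouette pixel."""
        return max(self.offset + self.ellipse_a, self.circle_r, self.ellipse_b)


def silhouette_mask(
    shape_hw: tuple[int, int],
    centre_xy: tuple[float, float],
    body: BodyShape,
    angle_deg: float,
) -> np.ndarray:
    """Rasterize the ellipse-union-circle silhouette at a body angle.

    Returns a boolean (H, W) mask sampled at pixel centres. The silhouette
    must fit inside the image at every rotation.
    """
    h, w = shape_hw
    cx, cy = centre_xy
    ext = body.max_extent
    if cx - ext < -0.5 or cy - ext < -0.5 or cx + ext > w - 0.5 or cy + ext > h - 0.5:
        raise ValueError("silhouette would exceed image bounds at some rotation")

    rad = np.deg2rad(angle_deg)
    # heading unit vector in image coords (y grows downward)
    ex, ey = np.sin(rad), -np.cos(rad)

    ys, xs = np.mgrid[0:h, 0:w]
    xs = xs.astype(float)
    ys = ys.astype(float)

    circle = (xs - cx) ** 2 + (ys - cy) ** 2 <= body.circle_r**2

    # abdomen centre sits behind the thorax along the body axis
    ax_c = cx - body.offset * ex
    ay_c = cy - body.offset * ey
    dx, dy = xs - ax_c, ys - ay_c
    s = dx * ex + dy * ey        # along-axis coordinate
    t = -dx * ey + dy * ex       # across-axis coordinate
    ellipse = (s / body.ellipse_a) ** 2 + (t / body.ellipse_b) ** 2 <= 1.0

    return circle | ellipse
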