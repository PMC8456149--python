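"""Body-orientation tracking by exhaustive rotation-search kernel matching.

The user defines the fly's silhouette on one frame as an ellipse (abdomen)
unified with a circle (thorax). That union is the kernel; for every frame
the kernel is rasterized at all 360 integer rotations about the tether
point and scored against the contrast-enhanced frame by normalized
cross-correlation (Pearson correlation between the binary kernel raster
and the inverted frame, so a dark body on a light background scores
positively). The reported angle is the argmax, to the nearest degree, with
ties broken toward the previous frame's angle to avoid jitter flips.

Because the abdomen trails the tether point the kernel is head/tail
asymmetric; frames where the scores at theta and theta+180 are nearly
equal are flagged as ambiguous, as are frames with no usable contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import BodyShape, silhouette_mask
from .circstats import wrap180

__all__ = [
    "FrameStack",
    "BodyKernel",
    "TrackedSeries",
    "enhance_contrast",
    "build_kernel",
    "match_angle",
    "track_stack",
]

# minimum score ratio between best angle and its antipode before the
# head/tail assignment is considered unambiguous
AMBIGUITY_RATIO = 1.02
# Pearson score below which a match is flagged low-confidence
LOW_CONFIDENCE_SCORE = 0.2


@dataclass
class FrameStack:
    """An ordered stack of 8-bit grayscale frames with timing metadata.

    ``calibration_offset_deg`` maps image-up to compass north: compass
    angle = image angle + offset.
    """

    frames: np.ndarray
    rate_hz: float
    timestamps: np.ndarray | None = None
    calibration_offset_deg: float = 0.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) array")
        if self.timestamps is None:
            self.timestamps = np.arange(len(self.frames)) / self.rate_hz
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.timestamps) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if len(self.frames) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self):
        return len(self.frames)


@dataclass
class BodyKernel:
    """Rasterized ellipse-union-circle silhouette used for rotation search.

    ``mask`` is the silhouette at ``reference_angle_deg`` (the thorax->head
    axis angle in the mask, measured clockwise from image-up);
    ``centre_xy`` is the rotation centre (tether point, thorax centre).
    The parametric shape is kept so rotated rasters are regenerated
    analytically rather than by image resampling.
    """

    mask: np.ndarray
    centre_xy: tuple[float, float]
    reference_angle_deg: float
    body: BodyShape
    _bank: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("kernel mask is empty")

    def rotated(self, angle_deg: float) -> np.ndarray:
        """Silhouette mask with the body axis at ``angle_deg``."""
        return silhouette_mask(self.mask.shape, self.centre_xy, self.body, angle_deg)

    def _rotation_bank(self) -> np.ndarray:
        """(360, H*W) matrix of centred, unit-norm rotated masks."""
        if self._bank is None:
            h, w = self.mask.shape
            bank = np.empty((360, h * w), dtype=np.float32)
            for a in range(360):
                m = self.rotated(float(a)).astype(np.float32).ravel()
                m -= m.mean()
                norm = np.linalg.norm(m)
                bank[a] = m / norm if norm > 0 else m
            self._bank = bank
        return self._bank


def enhance_contrast(frame: np.ndarray, clip_fraction: float = 0.05) -> np.ndarray:
    """Saturate the brightest pixels, then rescale to [0, 255].

    Emulates the manual step of lowering the display maximum until
    background detail disappears: intensities above the (1 - clip_fraction)
    quantile are clipped to it before a min-max rescale. With
    ``clip_fraction`` at least the background's pixel fraction the
    background saturates to a flat level; the default 0.05 is a gentle
    denoising clip. Ordering of intensities below the clip point is
    preserved.
    """
    if not 0.0 <= clip_fraction < 1.0:
        raise ValueError("clip_fraction must lie in [0, 1)")
    f = np.asarray(frame, dtype=float)
    if f.size == 0:
        raise ValueError("empty frame")
    hi = np.quantile(f, 1.0 - clip_fraction)
    lo = f.min()
    clipped = np.minimum(f, hi)
    if hi - lo < 1e-12:
        return np.zeros_like(f)
    return (clipped - lo) * (255.0 / (hi - lo))


def build_kernel(
    ellipse: tuple[float, float],
    circle_r: float,
    offset: float,
    image_shape: tuple[int, int],
    centre_xy: tuple[float, float] | None = None,
    reference_angle_deg: float = 0.0,
) -> BodyKernel:
    """Build the matching kernel from the two user-drawn shapes.

    ``ellipse`` gives the abdomen semi-axes (along-axis, across-axis),
    ``circle_r`` the thorax radius and ``offset`` the distance between the
    two shape centres. The shapes must overlap or touch (a connected
    body); the rotation centre defaults to the thorax-circle centre at the
    image centre.
    """
    body = BodyShape(
        ellipse_a=ellipse[0], ellipse_b=ellipse[1], circle_r=circle_r, offset=offset
    )
    h, w = image_shape
    if centre_xy is None:
        centre_xy = ((w - 1) / 2.0, (h - 1) / 2.0)
    mask = silhouette_mask((h, w), centre_xy, body, reference_angle_deg)
    return BodyKernel(
        mask=mask,
        centre_xy=centre_xy,
        reference_angle_deg=reference_angle_deg,
        body=body,
    )


def _score_all_rotations(frame_enhanced: np.ndarray, kernel: BodyKernel) -> np.ndarray:
    """Pearson score of every integer rotation against the inverted frame."""
    bank = kernel._rotation_bank()
    f = 255.0 - np.asarray(frame_enhanced, dtype=np.float32).ravel()
    f = f - f.mean()
    norm = np.linalg.norm(f)
    if norm < 1e-9:
        return np.zeros(360, dtype=np.float32)
    return bank @ (f / norm)


def match_angle(
    frame: np.ndarray,
    kernel: BodyKernel,
    previous_angle: float | None = None,
    enhanced: bool = False,
    clip_fraction: float = 0.05,
) -> tuple[int, float, bool]:
    """Best-fit body angle of one frame by exhaustive rotation search.

    Returns ``(angle_deg, score, flagged)``. ``angle_deg`` is the integer
    rotation (degrees clockwise from image-up) maximizing the correlation
    score; ties go to the candidate circularly nearest ``previous_angle``
    (else the smallest angle). ``flagged`` marks frames with no usable
    contrast, a weak best score, or a near-ambiguous head/tail assignment.
    """
    if frame.shape != kernel.mask.shape:
        raise ValueError("frame and kernel dimensions differ")
    img = np.asarray(frame, dtype=float)
    if not enhanced:
        img = enhance_contrast(img, clip_fraction)
    scores = _score_all_rotations(img, kernel)
    best = float(scores.max())
    candidates = np.flatnonzero(scores >= best - 1e-6)
    if candidates.size == 1:
        angle = int(candidates[0])
    elif previous_angle is not None:
        dist = np.abs([wrap180(c - previous_angle) for c in candidates])
        angle = int(candidates[int(np.argmin(dist))])
    else:
        angle = int(candidates[0])

    flagged = best < LOW_CONFIDENCE_SCORE
    anti = scores[(angle + 180) % 360]
    if anti > 0 and best > 0 and best / anti < AMBIGUITY_RATIO:
        flagged = True
    return angle, best, flagged


@dataclass
class TrackedSeries:
    """Per-frame tracked angles (1-degree resolution) with match scores."""

    angles_deg: np.ndarray
    scores: np.ndarray
    flags: np.ndarray
    frame_index: np.ndarray
    times_s: np.ndarray
    rate_hz: float


def track_stack(
    stack: FrameStack,
    kernel: BodyKernel,
    clip_fraction: float = 0.05,
) -> TrackedSeries:
    """Track the body angle through a whole stack.

    Each frame is contrast-enhanced and matched with the previous frame's
    angle as the tie-breaker. The stack's calibration offset is applied so
    the emitted angles are compass bearings when the offset is set.
    """
    if len(stack) == 0:
        raise ValueError("empty frame stack")
    if stack.frames.shape[1:] != kernel.mask.shape:
        raise ValueError("frame and kernel dimensions differ")
    n = len(stack)
    angles = np.empty(n, dtype=float)
    scores = np.empty(n)
    flags = np.zeros(n, dtype=bool)
    prev: float | None = None
    for k in range(n):
        a, s, fl = match_angle(
            stack.frames[k], kernel, previous_angle=prev, clip_fraction=clip_fraction
        )
        angles[k], scores[k], flags[k] = a, s, fl
        prev = a
    angles = np.mod(angles + stack.calibration_offset_deg, 360.0)
    return TrackedSeries(
        angles_deg=angles,
        scores=scores,
        flags=flags,
        frame_index=np.arange(n),
        times_s=stack.timestamps.copy(),
        rate_hz=stack.rate_hz,
    )
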