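"""Frame-level image operations: background correction, profiles, kymographs.

The background of each fluorescence frame is estimated by grayscale
morphological opening with a ball (spherical-cap) structuring element —
the classic "rolling ball" — and subtracted.  Anything smoother and wider
than the ball (dye haze, illumination falloff) is background; the
granular cell signal rides on top and survives.  Correction is applied to
each frame independently.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import grey_opening

from .errors import InvalidParameterError
from .stacks import ImageStack

DEFAULT_BALL_RADIUS_PX = 50


@dataclass(frozen=True)
class ChannelROI:
    """Rectangular channel region in pixel coordinates (0-based, half-open).

    ``gradient_axis`` names the image axis that runs left (chemoeffector)
    to right (plain medium); 1 means image columns (the default
    orientation), 0 means rows.
    """

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int
    gradient_axis: int = 1

    def __post_init__(self) -> None:
        if self.gradient_axis not in (0, 1):
            raise InvalidParameterError("gradient_axis must be 0 or 1")
        if self.row_start < 0 or self.col_start < 0:
            raise InvalidParameterError("ROI bounds must be non-negative")
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise InvalidParameterError("ROI bounds must be strictly increasing")
        if self.width < 2:
            raise InvalidParameterError(
                "ROI must span at least 2 pixels along the gradient axis"
            )

    @property
    def width(self) -> int:
        """Extent along the gradient axis, in pixels."""
        if self.gradient_axis == 1:
            return self.col_stop - self.col_start
        return self.row_stop - self.row_start

    @classmethod
    def full_frame(cls, shape: tuple[int, int], gradient_axis: int = 1) -> "ChannelROI":
        return cls(0, shape[0], 0, shape[1], gradient_axis)

    def validate_for(self, frame: np.ndarray) -> None:
        if self.row_stop > frame.shape[0] or self.col_stop > frame.shape[1]:
            raise InvalidParameterError(
                f"ROI {self} exceeds frame shape {frame.shape}"
            )

    def crop(self, frame: np.ndarray) -> np.ndarray:
        """Return the ROI sub-image oriented so axis 1 is the gradient axis."""
        self.validate_for(frame)
        sub = frame[self.row_start : self.row_stop, self.col_start : self.col_stop]
        return sub if self.gradient_axis == 1 else sub.T


@dataclass
class IntensityProfile:
    """Mean intensity across the channel width at one time point."""

    x_um: np.ndarray
    intensity: np.ndarray
    time_min: float = 0.0

    def __post_init__(self) -> None:
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.x_um.shape != self.intensity.shape:
            raise InvalidParameterError("x_um and intensity must be same length")


@dataclass
class Kymograph:
    """Space–time image: one length-compressed row per frame, time downward."""

    rows: np.ndarray
    time_min: np.ndarray
    x_um: np.ndarray

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.shape != (self.time_min.size, self.x_um.size):
            raise InvalidParameterError("kymograph axes do not match row block")


def ball_structuring_element(radius_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Footprint mask and height map of a ball of the given pixel radius."""
    if radius_px < 1:
        raise InvalidParameterError("radius_px must be >= 1")
    r = int(radius_px)
    u = np.arange(-r, r + 1)
    uu, vv = np.meshgrid(u, u, indexing="ij")
    d2 = uu * uu + vv * vv
    footprint = d2 <= r * r
    heights = np.zeros_like(d2, dtype=float)
    heights[footprint] = np.sqrt(r * r - d2[footprint])
    return footprint, heights


def rolling_ball_correct(
    frame: np.ndarray, radius_px: int = DEFAULT_BALL_RADIUS_PX
) -> np.ndarray:
    """Subtract the rolling-ball background from a grayscale frame.

    The background is the grayscale opening of the frame with a ball
    structuring element of the given radius; the corrected frame is
    ``frame - background`` clipped at zero (fluorescence cannot be
    negative).  The result is float and pointwise ≤ the input.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise InvalidParameterError("frame must be 2-D grayscale")
    r = int(radius_px)
    if r < 1:
        raise InvalidParameterError("radius_px must be >= 1")
    if 2 * r + 1 > min(frame.shape):
        raise InvalidParameterError(
            f"ball diameter {2 * r + 1} px exceeds frame extent {min(frame.shape)} px"
        )
    footprint, heights = ball_structuring_element(r)
    background = grey_opening(
        frame.astype(float), footprint=footprint, structure=heights, mode="nearest"
    )
    return np.clip(frame.astype(float) - background, 0.0, None)


def correct_stack(
    stack: ImageStack, radius_px: int = DEFAULT_BALL_RADIUS_PX
) -> ImageStack:
    """Rolling-ball-correct every frame of a stack independently."""
    corrected = np.stack(
        [rolling_ball_correct(f, radius_px) for f in stack.frames]
    )
    return ImageStack(
        frames=corrected,
        pixel_size_um=stack.pixel_size_um,
        frame_interval_min=stack.frame_interval_min,
        t0=stack.t0,
        extra={**stack.extra, "rolling_ball_radius_px": int(radius_px)},
    )


def intensity_profile(
    frame: np.ndarray,
    roi: ChannelROI,
    pixel_size_um: float = 1.0,
    time_min: float = 0.0,
) -> IntensityProfile:
    """Mean intensity across the channel width.

    For each position along the gradient axis within the ROI, the mean is
    taken over the perpendicular (channel-length) axis.
    """
    sub = roi.crop(np.asarray(frame))
    profile = sub.mean(axis=0)
    x_um = (np.arange(profile.size) + 0.5) * pixel_size_um
    return IntensityProfile(x_um=x_um, intensity=profile, time_min=time_min)


def build_kymograph(stack: ImageStack, roi: ChannelROI) -> Kymograph:
    """Compress each frame across the channel length and stack rows in time."""
    if len(stack) == 0:
        raise InvalidParameterError("stack is empty")
    rows = []
    for frame in stack.frames:
        rows.append(
            intensity_profile(frame, roi, stack.pixel_size_um).intensity
        )
    rows = np.stack(rows)
    x_um = (np.arange(rows.shape[1]) + 0.5) * stack.pixel_size_um
    return Kymograph(rows=rows, time_min=stack.times_min, x_um=x_um)
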