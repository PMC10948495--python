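"""Fluorescence rendering of simulated experiments.

Two rendering modes are provided:

``"particles"`` (default for bacterial scenarios)
    Each frame draws a Poisson number of discrete cells whose positions
    across the width follow the density profile; every cell is stamped as
    a small point-spread blob.  Fluorescence from individual GFP cells at
    low magnification is granular, and it is this granularity that lets
    rolling-ball background correction remove smooth background while
    preserving the cell signal.  Spot amplitudes are normalized so the
    expected mean pixel value over the channel is ``gain·b`` plus
    background, matching the continuum mode in expectation.

``"continuum"``
    Each frame is ``gain·b`` broadcast along the channel length.  This is
    the right model for a dissolved dye (the pyranine calibration images)
    and is the exact-linearity reference for unit contracts.

Both modes then add a constant background level, a smooth spurious
inhomogeneity field (out-of-focus light, illumination falloff), shot
noise, and additive Gaussian read noise, and quantize to the configured
bit depth.  Rendering is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import InvalidParameterError
from .geometry import ChannelGeometry
from .population import DensityField
from .stacks import ImageStack

logger = logging.getLogger(__name__)

RENDER_MODES = ("particles", "continuum")


@dataclass(frozen=True)
class NoiseModel:
    """Shot noise (Poisson on the expected signal) plus Gaussian read noise."""

    shot: bool = True
    read_sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.read_sigma < 0:
            raise InvalidParameterError("read_sigma must be >= 0")


@dataclass(frozen=True)
class BackgroundInhomogeneity:
    """Smooth spurious background: amplitude (counts) and length scale (µm)."""

    amplitude: float = 30.0
    length_scale_um: float = 300.0

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.length_scale_um <= 0:
            raise InvalidParameterError(
                "inhomogeneity amplitude must be >= 0 and length scale > 0"
            )


@dataclass(frozen=True)
class ImagingParams:
    """Rendering and acquisition parameters.

    Parameters
    ----------
    gain:
        Mean intensity counts per density unit.
    background_level:
        Additive constant offset in counts.
    background_inhomogeneity:
        Smooth spurious background field (amplitude, length scale).
    noise_model:
        Shot + read noise configuration.
    frame_interval_min, duration_h:
        Acquisition cadence (default one frame per 5 min over 9 h).
    bit_depth:
        Output sample depth (8 or 16).
    seed:
        Seed for all rendering randomness.
    mode:
        ``"particles"`` or ``"continuum"`` (see module docstring).
    cells_per_unit:
        Particles mode only: expected rendered cells per unit of ∫b dx.
    psf_sigma_px:
        Particles mode only: Gaussian point-spread sigma in pixels.
    """

    gain: float = 80.0
    background_level: float = 200.0
    background_inhomogeneity: BackgroundInhomogeneity = field(
        default_factory=BackgroundInhomogeneity
    )
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    frame_interval_min: float = 5.0
    duration_h: float = 9.0
    bit_depth: int = 16
    seed: int = 0
    mode: str = "particles"
    cells_per_unit: float = 3.0
    psf_sigma_px: float = 1.0

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise InvalidParameterError("gain must be strictly positive")
        if self.background_level < 0:
            raise InvalidParameterError("background_level must be >= 0")
        if self.frame_interval_min <= 0 or self.duration_h <= 0:
            raise InvalidParameterError("frame cadence must be positive")
        if self.bit_depth not in (8, 16):
            raise InvalidParameterError("bit_depth must be 8 or 16")
        if self.mode not in RENDER_MODES:
            raise InvalidParameterError(f"mode must be one of {RENDER_MODES}")
        if self.cells_per_unit <= 0 or self.psf_sigma_px <= 0:
            raise InvalidParameterError(
                "cells_per_unit and psf_sigma_px must be > 0"
            )

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_h * 60.0 / self.frame_interval_min)) + 1

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_min * 60.0

    @property
    def max_count(self) -> int:
        return 2**self.bit_depth - 1


def _inhomogeneity_field(
    shape: tuple[int, int],
    inhom: BackgroundInhomogeneity,
    pixel_size_um: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth zero-mean random field with the configured amplitude (std)."""
    if inhom.amplitude == 0:
        return np.zeros(shape)
    sigma_px = max(inhom.length_scale_um / pixel_size_um / 2.0, 1.0)
    white = rng.standard_normal(shape)
    smooth = gaussian_filter(white, sigma=sigma_px, mode="reflect")
    std = smooth.std()
    if std == 0:
        return np.zeros(shape)
    return smooth * (inhom.amplitude / std)


def _particle_frame(
    profile: np.ndarray,
    x: np.ndarray,
    shape: tuple[int, int],
    geometry: ChannelGeometry,
    imaging: ImagingParams,
    rng: np.random.Generator,
) -> np.ndarray:
    n_rows, n_cols = shape
    dx = x[1] - x[0]
    total_density = float(profile.sum() * dx)
    n_cells = rng.poisson(imaging.cells_per_unit * total_density)
    img = np.zeros(shape)
    if n_cells == 0 or total_density == 0:
        return img
    # inverse-CDF sampling of positions across the width
    cdf = np.concatenate([[0.0], np.cumsum(profile) * dx])
    cdf /= cdf[-1]
    x_edges = np.concatenate([[x[0] - dx / 2], x + dx / 2])
    xs = np.interp(rng.random(n_cells), cdf, x_edges)
    cols = np.clip((xs / geometry.pixel_size_um).astype(int), 0, n_cols - 1)
    rows = rng.integers(0, n_rows, n_cells)
    # per-cell integrated intensity chosen so the channel-mean pixel value
    # from cells equals gain * mean density, matching continuum mode
    amp = imaging.gain * n_rows * n_cols / (
        imaging.cells_per_unit * geometry.width_um
    )
    np.add.at(img, (rows, cols), amp)
    return gaussian_filter(img, sigma=imaging.psf_sigma_px, mode="constant")


def render_image_stack(
    density: DensityField,
    geometry: ChannelGeometry,
    imaging: ImagingParams,
) -> ImageStack:
    """Render a density field into a quantized grayscale time-lapse stack.

    The density field must be sampled at the acquisition frame times
    (``imaging.frame_times_s``); frames are matched by nearest stored time.
    """
    shape = (geometry.n_rows, geometry.n_cols)
    rng = np.random.default_rng(imaging.seed)
    inhom = _inhomogeneity_field(
        shape, imaging.background_inhomogeneity, geometry.pixel_size_um, rng
    )
    x_px = (np.arange(geometry.n_cols) + 0.5) * geometry.pixel_size_um

    frame_times = imaging.frame_times_s
    if density.times[-1] + 1e-9 < frame_times[-1]:
        raise InvalidParameterError(
            f"density field ends at {density.times[-1]:.0f} s but imaging "
            f"runs to {frame_times[-1]:.0f} s"
        )

    dtype = np.uint8 if imaging.bit_depth == 8 else np.uint16
    frames = np.empty((imaging.n_frames, *shape), dtype=dtype)
    n_saturated = 0
    for k, t in enumerate(frame_times):
        i = int(np.argmin(np.abs(density.times - t)))
        profile = density.b[i]
        if imaging.mode == "particles":
            signal = _particle_frame(
                profile, density.x, shape, geometry, imaging, rng
            )
        else:
            signal = np.broadcast_to(
                imaging.gain * np.interp(x_px, density.x, profile),
                shape,
            ).copy()
        signal += imaging.background_level + inhom
        np.clip(signal, 0.0, None, out=signal)
        if imaging.noise_model.shot:
            signal = rng.poisson(signal).astype(float)
        if imaging.noise_model.read_sigma > 0:
            signal += rng.normal(0.0, imaging.noise_model.read_sigma, shape)
        np.clip(signal, 0, imaging.max_count, out=signal)
        quantized = np.rint(signal).astype(dtype)
        n_saturated += int(np.count_nonzero(quantized == imaging.max_count))
        frames[k] = quantized

    frac = n_saturated / frames.size
    if frac > 0.01:
        logger.warning(
            "rendering saturated %.1f%% of pixels (> 1%%); reduce gain or "
            "background",
            100 * frac,
        )
    return ImageStack(
        frames=frames,
        pixel_size_um=geometry.pixel_size_um,
        frame_interval_min=imaging.frame_interval_min,
        extra={"seed": imaging.seed, "mode": imaging.mode},
    )
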