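"""Time-lapse image stacks: the in-memory container and TIFF round-trip.

A stack is a multi-page grayscale TIFF (one page per time point) plus a
YAML sidecar carrying the acquisition metadata the pixels cannot:
pixel size, frame interval, acquisition start, and — for synthetic
stacks — the generator parameters and seed.  The sidecar lives next to
the TIFF as ``<name>.yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml

from .errors import InvalidParameterError, UnsupportedFormatError

#: Sidecar fields required to interpret a stack.
REQUIRED_METADATA = ("pixel_size_um", "frame_interval_min")


@dataclass
class ImageStack:
    """Ordered grayscale frames with the metadata needed to analyze them.

    ``frames`` has shape ``(n_frames, n_rows, n_cols)``.  By convention
    image columns run along the gradient axis with the chemoeffector
    reservoir on the left; stacks acquired mirrored are flipped on load
    (see :func:`read_stack`).
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_min: float
    t0: str = ""
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise InvalidParameterError(
                f"frames must be (n_frames, rows, cols); got ndim={self.frames.ndim}"
            )
        if not self.frame_interval_min > 0:
            raise InvalidParameterError("frame_interval_min must be > 0")
        if not self.pixel_size_um > 0:
            raise InvalidParameterError("pixel_size_um must be > 0")
        if np.issubdtype(self.frames.dtype, np.floating) and np.any(self.frames < 0):
            raise InvalidParameterError("pixel values must be >= 0")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times_min(self) -> np.ndarray:
        """Frame acquisition times in minutes from the start."""
        return np.arange(len(self)) * float(self.frame_interval_min)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a multi-page grayscale TIFF plus its YAML sidecar.

    Returns the TIFF path.  The round trip through :func:`read_stack`
    preserves pixel values bit-exactly and all metadata fields.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames, photometric="minisblack")
    meta = {
        "pixel_size_um": float(stack.pixel_size_um),
        "frame_interval_min": float(stack.frame_interval_min),
        "t0": stack.t0,
        "dtype": str(stack.frames.dtype),
        **stack.extra,
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def read_stack(
    path: str | Path,
    pixel_size_um: float | None = None,
    frame_interval_min: float | None = None,
) -> ImageStack:
    """Read a multi-page grayscale TIFF into an :class:`ImageStack`.

    Metadata comes from the YAML sidecar when present; explicit arguments
    override it.  A sidecar key ``mirror: true`` marks a stack acquired
    with the chemoeffector on the right; such stacks are flipped along the
    column axis on load so "left" always means the chemoeffector side.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise UnsupportedFormatError(
            f"{path.name}: expected grayscale pages of one shape; "
            f"got array of ndim={frames.ndim} (RGB or mixed-shape pages?)"
        )

    meta: dict[str, Any] = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
    if pixel_size_um is not None:
        meta["pixel_size_um"] = pixel_size_um
    if frame_interval_min is not None:
        meta["frame_interval_min"] = frame_interval_min

    missing = [k for k in REQUIRED_METADATA if meta.get(k) is None]
    if missing:
        raise InvalidParameterError(
            f"{path.name}: missing required metadata {missing}; provide a "
            f"sidecar YAML or explicit overrides"
        )
    if meta.pop("mirror", False):
        frames = frames[:, :, ::-1].copy()
    meta.pop("dtype", None)
    return ImageStack(
        frames=frames,
        pixel_size_um=float(meta.pop("pixel_size_um")),
        frame_interval_min=float(meta.pop("frame_interval_min")),
        t0=str(meta.pop("t0", "")),
        extra=meta,
    )
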