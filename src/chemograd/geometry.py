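"""Observation-channel geometry.

The gradient generator holds a rectangular observation channel between two
reservoirs.  The *width* axis runs from the chemoeffector reservoir (left)
to the plain-medium reservoir (right); the *length* axis is perpendicular
to the gradient and is averaged over during analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidParameterError

#: Minimum number of pixel columns across the channel width for any geometry.
MIN_WIDTH_PX = 16


@dataclass(frozen=True)
class ChannelGeometry:
    """Physical dimensions of the observation channel and imaging raster.

    Parameters
    ----------
    width_um:
        Channel width along the gradient axis, in microns.
    length_um:
        Channel extent perpendicular to the gradient, in microns.
    pixel_size_um:
        Microns per pixel of the rendered/acquired images.
    """

    width_um: float = 1000.0
    length_um: float = 600.0
    pixel_size_um: float = 1.3

    def __post_init__(self) -> None:
        for name in ("width_um", "length_um", "pixel_size_um"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if self.n_cols < MIN_WIDTH_PX:
            raise InvalidParameterError(
                f"width_um/pixel_size_um yields {self.n_cols} pixel columns; "
                f"at least {MIN_WIDTH_PX} are required"
            )

    @property
    def n_cols(self) -> int:
        """Pixel columns across the channel width (gradient axis)."""
        return int(round(self.width_um / self.pixel_size_um))

    @property
    def n_rows(self) -> int:
        """Pixel rows along the channel length."""
        return max(1, int(round(self.length_um / self.pixel_size_um)))
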