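"""Quantitative readouts of the population's spatial distribution.

The central statistic is the asymmetry index

    A = (I_left − I_right) / (I_left + I_right)

where I_left and I_right are the mean fluorescence intensities of the two
equal halves of the observation channel.  A is +1 when all signal is on
the chemoeffector (left) side, −1 when all is on the right, and 0 for an
even distribution.  A is invariant under global intensity scaling but not
under additive offsets, which is why frames are background-corrected
before the index is computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .imageops import ChannelROI
from .stacks import ImageStack

#: Default assay endpoint: 9 h of incubation, in minutes.
DEFAULT_ENDPOINT_MIN = 9 * 60.0
#: Default trailing window for the saturation value, in minutes.
DEFAULT_SATURATION_WINDOW_MIN = 60.0


@dataclass
class AsymmetrySeries:
    """Asymmetry index per frame, with the underlying half-channel means.

    Frames where both halves are zero have no defined index and carry
    NaN in ``A`` (never 0).
    """

    time_min: np.ndarray
    A: np.ndarray
    I_left: np.ndarray
    I_right: np.ndarray

    def __post_init__(self) -> None:
        n = self.time_min.size
        if not (self.A.size == self.I_left.size == self.I_right.size == n):
            raise InvalidParameterError("series fields must be equal length")

    def at_time(self, t_min: float) -> float:
        """A at the frame nearest ``t_min`` (ties resolve to the earlier frame)."""
        if t_min > self.time_min[-1] + 1e-9:
            raise InvalidParameterError(
                f"endpoint {t_min} min is beyond the series "
                f"(last frame {self.time_min[-1]} min)"
            )
        i = int(np.argmin(np.abs(self.time_min - t_min)))
        return float(self.A[i])


@dataclass
class GrowthCurves:
    """Mean intensity of each half-channel per frame (population growth)."""

    time_min: np.ndarray
    mean_left: np.ndarray
    mean_right: np.ndarray


@dataclass
class ReplicateSummary:
    """Endpoint asymmetry across replicates: per-replicate values, mean, SD."""

    scenario: str
    endpoint_min: float
    values: np.ndarray
    mean: float
    sd: float  # sample SD (n-1); NaN for a single replicate


def _split_halves(sub: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split the width axis (axis 1) into two exactly equal halves.

    For an odd width the single middle column is excluded so the halves
    stay equal.
    """
    w = sub.shape[1]
    half = w // 2
    return sub[:, :half], sub[:, w - half :]


def asymmetry_index(
    frame: np.ndarray, roi: ChannelROI | None = None
) -> tuple[float, float, float]:
    """Asymmetry index of one (background-corrected) frame.

    Returns ``(A, I_left, I_right)``.  ``A`` is NaN when both half-channel
    means are zero (no signal — the index is undefined there).
    """
    frame = np.asarray(frame, dtype=float)
    if roi is None:
        roi = ChannelROI.full_frame(frame.shape)
    sub = roi.crop(frame)
    left, right = _split_halves(sub)
    i_left = float(left.mean())
    i_right = float(right.mean())
    total = i_left + i_right
    if total == 0:
        return math.nan, i_left, i_right
    return (i_left - i_right) / total, i_left, i_right


def asymmetry_series(stack: ImageStack, roi: ChannelROI | None = None) -> AsymmetrySeries:
    """Per-frame asymmetry index of a (background-corrected) stack."""
    if len(stack) == 0:
        raise InvalidParameterError("stack is empty")
    a = np.empty(len(stack))
    il = np.empty(len(stack))
    ir = np.empty(len(stack))
    for k, frame in enumerate(stack.frames):
        a[k], il[k], ir[k] = asymmetry_index(frame, roi)
    return AsymmetrySeries(time_min=stack.times_min, A=a, I_left=il, I_right=ir)


def growth_curves(stack: ImageStack, roi: ChannelROI | None = None) -> GrowthCurves:
    """Mean half-channel intensities per frame, split exactly as for A."""
    if len(stack) == 0:
        raise InvalidParameterError("stack is empty")
    series = asymmetry_series(stack, roi)
    return GrowthCurves(
        time_min=series.time_min,
        mean_left=series.I_left,
        mean_right=series.I_right,
    )


def summarize_endpoint(
    series_list: list[AsymmetrySeries],
    endpoint_min: float = DEFAULT_ENDPOINT_MIN,
    scenario: str = "",
) -> ReplicateSummary:
    """Endpoint A across replicates: mean and sample SD (n−1 denominator)."""
    if not series_list:
        raise InvalidParameterError("need at least one replicate series")
    values = np.array([s.at_time(endpoint_min) for s in series_list])
    mean = float(np.nanmean(values))
    sd = float(np.nanstd(values, ddof=1)) if values.size > 1 else math.nan
    return ReplicateSummary(
        scenario=scenario,
        endpoint_min=endpoint_min,
        values=values,
        mean=mean,
        sd=sd,
    )


def saturation_value(
    series: AsymmetrySeries, window_min: float = DEFAULT_SATURATION_WINDOW_MIN
) -> float:
    """Mean A over the trailing window (default the final 60 min)."""
    t_end = series.time_min[-1]
    if window_min > t_end - series.time_min[0]:
        raise InvalidParameterError(
            f"window {window_min} min exceeds series span "
            f"{t_end - series.time_min[0]} min"
        )
    mask = series.time_min >= t_end - window_min
    return float(np.nanmean(series.A[mask]))
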