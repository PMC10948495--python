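"""Intensity-to-concentration calibration and gradient linearity checks.

The dye experiment validates the gradient generator: a fluorescent dye
(pyranine, 100 nM) is loaded into the left reservoir and imaged; a
control with the same concentration in both reservoirs pins the
intensity scale.  A linear (affine) intensity–concentration relation is
assumed — standard for dilute fluorescein-class dyes:

    c(x) = slope · (I(x) − offset)

with ``offset`` the dye-free background intensity and ``slope`` fixed by
the uniform-concentration control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import CalibrationError, InvalidParameterError
from .imageops import IntensityProfile


@dataclass(frozen=True)
class CalibrationModel:
    """Affine intensity→concentration conversion."""

    slope: float  # concentration units per intensity count
    offset: float  # counts at zero concentration
    reference_conc: float

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise InvalidParameterError("slope must be strictly positive")
        if self.offset < 0:
            raise InvalidParameterError("offset must be >= 0")


@dataclass(frozen=True)
class GradientFit:
    """OLS line through a concentration profile across the channel width."""

    slope: float  # concentration per µm
    intercept: float  # concentration at x = 0
    r_squared: float
    c_at_left: float
    c_at_right: float


def fit_calibration(
    uniform_profile: IntensityProfile,
    dark_profile: IntensityProfile,
    reference_conc: float,
) -> CalibrationModel:
    """Calibrate from a uniform-concentration control and a dye-free profile.

    ``offset`` is the mean of the dark profile; ``slope`` maps the excess
    intensity of the uniform control onto its known concentration.
    """
    if not reference_conc > 0:
        raise InvalidParameterError("reference_conc must be > 0")
    if uniform_profile.intensity.size != dark_profile.intensity.size:
        raise InvalidParameterError("profiles must be the same length")
    offset = float(dark_profile.intensity.mean())
    excess = float(uniform_profile.intensity.mean()) - offset
    if excess <= 0:
        raise CalibrationError(
            "uniform-control intensity does not exceed the dark offset; "
            "cannot establish an intensity scale"
        )
    return CalibrationModel(
        slope=reference_conc / excess,
        offset=offset,
        reference_conc=reference_conc,
    )


def to_concentration(
    profile: IntensityProfile, model: CalibrationModel
) -> IntensityProfile:
    """Convert an intensity profile to concentration, clipped at zero.

    Returns a profile whose ``intensity`` field holds concentrations in
    the calibration's units.
    """
    conc = np.clip(model.slope * (profile.intensity - model.offset), 0.0, None)
    return IntensityProfile(
        x_um=profile.x_um.copy(), intensity=conc, time_min=profile.time_min
    )


def fit_linear_gradient(conc_profile: IntensityProfile) -> GradientFit:
    """Least-squares line through a concentration profile.

    Endpoint concentrations are the fitted line evaluated at the ROI
    edges (half a pixel beyond the outermost sample centers).
    """
    x = conc_profile.x_um
    y = conc_profile.intensity
    if x.size < 3:
        raise InvalidParameterError("need at least 3 points to fit a gradient")
    res = stats.linregress(x, y)
    dx = x[1] - x[0]
    left_edge = x[0] - dx / 2
    right_edge = x[-1] + dx / 2
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    return GradientFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        c_at_left=float(res.intercept + res.slope * left_edge),
        c_at_right=float(res.intercept + res.slope * right_edge),
    )
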