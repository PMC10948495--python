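"""Bacterial population dynamics across the channel width.

A continuum drift–diffusion–growth (Keller–Segel type) model:

    ∂b/∂t = D_b ∂²b/∂x² − ∂/∂x(χ b ∂c/∂x) + r(c) b

with zero-flux walls — the membrane confines cells to the channel.  D_b is
the effective motility diffusivity of the run-and-reverse swimmer, χ the
chemotactic sensitivity, and r(c) a local specific growth rate set by the
nutrient concentration.  The solver is an operator-split explicit scheme:
conservative central diffusion, first-order upwind advection on face
velocities, and pointwise exponential growth, with the time step chosen to
satisfy both CFL conditions with a safety factor of 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, SolverError
from .geometry import ChannelGeometry
from .transport import ConcentrationField

CFL_SAFETY = 0.5

GROWTH_LAWS = ("monod", "linear", "constant", "none")


@dataclass(frozen=True)
class PopulationParams:
    """Parameters of the drift–diffusion–growth model.

    Parameters
    ----------
    D_b:
        Motility diffusivity in µm²/s.
    chi:
        Chemotactic sensitivity in µm²/(s·concentration-unit); the drift
        velocity in a gradient is χ ∂c/∂x.
    r0:
        Maximal specific growth rate in 1/h.
    growth_law:
        How local concentration maps to specific growth rate:
        ``"monod"``  r(c) = r0·c/(K + c)    (saturating, default)
        ``"linear"`` r(c) = r0·c/K          (proportional)
        ``"constant"`` r(c) = r0            (nutrient-independent)
        ``"none"``   r(c) = 0
    K:
        Concentration scale of the growth law (half-saturation for Monod),
        in the same units as the concentration field.
    b0:
        Initial density profile over the width; a scalar means uniform.
        Density units are arbitrary and carried through rendering.
    """

    D_b: float = 30.0
    chi: float = 0.0
    r0: float = 0.0
    growth_law: str = "monod"
    K: float = 1.0
    b0: float | np.ndarray = 1.0

    def __post_init__(self) -> None:
        if not self.D_b > 0:
            raise InvalidParameterError("D_b must be strictly positive")
        if self.chi < 0 or self.r0 < 0:
            raise InvalidParameterError("chi and r0 must be >= 0")
        if self.growth_law not in GROWTH_LAWS:
            raise InvalidParameterError(
                f"growth_law must be one of {GROWTH_LAWS}, got {self.growth_law!r}"
            )
        if self.growth_law in ("monod", "linear") and not self.K > 0:
            raise InvalidParameterError("K must be strictly positive")
        if np.any(np.asarray(self.b0) < 0):
            raise InvalidParameterError("b0 must be non-negative everywhere")

    def growth_rate(self, c: np.ndarray) -> np.ndarray:
        """Specific growth rate r(c) in 1/s for local concentration ``c``."""
        r0_s = self.r0 / 3600.0
        c = np.asarray(c, dtype=float)
        if self.growth_law == "monod":
            return r0_s * c / (self.K + c)
        if self.growth_law == "linear":
            return r0_s * c / self.K
        if self.growth_law == "constant":
            return np.full_like(c, r0_s)
        return np.zeros_like(c)


@dataclass
class DensityField:
    """Bacterial density b(t, x) across the channel width.

    ``b`` has shape ``(len(times), len(x))``; ``times`` in seconds, ``x``
    in µm from the left wall.
    """

    times: np.ndarray
    x: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.b.shape != (self.times.size, self.x.size):
            raise InvalidParameterError(
                f"b has shape {self.b.shape}, expected "
                f"({self.times.size}, {self.x.size})"
            )
        if np.any(self.b < 0):
            raise InvalidParameterError("densities must be non-negative")

    def mass(self) -> np.ndarray:
        """Total population ∫b dx per stored time (uniform-cell quadrature)."""
        dx = self.x[1] - self.x[0]
        return self.b.sum(axis=1) * dx

    def centroid(self) -> np.ndarray:
        """Density-weighted mean position per stored time, in µm."""
        w = self.b.sum(axis=1)
        return (self.b * self.x).sum(axis=1) / np.where(w > 0, w, np.nan)


def cell_centers(geometry: ChannelGeometry, n_cells: int | None = None) -> np.ndarray:
    """Centers of the finite-volume cells tiling the channel width.

    By default one cell per imaging pixel column, so rendered pixel values
    map one-to-one onto density cells.
    """
    n = n_cells if n_cells is not None else geometry.n_cols
    if n < 2:
        raise InvalidParameterError("need at least 2 cells across the width")
    h = geometry.width_um / n
    return (np.arange(n) + 0.5) * h


def _conc_profile(conc: ConcentrationField, t: float) -> np.ndarray:
    if conc.times.size == 1:
        return conc.c[0]
    i = int(np.searchsorted(conc.times, t, side="right")) - 1
    return conc.c[min(max(i, 0), conc.times.size - 1)]


def simulate_population(
    geometry: ChannelGeometry,
    population: PopulationParams,
    conc: ConcentrationField,
    times: np.ndarray,
    n_cells: int | None = None,
) -> DensityField:
    """Evolve the population model over ``times`` (seconds, starting at 0).

    The density lives on a cell-centered finite-volume grid tiling
    [0, width] (default: one cell per pixel column, or the length of an
    array-valued ``b0``).  The concentration field may be steady (single
    stored time) or time-resolved; it is held piecewise-constant between
    its stored times and interpolated onto cell faces in space.
    Boundaries are zero-flux, so with r0 = 0 the scheme conserves ∫b dx
    to round-off.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0 or times[0] != 0.0 or np.any(np.diff(times) <= 0):
        raise InvalidParameterError("times must be strictly increasing from 0")
    if conc.x[0] > 1e-9 or not np.isclose(conc.x[-1], geometry.width_um):
        raise InvalidParameterError(
            "concentration grid does not span the channel width"
        )

    b0_arr = np.asarray(population.b0, dtype=float)
    if n_cells is None and b0_arr.ndim == 1:
        n_cells = b0_arr.size
    x = cell_centers(geometry, n_cells)
    nx = x.size
    dx = x[1] - x[0]

    b = np.broadcast_to(b0_arr, (nx,)).copy()

    # face drift velocities from the (piecewise-steady) concentration field
    def face_velocity(t: float) -> np.ndarray:
        c_cells = np.interp(x, conc.x, _conc_profile(conc, t))
        return population.chi * np.diff(c_cells) / dx

    steady = conc.times.size == 1
    v_steady = face_velocity(0.0)
    vmax = np.max(np.abs(v_steady)) if v_steady.size else 0.0
    dt_diff = dx * dx / (2.0 * population.D_b)
    dt_adv = dx / vmax if vmax > 0 else np.inf
    dt = CFL_SAFETY * min(dt_diff, dt_adv)

    grow = population.r0 > 0 and population.growth_law != "none"
    out = np.empty((times.size, nx))
    out[0] = b
    t_now = 0.0
    for k in range(1, times.size):
        target = times[k]
        n_steps = int(np.ceil((target - t_now) / dt))
        step = (target - t_now) / n_steps
        if steady:
            v = v_steady
            growth_factor = (
                np.exp(population.growth_rate(np.interp(x, conc.x, _conc_profile(conc, 0.0))) * step)
                if grow
                else None
            )
        for _ in range(n_steps):
            if not steady:
                v = face_velocity(t_now)
                growth_factor = (
                    np.exp(
                        population.growth_rate(np.interp(x, conc.x, _conc_profile(conc, t_now))) * step
                    )
                    if grow
                    else None
                )
            # upwind advective flux at interior faces, zero at the walls
            flux = np.where(v > 0, v * b[:-1], v * b[1:])
            # diffusive flux at interior faces
            flux -= population.D_b * np.diff(b) / dx
            b[:-1] -= step / dx * flux
            b[1:] += step / dx * flux
            if growth_factor is not None:
                b *= growth_factor
            t_now += step
        if np.min(b) < -1e-9 * max(np.max(b), 1.0):
            raise SolverError(
                f"negative density {np.min(b):.3e} at t={t_now:.1f} s"
            )
        np.clip(b, 0.0, None, out=b)
        out[k] = b
    return DensityField(times=times, x=x, b=out)
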