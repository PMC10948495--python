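"""Chemoeffector transport in the observation channel.

The two reservoirs flank the channel and are large enough to act as
constant-concentration sources over the experiment, while the 0.1-µm-pore
membrane passes solutes freely and blocks cells.  Transport across the
channel width is therefore one-dimensional diffusion with Dirichlet
boundaries; the steady state is the linear gradient the device is built
to produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidParameterError
from .geometry import ChannelGeometry

#: CFL safety factor for the explicit diffusion update.
CFL_SAFETY = 0.5


@dataclass(frozen=True)
class TransportParams:
    """Diffusive transport parameters for the chemoeffector.

    Parameters
    ----------
    D_c:
        Chemoeffector diffusivity in µm²/s.  Small organic acids and
        fluorescein-class dyes are in the 400–1000 µm²/s range in water.
    c_left, c_right:
        Reservoir concentrations (any consistent unit: nM, mM, or an
        effective-attractant unit).  Left is the chemoeffector side.
    membrane_ideal:
        Solutes cross the membrane freely while cells do not.  Always true
        in this version; pore-scale transport is not modeled.
    """

    D_c: float = 500.0
    c_left: float = 0.0
    c_right: float = 0.0
    membrane_ideal: bool = True

    def __post_init__(self) -> None:
        if not self.D_c > 0:
            raise InvalidParameterError("D_c must be strictly positive")
        if self.c_left < 0 or self.c_right < 0:
            raise InvalidParameterError("reservoir concentrations must be >= 0")
        if not self.membrane_ideal:
            raise InvalidParameterError("only the ideal-membrane model is supported")


@dataclass
class ConcentrationField:
    """Chemoeffector concentration c(t, x) across the channel width.

    ``c`` has shape ``(len(times), len(x))``; ``x`` is in µm measured from
    the left (chemoeffector) wall, ``times`` in seconds.
    """

    times: np.ndarray
    x: np.ndarray
    c: np.ndarray
    units: str = "mM"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.c.shape != (self.times.size, self.x.size):
            raise InvalidParameterError(
                f"c has shape {self.c.shape}, expected "
                f"({self.times.size}, {self.x.size})"
            )
        if np.any(self.c < 0):
            raise InvalidParameterError("concentrations must be non-negative")

    def at_time(self, t: float) -> np.ndarray:
        """Concentration profile at the stored time nearest ``t`` (seconds)."""
        i = int(np.argmin(np.abs(self.times - t)))
        return self.c[i]


def _grid(geometry: ChannelGeometry, n_points: int | None) -> np.ndarray:
    if n_points is None:
        n_points = max(geometry.n_cols + 1, 2)
    if n_points < 2:
        raise InvalidParameterError("grid needs at least 2 points")
    return np.linspace(0.0, geometry.width_um, n_points)


def steady_gradient(
    geometry: ChannelGeometry,
    transport: TransportParams,
    times: np.ndarray | None = None,
    n_points: int | None = None,
) -> ConcentrationField:
    """Steady-state linear concentration profile across the channel.

    With constant reservoirs the diffusion equation relaxes to the straight
    line interpolating ``c_left`` at x=0 to ``c_right`` at x=width.  The
    returned field is time-independent; ``times`` only sets the stored time
    axis (default a single t=0 entry).
    """
    x = _grid(geometry, n_points)
    if times is None:
        times = np.array([0.0])
    times = np.asarray(times, dtype=float)
    profile = transport.c_left + (transport.c_right - transport.c_left) * (
        x / geometry.width_um
    )
    c = np.tile(profile, (times.size, 1))
    return ConcentrationField(times=times, x=x, c=c)


def simulate_concentration(
    geometry: ChannelGeometry,
    transport: TransportParams,
    times: np.ndarray,
    n_points: int | None = None,
) -> ConcentrationField:
    """Transient gradient formation after loading the left reservoir.

    Solves ∂c/∂t = D_c ∂²c/∂x² on [0, width] with Dirichlet boundaries
    fixed at the reservoir concentrations, starting from a channel
    uniformly at ``c_right`` (the pre-loading medium).  An explicit
    conservative scheme is used with the step chosen to satisfy the
    diffusive CFL condition with a safety factor of 0.5.

    Parameters
    ----------
    times:
        Strictly increasing output times in seconds, starting at 0.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0 or times[0] != 0.0:
        raise InvalidParameterError("times must start at 0")
    if np.any(np.diff(times) <= 0):
        raise InvalidParameterError("times must be strictly increasing")

    x = _grid(geometry, n_points)
    dx = x[1] - x[0]
    dt = CFL_SAFETY * dx * dx / (2.0 * transport.D_c)
    if not np.isfinite(dt) or dt <= 0:
        raise ConfigurationError(
            f"diffusion step dt={dt!r} is unusable for dx={dx:.3g} µm, "
            f"D_c={transport.D_c:.3g} µm²/s"
        )
    # explicit stability check (always satisfied by construction; kept as a
    # guard should CFL_SAFETY ever be overridden)
    if transport.D_c * dt / dx**2 > 0.5:
        raise ConfigurationError(
            f"CFL violation: D_c*dt/dx² = {transport.D_c * dt / dx**2:.3f} > 0.5 "
            f"(dt={dt:.3g} s, dx={dx:.3g} µm)"
        )

    c = np.full(x.size, transport.c_right, dtype=float)
    c[0], c[-1] = transport.c_left, transport.c_right
    out = np.empty((times.size, x.size))
    out[0] = c
    t_now = 0.0
    for k in range(1, times.size):
        target = times[k]
        n_steps = int(np.ceil((target - t_now) / dt))
        step = (target - t_now) / n_steps
        a = transport.D_c * step / dx**2
        for _ in range(n_steps):
            c[1:-1] += a * (c[2:] - 2.0 * c[1:-1] + c[:-2])
        t_now = target
        out[k] = c
    np.clip(out, 0.0, None, out=out)
    return ConcentrationField(times=times, x=x, c=out)
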