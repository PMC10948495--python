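"""Independent oracles used by the test suite.

These deliberately share no code with the package paths they check:
a brute-force grayscale ball opening, a Fourier-series solution of the
Dirichlet diffusion problem, and an agent-based biased random walk.
"""

from __future__ import annotations

import numpy as np


def brute_force_ball_opening(frame: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale opening with a ball SE by direct min/max over neighborhoods.

    Edge handling replicates border values (matching 'nearest' extension).
    """
    frame = np.asarray(frame, dtype=float)
    r = int(radius)
    u = np.arange(-r, r + 1)
    uu, vv = np.meshgrid(u, u, indexing="ij")
    mask = uu**2 + vv**2 <= r * r
    heights = np.zeros_like(uu, dtype=float)
    heights[mask] = np.sqrt(r * r - (uu**2 + vv**2)[mask])
    offsets = list(zip(uu[mask], vv[mask], heights[mask]))

    def pad(img):
        return np.pad(img, r, mode="edge")

    padded = pad(frame)
    eroded = np.full(frame.shape, np.inf)
    for du, dv, h in offsets:
        shifted = padded[
            r + du : r + du + frame.shape[0], r + dv : r + dv + frame.shape[1]
        ]
        eroded = np.minimum(eroded, shifted - h)
    padded_e = pad(eroded)
    opened = np.full(frame.shape, -np.inf)
    for du, dv, h in offsets:
        shifted = padded_e[
            r + du : r + du + frame.shape[0], r + dv : r + dv + frame.shape[1]
        ]
        opened = np.maximum(opened, shifted + h)
    return opened


def fourier_dirichlet_diffusion(
    x: np.ndarray,
    t: float,
    length: float,
    D: float,
    c_left: float,
    c_right: float,
    n_terms: int = 200,
) -> np.ndarray:
    """Series solution of ∂c/∂t = D ∂²c/∂x², c(0)=c_left, c(L)=c_right,
    starting from c(x, 0) = c_right in the interior."""
    steady = c_left + (c_right - c_left) * x / length
    fine = np.linspace(0.0, length, 4001)
    init = np.full_like(fine, c_right)
    init[0] = c_left
    dev = init - (c_left + (c_right - c_left) * fine / length)
    out = steady.copy()
    for n in range(1, n_terms + 1):
        basis = np.sin(n * np.pi * fine / length)
        b_n = 2.0 / length * np.trapezoid(dev * basis, fine)
        out += (
            b_n
            * np.sin(n * np.pi * x / length)
            * np.exp(-D * (n * np.pi / length) ** 2 * t)
        )
    return out


def biased_random_walk(
    n_agents: int,
    drift: float,
    D: float,
    length: float,
    x0: np.ndarray,
    times: np.ndarray,
    dt: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Euler–Maruyama biased walk on [0, length] with reflecting walls.

    Returns agent positions at each requested time.
    """
    x = np.array(x0, dtype=float)
    sigma = np.sqrt(2.0 * D * dt)
    out = []
    t_now = 0.0
    for target in times:
        n_steps = int(round((target - t_now) / dt))
        for _ in range(n_steps):
            x += drift * dt + sigma * rng.standard_normal(n_agents)
            # reflect off the walls
            x = np.abs(x)
            x = length - np.abs(length - x)
        t_now = target
        out.append(x.copy())
    return out
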