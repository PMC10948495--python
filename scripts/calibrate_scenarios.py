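"""One-time calibration of the effective-attractant scenarios.

The algae and conditioned-media sources are complex mixtures with no
measured attractant concentration, so their chemotactic sensitivity chi
is not a measurable input.  This script sweeps chi for each of those
scenarios, runs the full pipeline (simulate → render → rolling-ball
correct → asymmetry series) over a few seeds, and prints the 9-h
endpoint mean so the value landing in the observed endpoint band can be
frozen into ``chemograd.scenarios._SCENARIO_TABLE``.

The shipped defaults (algae chi = 185, conditioned media chi = 135,
both with r0 = 0.15 1/h Monod growth) came from running:

    python scripts/calibrate_scenarios.py --seeds 4

Usage:
    python scripts/calibrate_scenarios.py [--seeds N] [--scenario NAME]
"""

from __future__ import annotations

import argparse
import dataclasses

import numpy as np

from chemograd import asymmetry_series, correct_stack, simulate_replicate
from chemograd.scenarios import make_scenario

SWEEPS = {
    "algae": [135, 160, 185, 210],
    "conditioned_media": [110, 125, 135, 150],
}
ENDPOINT_MIN = 9 * 60.0
BALL_RADIUS_PX = 20


def endpoint_mean(name: str, chi: float, n_seeds: int) -> tuple[float, float]:
    spec = make_scenario(name)
    spec = dataclasses.replace(
        spec, population=dataclasses.replace(spec.population, chi=float(chi))
    )
    vals = []
    for seed in range(1, n_seeds + 1):
        _, _, stack = simulate_replicate(spec, seed)
        series = asymmetry_series(correct_stack(stack, BALL_RADIUS_PX))
        vals.append(series.at_time(ENDPOINT_MIN))
    return float(np.mean(vals)), float(np.std(vals, ddof=1))


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seeds", type=int, default=4)
    parser.add_argument("--scenario", choices=sorted(SWEEPS), default=None)
    args = parser.parse_args()

    names = [args.scenario] if args.scenario else sorted(SWEEPS)
    for name in names:
        print(f"# {name}")
        for chi in SWEEPS[name]:
            mean, sd = endpoint_mean(name, chi, args.seeds)
            print(f"chi={chi:<6g} endpoint A = {mean:.3f} +/- {sd:.3f}")


if __name__ == "__main__":
    main()
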