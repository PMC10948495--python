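# chemograd

Analysis of flow-free microfluidic chemotaxis assays: how a motile
bacterial population redistributes across an observation channel when a
chemical gradient diffuses in from a side reservoir.

## The assay and the statistic

In a diffusion-based gradient generator, two large reservoirs flank a
rectangular observation channel, separated by a 0.1-µm-pore membrane:
solutes cross freely, cells cannot. Loading a chemoeffector (an organic
acid, an algal culture, or its conditioned medium) into the **left**
reservoir establishes a linear concentration gradient across the channel
width within minutes, stable over the 9-hour experiment. GFP-labelled
bacteria (*Azospirillum brasilense* is the motivating organism) swim in
the channel and are imaged by fluorescence time-lapse microscopy, one
frame every 5 minutes.

The central readout is the **asymmetry index**: split the channel into
two equal halves and compare the mean background-corrected fluorescence
intensities *I*<sub>left</sub> and *I*<sub>right</sub>,

&nbsp;&nbsp;&nbsp;&nbsp;*A* = (*I*<sub>left</sub> − *I*<sub>right</sub>) / (*I*<sub>left</sub> + *I*<sub>right</sub>),

so *A* = +1 means all cells on the chemoeffector side, 0 an even
distribution, −1 all cells on the far side. Accumulation can come both
from chemotactic drift and from position-dependent (differential) growth;
both are modeled.

The package provides:

- **synthetic experiments** (`chemograd.scenarios`): a 1-D
  drift–diffusion–growth (Keller–Segel type) simulation
  ∂b/∂t = D_b ∂²b/∂x² − ∂/∂x(χ b ∂c/∂x) + r(c) b with zero-flux walls,
  a Dirichlet diffusion solver for gradient formation, and a fluorescence
  renderer (discrete cell spots or continuum dye, background structure,
  shot + read noise) — so the whole analysis chain runs without any
  microscope data;
- **image processing** (`chemograd.imageops`, `chemograd.stacks`):
  multi-page TIFF I/O with a YAML metadata sidecar, rolling-ball
  background correction (grayscale opening with a ball structuring
  element), cross-channel intensity profiles, kymographs;
- **metrics** (`chemograd.metrics`): per-frame asymmetry index,
  left/right growth curves, replicate endpoint summaries (mean ± sample
  SD), saturation values over a trailing window;
- **gradient calibration** (`chemograd.calibration`): affine
  intensity→concentration conversion pinned by a uniform-dye control,
  and least-squares linearity checks of the measured gradient;
- **HPLC arithmetic** (`chemograd.hplc`): percent peak area,
  single-point calibration quantification, mg/ml→mM conversion with a
  bundled molecular-weight table for TCA-cycle organic acids;
- a **CLI** (`chemograd simulate|analyze|calibrate|hplc|compare`) that
  orchestrates reproducible runs with config files and fixed seeds.

## Worked example

Simulate three replicates of the algae-gradient scenario, background-correct
each rendered stack, and summarize the asymmetry endpoint:

```python
import numpy as np
from chemograd import (
    make_scenario, simulate_replicate, correct_stack,
    asymmetry_series, saturation_value, summarize_endpoint,
)

series_list = []
for seed in (1, 2, 3):
    _, _, stack = simulate_replicate(make_scenario("algae"), seed)
    corrected = correct_stack(stack, radius_px=20)
    series_list.append(asymmetry_series(corrected))

summary = summarize_endpoint(series_list, endpoint_min=540.0, scenario="algae")
sat = np.mean([saturation_value(s, window_min=60.0) for s in series_list])
print(f"endpoint A (9 h): {summary.mean:.2f} +/- {summary.sd:.2f} (n={len(series_list)})")
print(f"saturation (final hour): {sat:.2f}")
```

This prints:

```
endpoint A (9 h): 0.60 +/- 0.05 (n=3)
saturation (final hour): 0.61
```

meaning the simulated population ends the 9-hour run strongly skewed
toward the chemoeffector side (*A* ≈ 0.6 of a possible 1.0), with the
index already saturated over the final hour — the signature of a strong
attractant. A gradient-free control run the same way fluctuates around
*A* ≈ 0.

The same analysis from the shell, with per-replicate CSV/PNG artifacts
and a cross-replicate summary written to a run directory:

```bash
chemograd analyze --scenario algae -n 3 -s 1 --out runs
chemograd analyze --scenario control -n 3 -s 1 --out runs
chemograd compare runs/algae runs/control
```

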