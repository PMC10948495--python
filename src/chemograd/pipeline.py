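"""End-to-end runs: simulate → correct → profile → metrics → report.

A run produces one directory with flat, diff-able artifacts per
replicate (corrected stack, kymograph, profile CSVs at the start and the
endpoint, asymmetry and growth CSVs) plus a cross-replicate summary and
a provenance record sufficient to reproduce every output byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, InvalidParameterError
from .imageops import ChannelROI, build_kymograph, correct_stack, intensity_profile
from .metrics import (
    DEFAULT_ENDPOINT_MIN,
    DEFAULT_SATURATION_WINDOW_MIN,
    AsymmetrySeries,
    asymmetry_series,
    saturation_value,
    summarize_endpoint,
)
from .scenarios import ScenarioSpec, make_scenario, simulate_replicate
from .stacks import ImageStack, read_stack, write_stack

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    Either ``scenario`` (synthetic) or ``stack_paths`` (acquired TIFFs)
    must be set.  External stacks additionally require an explicit ROI.
    """

    scenario: str | None = None
    stack_paths: list[str] = field(default_factory=list)
    roi: tuple[int, int, int, int] | None = None  # row0, row1, col0, col1
    rolling_ball_radius_px: int = 20
    endpoint_min: float = DEFAULT_ENDPOINT_MIN
    saturation_window_min: float = DEFAULT_SATURATION_WINDOW_MIN
    replicates: int = 5
    seed: int = 0
    out_dir: str = "runs"
    log_level: str = "INFO"
    write_tiffs: bool = True
    write_plots: bool = True

    def validate(self) -> None:
        if (self.scenario is None) == (not self.stack_paths):
            raise ConfigurationError(
                "exactly one of 'scenario' or 'stack_paths' must be set"
            )
        if self.stack_paths and self.roi is None:
            raise ConfigurationError(
                "missing required field 'roi': external stacks need an "
                "explicit channel ROI (row_start, row_stop, col_start, col_stop)"
            )
        if self.rolling_ball_radius_px < 1:
            raise ConfigurationError("rolling_ball_radius_px must be >= 1")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields {sorted(unknown)}")
        if data.get("roi") is not None:
            data["roi"] = tuple(data["roi"])
        return cls(**data)


def _channel_roi(config: RunConfig, stack: ImageStack) -> ChannelROI:
    if config.roi is None:
        return ChannelROI.full_frame(stack.shape)
    r0, r1, c0, c1 = config.roi
    return ChannelROI(r0, r1, c0, c1)


def _write_profile_csv(path: Path, stack: ImageStack, roi: ChannelROI, t_min: float) -> None:
    i = int(np.argmin(np.abs(stack.times_min - t_min)))
    prof = intensity_profile(stack.frames[i], roi, stack.pixel_size_um, t_min)
    pd.DataFrame({"x_um": prof.x_um, "intensity": prof.intensity}).to_csv(
        path, index=False, float_format="%.6g"
    )


def _analyze_replicate(
    stack: ImageStack, config: RunConfig, rep_dir: Path
) -> AsymmetrySeries:
    rep_dir.mkdir(parents=True, exist_ok=True)
    roi = _channel_roi(config, stack)
    t_start = time.perf_counter()
    stack_hash = hashlib.sha1(stack.frames.tobytes()).hexdigest()[:12]
    corrected = correct_stack(stack, config.rolling_ball_radius_px)
    logger.info(
        "stage=correct rep=%s frames=%d hash=%s radius_px=%d elapsed_s=%.2f",
        rep_dir.name,
        len(stack),
        stack_hash,
        config.rolling_ball_radius_px,
        time.perf_counter() - t_start,
    )
    if config.write_tiffs:
        write_stack(stack, rep_dir / "stack.tif")
    series = asymmetry_series(corrected, roi)
    kymo = build_kymograph(corrected, roi)

    pd.DataFrame(
        {
            "time_min": series.time_min,
            "A": series.A,
            "I_left": series.I_left,
            "I_right": series.I_right,
        }
    ).to_csv(rep_dir / "asymmetry.csv", index=False, float_format="%.6g")
    pd.DataFrame(
        {
            "time_min": series.time_min,
            "mean_left": series.I_left,
            "mean_right": series.I_right,
        }
    ).to_csv(rep_dir / "growth_curves.csv", index=False, float_format="%.6g")
    _write_profile_csv(rep_dir / "profile_t0.csv", corrected, roi, 0.0)
    _write_profile_csv(
        rep_dir / "profile_endpoint.csv", corrected, roi, config.endpoint_min
    )

    if config.write_plots:
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.plot(series.time_min / 60, series.A)
        ax.set(xlabel="time (h)", ylabel="asymmetry index A", ylim=(-1, 1))
        fig.tight_layout()
        fig.savefig(rep_dir / "asymmetry.png", dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(4, 5))
        ax.imshow(
            kymo.rows,
            aspect="auto",
            origin="upper",
            extent=(kymo.x_um[0], kymo.x_um[-1], kymo.time_min[-1], 0),
            cmap="viridis",
        )
        ax.set(xlabel="x (µm)", ylabel="time (min)")
        fig.tight_layout()
        fig.savefig(rep_dir / "kymograph.png", dpi=120)
        plt.close(fig)
    return series


def run_experiment(config: RunConfig, run_dir: str | Path | None = None) -> Path:
    """Execute a full run; returns the run directory.

    Per-replicate failures are logged and skipped; a run where any
    replicate failed raises :class:`ConfigurationError` after writing
    what it could (the CLI maps this to a nonzero exit status).
    """
    config.validate()
    run_dir = Path(run_dir) if run_dir is not None else Path(config.out_dir) / (
        config.scenario or "external"
    )
    run_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    spec: ScenarioSpec | None = None
    if config.scenario is not None:
        spec = make_scenario(
            config.scenario, replicates=config.replicates, seed=config.seed
        )
        seeds = spec.replicate_seeds(config.seed)
        sources: list = list(seeds)
    else:
        sources = list(config.stack_paths)

    series_list: list[AsymmetrySeries] = []
    sat_values: list[float] = []
    final_lr: list[tuple[float, float]] = []
    failures = 0
    for r, src in enumerate(sources, start=1):
        rep_dir = run_dir / f"rep{r:02d}"
        try:
            if spec is not None:
                logger.info("simulating %s replicate %d (seed %s)", spec.name, r, src)
                _, _, stack = simulate_replicate(spec, int(src))
            else:
                logger.info("loading stack %s", src)
                stack = read_stack(src)
            series = _analyze_replicate(stack, config, rep_dir)
            series_list.append(series)
            sat_values.append(
                saturation_value(series, config.saturation_window_min)
            )
            final_lr.append((float(series.I_left[-1]), float(series.I_right[-1])))
        except Exception:
            failures += 1
            logger.exception("replicate %d failed", r)

    if series_list:
        summary = summarize_endpoint(
            series_list, config.endpoint_min, scenario=config.scenario or "external"
        )
        pd.DataFrame(
            {
                "scenario": [summary.scenario],
                "endpoint_min": [summary.endpoint_min],
                "n": [summary.values.size],
                "mean_A": [summary.mean],
                "sd_A": [summary.sd],
                "saturation_mean": [float(np.nanmean(sat_values))],
                "final_left": [float(np.mean([v[0] for v in final_lr]))],
                "final_right": [float(np.mean([v[1] for v in final_lr]))],
            }
        ).to_csv(run_dir / "summary.csv", index=False, float_format="%.6g")
        pd.DataFrame(
            {
                "replicate": np.arange(1, summary.values.size + 1),
                "A_endpoint": summary.values,
                "saturation": sat_values,
            }
        ).to_csv(run_dir / "endpoints.csv", index=False, float_format="%.6g")

    provenance = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "replicate_sources": [str(s) for s in sources],
        "failures": failures,
    }
    (run_dir / "provenance.yaml").write_text(
        yaml.safe_dump(provenance, sort_keys=False)
    )
    config.to_yaml(run_dir / "config.yaml")

    if failures:
        raise ConfigurationError(
            f"{failures} of {len(sources)} replicates failed; see logs and "
            f"{run_dir / 'provenance.yaml'}"
        )
    return run_dir


def compare_scenarios(run_dirs: list[str | Path]) -> pd.DataFrame:
    """Cross-scenario comparison table from completed run directories."""
    if len(run_dirs) < 2:
        raise InvalidParameterError("need at least 2 completed runs to compare")
    rows = []
    for d in run_dirs:
        summary_path = Path(d) / "summary.csv"
        if not summary_path.exists():
            raise InvalidParameterError(f"{d} has no summary.csv (incomplete run?)")
        rows.append(pd.read_csv(summary_path))
    table = pd.concat(rows, ignore_index=True)
    endpoints = table["endpoint_min"].unique()
    if endpoints.size > 1:
        raise InvalidParameterError(
            f"runs have incompatible endpoints: {sorted(endpoints)}"
        )
    return table
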