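"""Simulation harness validating the stability-point estimator.

Synthetic populations with known size N and true prevalence p are handed
to the estimator as if they were field data (the population itself is the
dataset, so k_MAX = N). The harness covers:

* a factorial grid over N in {100, 1000, 10000}, p in {10%..90% step 10%}
  and replicate counts n in {10..100 step 10, 200, 500} with the detector
  at its defaults — 324 cells;
* a detector-parameter sweep (x in {2, 10, 50}, y in {1, 2, 5, 10},
  z in {0.5, 1, 2}) on the focal case N = 1000, p = 50%, n = 50;
* repeated runs of a single case to quantify the stochasticity of the
  stability point;
* the closed-form SRSWOR standard error with finite-population
  correction, the analytic reference for the sampling noise on the curve.

Stability points are hardest (largest) at mid prevalence because the
variance p(1-p) of the underlying binomial-like draw peaks at p = 0.5.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import detect_stability, resample_prevalence_curve
from .types import StabilityParams

__all__ = [
    "PopulationSpec",
    "RepeatSummary",
    "make_population",
    "run_single",
    "run_default_grid",
    "run_parameter_sweep",
    "repeat_runs",
    "expected_se",
    "summarize_grid",
    "load_config",
    "run_from_config",
    "GRID_SIZES",
    "GRID_PREVALENCES",
    "GRID_REPLICATES",
    "SWEEP_SUCCESSIVE_POINTS",
    "SWEEP_MEAN_DIFF",
    "SWEEP_DELTA",
]

GRID_SIZES = (100, 1000, 10000)
GRID_PREVALENCES = tuple(round(0.1 * i, 1) for i in range(1, 10))
GRID_REPLICATES = tuple(range(10, 101, 10)) + (200, 500)

SWEEP_SUCCESSIVE_POINTS = (2, 10, 50)
SWEEP_MEAN_DIFF = (1.0, 2.0, 5.0, 10.0)
SWEEP_DELTA = (0.5, 1.0, 2.0)

GRID_COLUMNS = [
    "population_size",
    "true_prevalence",
    "n_replicates",
    "successive_points",
    "mean_diff_threshold",
    "delta_threshold",
    "run_index",
    "stability_point",
    "estimated_prevalence",
    "abs_error_pp",
]


@dataclasses.dataclass(frozen=True)
class PopulationSpec:
    """A synthetic population: ``round(N * p)`` presences among N units."""

    population_size: int
    true_prevalence: float

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be positive")
        if not 0.0 <= self.true_prevalence <= 1.0:
            raise ValueError("true_prevalence must lie in [0, 1]")


@dataclasses.dataclass(frozen=True)
class RepeatSummary:
    """Mean +/- sd of the stability point over repeated independent runs."""

    mean_stability_point: float
    sd_stability_point: float
    runs: int
    na_count: int
    stability_points: tuple = ()
    note: str = ""


def make_population(spec: PopulationSpec) -> np.ndarray:
    """Binary vector of length N with exactly round(N*p) ones."""
    n_ones = int(round(spec.population_size * spec.true_prevalence))
    pop = np.zeros(spec.population_size, dtype=np.int64)
    pop[:n_ones] = 1
    return pop


def expected_se(p: float, k: int, n_population: int) -> float:
    """SRSWOR standard error of a prevalence estimate, percentage points.

    ``100 * sqrt(p (1-p) / k * (N-k)/(N-1))`` — the hypergeometric sd of a
    size-k sample proportion from a population of N with proportion p. The
    finite-population correction (N-k)/(N-1) drives the SE to 0 at k = N.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if not 1 <= k <= n_population:
        raise ValueError(f"k must lie in [1, N={n_population}], got {k}")
    if k == n_population:
        return 0.0
    fpc = (n_population - k) / (n_population - 1)
    return 100.0 * math.sqrt(p * (1.0 - p) / k * fpc)


def run_single(
    spec: PopulationSpec,
    params: StabilityParams,
    rng: np.random.Generator | None = None,
    *,
    resampling: str = "cumulative",
    run_index: int = 0,
) -> dict:
    """One grid record: build the population, estimate, measure the error."""
    pop = make_population(spec)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    curve = resample_prevalence_curve(
        pop, params, rng, resampling=resampling,
        group=f"N={spec.population_size}", species=f"p={spec.true_prevalence}",
    )
    res = detect_stability(curve, params)
    est = res.estimated_prevalence
    err = abs(est - 100.0 * spec.true_prevalence) if res.stability_point is not None else math.nan
    return {
        "population_size": spec.population_size,
        "true_prevalence": spec.true_prevalence,
        "n_replicates": params.n_replicates,
        "successive_points": params.successive_points,
        "mean_diff_threshold": params.mean_diff_threshold,
        "delta_threshold": params.delta_threshold,
        "run_index": run_index,
        "stability_point": math.nan if res.stability_point is None else res.stability_point,
        "estimated_prevalence": est,
        "abs_error_pp": err,
    }


def _cell_rng(seed: int | None, index: int) -> np.random.Generator:
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0xFFFFFFFF, index]))


def run_default_grid(
    seed: int | None = None,
    *,
    sizes: Sequence[int] = GRID_SIZES,
    prevalences: Sequence[float] = GRID_PREVALENCES,
    replicates: Sequence[int] = GRID_REPLICATES,
    successive_points: int = 10,
    mean_diff_threshold: float = 2.0,
    delta_threshold: float = 1.0,
    resampling: str = "cumulative",
) -> pd.DataFrame:
    """Factorial N x p x n grid with detector defaults (324 cells).

    Each cell gets an independent child random stream derived from
    ``seed`` and the cell index, so cells are individually reproducible.
    """
    records = []
    for idx, (n_pop, p, n_rep) in enumerate(
        itertools.product(sizes, prevalences, replicates)
    ):
        params = StabilityParams(
            n_replicates=n_rep,
            successive_points=successive_points,
            mean_diff_threshold=mean_diff_threshold,
            delta_threshold=delta_threshold,
            seed=seed,
        )
        records.append(
            run_single(
                PopulationSpec(n_pop, p), params, _cell_rng(seed, idx), resampling=resampling
            )
        )
    return pd.DataFrame.from_records(records, columns=GRID_COLUMNS)


def run_parameter_sweep(
    seed: int | None = None,
    *,
    population_size: int = 1000,
    true_prevalence: float = 0.5,
    n_replicates: int = 50,
    successive_points: Sequence[int] = SWEEP_SUCCESSIVE_POINTS,
    mean_diff_thresholds: Sequence[float] = SWEEP_MEAN_DIFF,
    delta_thresholds: Sequence[float] = SWEEP_DELTA,
    resampling: str = "cumulative",
) -> pd.DataFrame:
    """Detector-parameter sweep on the focal N=1000, p=50%, n=50 case (36 cells)."""
    spec = PopulationSpec(population_size, true_prevalence)
    records = []
    for idx, (x, y, z) in enumerate(
        itertools.product(successive_points, mean_diff_thresholds, delta_thresholds)
    ):
        params = StabilityParams(
            n_replicates=n_replicates,
            successive_points=x,
            mean_diff_threshold=y,
            delta_threshold=z,
            seed=seed,
        )
        records.append(run_single(spec, params, _cell_rng(seed, idx), resampling=resampling))
    return pd.DataFrame.from_records(records, columns=GRID_COLUMNS)


def repeat_runs(
    spec: PopulationSpec,
    params: StabilityParams,
    runs: int,
    seed: int | None = None,
    *,
    resampling: str = "cumulative",
) -> RepeatSummary:
    """Run the full estimator ``runs`` times with independent seeds.

    Quantifies the intrinsic stochasticity of the stability point; users
    are advised to average at least five runs on real data. With a single
    run the sd is reported as 0 by convention and flagged in ``note``.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    points = []
    for i in range(runs):
        rec = run_single(spec, params, _cell_rng(seed, i), resampling=resampling, run_index=i)
        points.append(rec["stability_point"])
    finite = [p for p in points if not math.isnan(p)]
    na_count = runs - len(finite)
    if not finite:
        return RepeatSummary(math.nan, math.nan, runs, na_count, tuple(points), note="all runs na")
    mean = float(np.mean(finite))
    if len(finite) < 2:
        return RepeatSummary(
            mean, 0.0, runs, na_count, tuple(points), note="sd undefined for a single run; 0 by convention"
        )
    return RepeatSummary(mean, float(np.std(finite, ddof=1)), runs, na_count, tuple(points))


def summarize_grid(df: pd.DataFrame) -> dict:
    """Headline summaries of a grid result table.

    Means are taken over cells with a finite stability point; the NA count
    is reported alongside.
    """
    sp = df["stability_point"]
    finite = df[sp.notna()]
    by_p = finite.groupby("true_prevalence")["stability_point"].mean()
    extreme = finite[finite["true_prevalence"].isin([0.1, 0.9])]
    mid = finite[finite["true_prevalence"].isin([0.4, 0.5, 0.6])]
    errs = finite["abs_error_pp"].dropna()
    return {
        "n_cells": int(len(df)),
        "n_na": int(sp.isna().sum()),
        "grand_mean_stability_point": float(finite["stability_point"].mean()),
        "mean_stability_point_by_prevalence": {float(k): float(v) for k, v in by_p.items()},
        "mean_stability_point_extreme_prevalence": float(extreme["stability_point"].mean())
        if len(extreme)
        else math.nan,
        "mean_stability_point_mid_prevalence": float(mid["stability_point"].mean())
        if len(mid)
        else math.nan,
        "median_abs_error_pp": float(errs.median()) if len(errs) else math.nan,
        "q90_abs_error_pp": float(errs.quantile(0.9)) if len(errs) else math.nan,
    }


_CONFIG_KEYS = {
    "mode",
    "seed",
    "resampling",
    "sizes",
    "prevalences",
    "replicates",
    "successive_points",
    "mean_diff_threshold",
    "delta_threshold",
    "population_size",
    "true_prevalence",
    "n_replicates",
    "runs",
}


def load_config(path: str | Path) -> dict:
    """Load and check a simulation config (YAML key-value file)."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping) or not cfg:
        raise ValueError("simulation config is empty or not a key-value mapping")
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    mode = cfg.get("mode", "grid")
    if mode not in ("grid", "sweep", "repeat"):
        raise ValueError(f"config key 'mode' must be grid, sweep or repeat, got {mode!r}")
    return dict(cfg, mode=mode)


def run_from_config(cfg: Mapping, seed: int | None = None) -> tuple[pd.DataFrame | None, dict]:
    """Execute a simulation described by a config mapping.

    Returns ``(records, summary)``; ``records`` is None for repeat mode.
    A ``seed`` argument overrides the config's seed.
    """
    mode = cfg.get("mode", "grid")
    seed = cfg.get("seed") if seed is None else seed
    resampling = cfg.get("resampling", "cumulative")
    if mode == "grid":
        df = run_default_grid(
            seed,
            sizes=cfg.get("sizes", GRID_SIZES),
            prevalences=cfg.get("prevalences", GRID_PREVALENCES),
            replicates=cfg.get("replicates", GRID_REPLICATES),
            successive_points=cfg.get("successive_points", 10),
            mean_diff_threshold=cfg.get("mean_diff_threshold", 2.0),
            delta_threshold=cfg.get("delta_threshold", 1.0),
            resampling=resampling,
        )
        return df, summarize_grid(df)
    if mode == "sweep":
        df = run_parameter_sweep(
            seed,
            population_size=cfg.get("population_size", 1000),
            true_prevalence=cfg.get("true_prevalence", 0.5),
            n_replicates=cfg.get("n_replicates", 50),
            resampling=resampling,
        )
        by_x = df.groupby("successive_points")["stability_point"].mean()
        return df, {
            "n_cells": int(len(df)),
            "n_na": int(df["stability_point"].isna().sum()),
            "mean_stability_point_by_successive_points": {
                int(k): float(v) for k, v in by_x.items()
            },
        }
    # repeat
    spec = PopulationSpec(cfg.get("population_size", 1000), cfg.get("true_prevalence", 0.5))
    params = StabilityParams(
        n_replicates=cfg.get("n_replicates", 50),
        successive_points=cfg.get("successive_points", 10),
        mean_diff_threshold=cfg.get("mean_diff_threshold", 2.0),
        delta_threshold=cfg.get("delta_threshold", 1.0),
        seed=seed,
    )
    summary = repeat_runs(spec, params, cfg.get("runs", 10), seed, resampling=resampling)
    return None, dataclasses.asdict(summary)
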