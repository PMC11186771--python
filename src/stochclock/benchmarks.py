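"""Headline synthetic benchmarks: the package's reference experiments.

Each benchmark runs a full simulate-train-validate pipeline at the study
conditions and reports one metric (validation Pearson r or R²) as the
median over independent repeats with different ground states.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Callable

import numpy as np

from .evaluation import EvalReport, run_bulk_experiment, \
    run_methylation_experiment

__all__ = ["Benchmark", "BENCHMARKS", "run_benchmark"]


@dataclass(frozen=True)
class Benchmark:
    name: str
    metric: str  # "pearson_r" | "r_squared"
    repeats: int
    runner: Callable[..., EvalReport]
    kwargs: dict
    description: str


BENCHMARKS: dict[str, Benchmark] = {}


def _register(name, metric, repeats, runner, description, **kwargs):
    BENCHMARKS[name] = Benchmark(name, metric, repeats, runner, kwargs,
                                 description)


_register(
    "bulk_clamped", "pearson_r", 3, run_bulk_experiment,
    "clamped bulk clock, 2000 features, 6x100 samples, plateau sigma",
    n_features=2000, per_step_sd=0.05, mode="clamped")
_register(
    "bulk_logit", "pearson_r", 3, run_bulk_experiment,
    "logit-space accumulation mapped back through expit",
    n_features=2000, per_step_sd=0.2, mode="logit")
_register(
    "bulk_small_sigma", "r_squared", 3, run_bulk_experiment,
    "per-step sigma 0.005, smaller than the 0.01 baseline jitter",
    n_features=2000, per_step_sd=0.005, mode="clamped")
_register(
    "bulk_feature_plateau", "r_squared", 3, run_bulk_experiment,
    "feature-count sweep plateau point, 2000 features",
    n_features=2000, per_step_sd=0.05, mode="clamped")
_register(
    "single_cell_999", "r_squared", 3, run_methylation_experiment,
    "500 features, 1000 cells, universal E_m = E_u = 99.9%",
    n_features=500, e_m=0.999, n_cells=1000)
_register(
    "single_cell_99995", "r_squared", 3, run_methylation_experiment,
    "as single_cell_999 with maintenance raised to 99.995%",
    n_features=500, e_m=0.99995, n_cells=1000)
_register(
    "single_cell_32_features", "r_squared", 10, run_methylation_experiment,
    "feature-count sweep plateau point of the 99.9% single-cell clock",
    n_features=32, e_m=0.999, n_cells=1000)
_register(
    "equilibrium_start_051", "pearson_r", 3, run_methylation_experiment,
    "all features start at 0.51 with equilibrium 0.5: regression toward "
    "equilibrium carries the age signal (2000-feature default)",
    n_features=2000, e_m=0.999, ground_const=0.51, n_cells=1000)


def run_benchmark(name: str, seed: int = 1, repeats: int | None = None,
                  ) -> tuple[float, int]:
    """Median metric over independent repeats; returns (value, n_validation)."""
    bench = BENCHMARKS[name]
    repeats = repeats or bench.repeats
    children = np.random.SeedSequence(seed).spawn(repeats)
    values, n = [], 0
    for child in children:
        child_seed = int(child.generate_state(1)[0] % (2**31))
        report = bench.runner(seed=child_seed, **bench.kwargs)
        values.append(getattr(report, bench.metric))
        n = report.n
    return float(median(values)), n
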