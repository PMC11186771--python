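"""Single-cell DNA-methylation maintenance dynamics.

Each CpG site (feature) is represented by a population of ``n_cells``
binary cells.  Per time-step a methylated cell stays methylated with
probability E_m (maintenance efficiency) and an unmethylated cell gains
methylation with probability E_d (de novo efficiency); E_u = 1 - E_d is
the maintenance efficiency of the unmethylated state.  The bulk beta
value of a site is the methylated fraction of its cells.

The per-feature methylated count is advanced with the exact aggregate of
the per-cell coin flips,

    count' ~ Binomial(count, E_m) + Binomial(n_cells - count, E_d),

which is distributionally identical to flipping every cell independently
(cells are exchangeable) and orders of magnitude cheaper.  The expected
beta obeys E[b_{t+1}] = b_t E_m + (1 - b_t) E_d and converges
geometrically, with factor (E_m - E_d), to the equilibrium

    M_eq = E_d / (1 + E_d - E_m).

An event-based (Gillespie) variant draws exponential waiting times
between single-cell switch events instead of using discrete steps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .bulk import GroundState, LabeledDataset

__all__ = [
    "RateLimits",
    "DEFAULT_LIMITS",
    "IMPROVED_LIMITS",
    "MaintenanceRates",
    "MethylationPopulation",
    "GillespieConfig",
    "equilibrium",
    "estimate_rates",
    "init_population",
    "step_population",
    "simulate_methylation_dataset",
    "gillespie_dataset",
]


class RateLimits(NamedTuple):
    """Open/closed validity bounds: e_m_low < E_m <= e_m_high, e_d_low <= E_d < e_d_high."""

    e_m_low: float = 0.95
    e_m_high: float = 1.0
    e_d_low: float = 0.0
    e_d_high: float = 0.23


#: biologically meaningful region reported across maintenance-rate studies
DEFAULT_LIMITS = RateLimits(0.95, 1.0, 0.0, 0.23)
#: narrower region that best matches first-generation clock behaviour
IMPROVED_LIMITS = RateLimits(0.97, 1.0, 0.0, 0.05)


@dataclass(frozen=True)
class MaintenanceRates:
    """Per-feature maintenance (E_m) and de novo (E_d) efficiencies."""

    e_m: np.ndarray
    e_d: np.ndarray
    limits: RateLimits = DEFAULT_LIMITS
    provenance: str = "universal"

    def __post_init__(self):
        e_m = np.atleast_1d(np.asarray(self.e_m, dtype=float))
        e_d = np.atleast_1d(np.asarray(self.e_d, dtype=float))
        if e_m.shape != e_d.shape:
            raise ValueError("e_m and e_d must have the same shape")
        if np.any((e_m < 0) | (e_m > 1)) or np.any((e_d < 0) | (e_d > 1)):
            raise ValueError("rates are probabilities and must lie in [0, 1]")
        object.__setattr__(self, "e_m", e_m)
        object.__setattr__(self, "e_d", e_d)

    @property
    def e_u(self) -> np.ndarray:
        return 1.0 - self.e_d

    @property
    def n_features(self) -> int:
        return self.e_m.size

    def within_limits(self) -> np.ndarray:
        lo_m, hi_m, lo_d, hi_d = self.limits
        return ((self.e_m > lo_m) & (self.e_m <= hi_m)
                & (self.e_d >= lo_d) & (self.e_d < hi_d))

    @classmethod
    def universal(cls, n_features: int, e_m: float, e_d: float | None = None,
                  limits: RateLimits = DEFAULT_LIMITS) -> "MaintenanceRates":
        """Same rates at every site; by default E_u = E_m (so E_d = 1 - E_m)."""
        if e_d is None:
            e_d = 1.0 - e_m
        return cls(np.full(n_features, e_m), np.full(n_features, e_d),
                   limits, "universal")

    @classmethod
    def random(cls, n_features: int, seed: int,
               limits: RateLimits = DEFAULT_LIMITS) -> "MaintenanceRates":
        """Site-specific rates drawn uniformly inside the limits."""
        rng = np.random.default_rng(seed)
        lo_m, hi_m, lo_d, hi_d = limits
        return cls(rng.uniform(lo_m, hi_m, n_features),
                   rng.uniform(lo_d, hi_d, n_features), limits, "random")


def equilibrium(rates: MaintenanceRates) -> np.ndarray:
    """Site-specific equilibrium M_eq = E_d / (1 + E_d - E_m).

    Perfectly maintained sites (E_m = 1 and E_d = 0) have no unique
    equilibrium (0/0); they are flagged as NaN.
    """
    e_m, e_d = rates.e_m, rates.e_d
    denom = 1.0 + e_d - e_m
    perfect = (e_m == 1.0) & (e_d == 0.0)
    if np.any(denom[~perfect] <= 0):
        raise ValueError("equilibrium undefined: 1 + E_d - E_m must be > 0")
    out = np.empty_like(e_m)
    out[perfect] = np.nan
    out[~perfect] = e_d[~perfect] / denom[~perfect]
    return out


def estimate_rates(target_meq: np.ndarray, limits: RateLimits = DEFAULT_LIMITS,
                   fix_side: str = "fix_em", seed: int = 0,
                   max_tries: int = 1000) -> MaintenanceRates:
    """Site-specific rates whose equilibrium matches an observed methylation state.

    The empirical recipe: take the oldest sample's beta values as the
    site-specific equilibria (an approximation — old sites need not have
    converged), fix one rate by drawing it uniformly within its validity
    limits, and solve the equilibrium equation for the other:

        E_d = M_eq (1 - E_m) / (1 - M_eq)   (E_m fixed)
        E_m = 1 - E_d (1 - M_eq) / M_eq     (E_d fixed)

    redrawing until both rates fall inside the limits.  Degenerate targets
    short-circuit: M_eq = 0 forces E_d = 0, M_eq = 1 forces E_m = 1.
    """
    if fix_side not in ("fix_em", "fix_ed"):
        raise ValueError("fix_side must be 'fix_em' or 'fix_ed'")
    meq = np.atleast_1d(np.asarray(target_meq, dtype=float))
    if np.any((meq < 0) | (meq > 1)):
        raise ValueError("target equilibria must lie in [0, 1]")
    lo_m, hi_m, lo_d, hi_d = limits
    rng = np.random.default_rng(seed)
    e_m = np.empty_like(meq)
    e_d = np.empty_like(meq)
    for i, m in enumerate(meq):
        if m == 0.0:
            e_d[i] = 0.0
            e_m[i] = rng.uniform(lo_m, hi_m) if fix_side == "fix_em" else hi_m
            continue
        if m == 1.0:
            e_m[i] = 1.0
            e_d[i] = rng.uniform(lo_d, hi_d) if fix_side == "fix_ed" else lo_d
            continue
        for _ in range(max_tries):
            if fix_side == "fix_em":
                em = rng.uniform(lo_m, hi_m)
                ed = m * (1.0 - em) / (1.0 - m)
            else:
                ed = rng.uniform(lo_d, hi_d)
                em = 1.0 - ed * (1.0 - m) / m
            if lo_m < em <= hi_m and lo_d <= ed < hi_d:
                e_m[i], e_d[i] = em, ed
                break
        else:
            raise RuntimeError(
                f"estimate_rates: no admissible rates for feature {i} "
                f"(target equilibrium {m:.4g}) in {max_tries} draws"
            )
    return MaintenanceRates(e_m, e_d, limits, "estimated")


@dataclass
class MethylationPopulation:
    """Per-feature methylated-cell counts out of ``n_cells`` binary cells."""

    methylated_counts: np.ndarray
    n_cells: int = 1000

    def __post_init__(self):
        counts = np.asarray(self.methylated_counts)
        if np.any((counts < 0) | (counts > self.n_cells)):
            raise ValueError("counts must lie in [0, n_cells]")
        self.methylated_counts = counts.astype(np.int64)

    @property
    def betas(self) -> np.ndarray:
        return self.methylated_counts / self.n_cells


def init_population(ground: GroundState, n_cells: int = 1000) -> MethylationPopulation:
    """Round-half-up ground betas to cell counts (0.13 -> 130 of 1000 cells)."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    counts = np.floor(ground.values * n_cells + 0.5).astype(np.int64)
    return MethylationPopulation(counts, n_cells)


def step_population(pop: MethylationPopulation, rates: MaintenanceRates,
                    rng: np.random.Generator) -> MethylationPopulation:
    """One maintenance time-step: the exact aggregate of per-cell coin flips."""
    m = pop.methylated_counts
    if rates.n_features != m.size:
        raise ValueError("rates must align with population features")
    kept = rng.binomial(m, rates.e_m)
    gained = rng.binomial(pop.n_cells - m, rates.e_d)
    return MethylationPopulation(kept + gained, pop.n_cells)


def simulate_methylation_dataset(ground: GroundState, rates: MaintenanceRates,
                                 max_age: int = 100, n_sets: int = 6,
                                 n_cells: int = 1000, seed: int = 0,
                                 age_start: int = 0) -> LabeledDataset:
    """Replicate sets of bulk betas, one independent sample per age.

    Ages run 0..max_age-1 by default (100 age steps).  Every sample
    restarts from the ground-state population and advances ``age``
    maintenance steps with its own RNG stream, mirroring the independent
    per-sample design of the bulk simulations.
    """
    if max_age < 1 or n_sets < 1:
        raise ValueError("max_age and n_sets must be >= 1")
    ages = np.arange(age_start, age_start + max_age)
    streams = np.random.SeedSequence(seed).spawn(n_sets * len(ages))
    start = init_population(ground, n_cells)
    rows, out_ages, out_sets = [], [], []
    k = 0
    for s in range(n_sets):
        for a in ages:
            rng = np.random.default_rng(streams[k]); k += 1
            pop = MethylationPopulation(start.methylated_counts.copy(), n_cells)
            for _ in range(int(a)):
                pop = step_population(pop, rates, rng)
            rows.append(pop.betas)
            out_ages.append(a)
            out_sets.append(s)
    return LabeledDataset(np.asarray(rows), np.asarray(out_ages),
                          np.asarray(out_sets), ground.feature_ids, "clamped")


@dataclass(frozen=True)
class GillespieConfig:
    """Event-based simulation parameters.

    Two reactions per site: unmethylated -> methylated at rate
    ``switch_rate_on`` per cell and the reverse at ``switch_rate_off``;
    waiting times between events are exponential in the total propensity.
    ``nrmax`` caps the number of events per site trajectory.
    """

    switch_rate_on: float = 0.1
    switch_rate_off: float = 0.1
    tmax: float = 5.0
    nrmax: int = 8000
    seed: int = 0

    def __post_init__(self):
        if self.switch_rate_on <= 0 or self.switch_rate_off <= 0:
            raise ValueError("switch rates must be > 0")
        if self.tmax <= 0 or self.nrmax < 1:
            raise ValueError("tmax must be > 0 and nrmax >= 1")


def _gillespie_site(m0: int, n_cells: int, cfg: GillespieConfig,
                    obs_times: np.ndarray, rng: np.random.Generator):
    """One site trajectory; returns methylated counts at the observation times."""
    m, t, events = m0, 0.0, 0
    out = np.empty(obs_times.size, dtype=np.int64)
    idx = 0
    truncated = False
    while idx < obs_times.size:
        a_on = cfg.switch_rate_on * (n_cells - m)
        a_off = cfg.switch_rate_off * m
        total = a_on + a_off
        t_next = np.inf if total == 0 else t + rng.exponential(1.0 / total)
        while idx < obs_times.size and obs_times[idx] < t_next:
            out[idx] = m
            idx += 1
        if idx >= obs_times.size:
            break
        if events >= cfg.nrmax:
            truncated = True
            while idx < obs_times.size:
                out[idx] = m
                idx += 1
            break
        t = t_next
        m += 1 if rng.uniform() * total < a_on else -1
        events += 1
    return out, truncated


def gillespie_dataset(ground: GroundState, cfg: GillespieConfig,
                      n_samples_per_time: int = 3, n_timepoints: int = 21,
                      n_cells: int = 100, age_scale: float = 100.0,
                      ) -> LabeledDataset:
    """Event-based methylation dataset observed on an even time grid.

    For each replicate set and feature a single two-reaction trajectory is
    simulated to ``tmax`` (or ``nrmax`` events, with a warning) and the
    bulk beta recorded at ``n_timepoints`` evenly spaced observation times
    including 0 and tmax.  Observation times are min-max rescaled to
    [0, age_scale] so reported ages share the range of step-based clocks
    (the rescaling leaves correlations untouched).
    """
    import warnings

    obs = np.linspace(0.0, cfg.tmax, n_timepoints)
    start = init_population(ground, n_cells)
    streams = np.random.SeedSequence(cfg.seed).spawn(
        n_samples_per_time * ground.n_features)
    rows = np.empty((n_samples_per_time, n_timepoints, ground.n_features))
    any_truncated = False
    k = 0
    for s in range(n_samples_per_time):
        for j in range(ground.n_features):
            rng = np.random.default_rng(streams[k]); k += 1
            counts, truncated = _gillespie_site(
                int(start.methylated_counts[j]), n_cells, cfg, obs, rng)
            any_truncated |= truncated
            rows[s, :, j] = counts / n_cells
    if any_truncated:
        warnings.warn("gillespie_dataset: nrmax reached before tmax; "
                      "trajectories truncated at the last event state")
    ages = obs / cfg.tmax * age_scale
    matrix = rows.reshape(-1, ground.n_features)
    out_ages = np.tile(ages, n_samples_per_time)
    out_sets = np.repeat(np.arange(n_samples_per_time), n_timepoints)
    return LabeledDataset(matrix, out_ages, out_sets, ground.feature_ids,
                          "clamped")
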