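"""Bulk stochastic-variation accumulation simulations.

A *ground state* is a per-feature vector of fractions in [0, 1] defining
"age zero".  A sample of simulated age ``a`` is produced by adding one
baseline jitter draw and then ``a`` independent draws of per-step normal
noise to the ground state.  Because the values are bounded (clamped to
[0, 1], or squashed through the inverse-logit), the accumulated noise
produces a systematic regression toward the middle of the range — the only
age signal in the data, and the one an elastic-net clock learns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "GroundState",
    "NoiseConfig",
    "LabeledDataset",
    "make_ground_state",
    "accumulate_variation",
    "generate_dataset",
]

MODES = ("clamped", "unbounded", "logit")


@dataclass(frozen=True)
class GroundState:
    """Per-feature baseline values in [0, 1] at age zero."""

    values: np.ndarray
    feature_ids: tuple[str, ...] = ()
    origin: str = "synthetic"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("ground state must be a non-empty 1-D vector")
        if np.any((values < 0) | (values > 1)) or not np.all(np.isfinite(values)):
            raise ValueError("ground state values must lie in [0, 1]")
        object.__setattr__(self, "values", values)
        ids = tuple(self.feature_ids) or tuple(
            f"f{i:05d}" for i in range(values.size)
        )
        if len(ids) != values.size or len(set(ids)) != len(ids):
            raise ValueError("feature_ids must be unique and match values")
        object.__setattr__(self, "feature_ids", ids)

    @property
    def n_features(self) -> int:
        return self.values.size

    @classmethod
    def constant(cls, n_features: int, value: float, origin: str = "synthetic"):
        return cls(np.full(n_features, float(value)), origin=origin)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"feature_id": self.feature_ids, "value": self.values}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GroundState":
        df = pd.read_csv(path, sep="\t")
        return cls(df["value"].to_numpy(), tuple(df["feature_id"].astype(str)),
                   origin=str(path))


@dataclass(frozen=True)
class NoiseConfig:
    """Noise model for one simulation run.

    per_step_sd
        σ of the per-step normal distribution N(0, σ²); applied once per
        unit of simulated age.
    baseline_sd
        σ of the one-time per-sample jitter emulating inter-individual
        biological variation (default 0.01).
    mode
        ``clamped`` — clip to [0, 1] after every addition;
        ``unbounded`` — never clip (negative control: no age signal);
        ``logit`` — accumulate in logit space, return through expit.
    terminal_clamp
        clamp only once after all additions instead of per step
        (a censored-Gaussian variant kept for comparison).
    """

    per_step_sd: float
    baseline_sd: float = 0.01
    mode: str = "clamped"
    seed: int = 0
    logit_eps: float = 1e-6
    terminal_clamp: bool = False

    def __post_init__(self):
        if not self.per_step_sd > 0:
            raise ValueError("per_step_sd must be > 0")
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be >= 0")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    def with_seed(self, seed: int) -> "NoiseConfig":
        return replace(self, seed=seed)


@dataclass
class LabeledDataset:
    """Samples x features matrix with simulated ages and replicate-set labels."""

    matrix: np.ndarray
    ages: np.ndarray
    set_labels: np.ndarray
    feature_ids: tuple[str, ...]
    mode: str = "clamped"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.ages = np.asarray(self.ages, dtype=float)
        self.set_labels = np.asarray(self.set_labels, dtype=int)
        n = self.matrix.shape[0]
        if not (len(self.ages) == len(self.set_labels) == n):
            raise ValueError("ages and set_labels must match matrix rows")
        if np.any(self.ages < 0):
            raise ValueError("ages must be nonnegative")
        if self.mode in ("clamped", "logit") and (
            self.matrix.min() < 0 or self.matrix.max() > 1
        ):
            raise ValueError(f"{self.mode}-mode values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def subset_sets(self, sets: Sequence[int]) -> "LabeledDataset":
        mask = np.isin(self.set_labels, list(sets))
        return LabeledDataset(
            self.matrix[mask], self.ages[mask], self.set_labels[mask],
            self.feature_ids, self.mode,
        )

    def train_validation_split(self, n_train_sets: int):
        """First ``n_train_sets`` replicate sets for training, rest held out."""
        sets = np.unique(self.set_labels)
        return (self.subset_sets(sets[:n_train_sets]),
                self.subset_sets(sets[n_train_sets:]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=list(self.feature_ids))
        df.insert(0, "age", self.ages)
        df.insert(1, "set", self.set_labels)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, mode: str = "clamped") -> "LabeledDataset":
        df = pd.read_csv(path, sep="\t")
        features = [c for c in df.columns if c not in ("age", "set")]
        return cls(df[features].to_numpy(), df["age"].to_numpy(),
                   df["set"].to_numpy(), tuple(features), mode)


def make_ground_state(n_features: int, seed: int) -> GroundState:
    """Uniform-random ground state on [0, 1]."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    rng = np.random.default_rng(seed)
    return GroundState(rng.uniform(0.0, 1.0, n_features))


def _accumulate(values: np.ndarray, age: int, cfg: NoiseConfig,
                rng: np.random.Generator) -> np.ndarray:
    n = values.size
    if cfg.mode == "logit":
        safe = np.clip(values, cfg.logit_eps, 1 - cfg.logit_eps)
        v = logit(safe)
        v = v + rng.normal(0.0, cfg.baseline_sd, n)
        for _ in range(age):
            v = v + rng.normal(0.0, cfg.per_step_sd, n)
        return expit(v)
    clamp = cfg.mode == "clamped" and not cfg.terminal_clamp
    v = values + rng.normal(0.0, cfg.baseline_sd, n)
    if clamp:
        v = np.clip(v, 0.0, 1.0)
    for _ in range(age):
        v = v + rng.normal(0.0, cfg.per_step_sd, n)
        if clamp:
            v = np.clip(v, 0.0, 1.0)
    if cfg.mode == "clamped" and cfg.terminal_clamp:
        v = np.clip(v, 0.0, 1.0)
    return v


def accumulate_variation(ground: GroundState, age: int, cfg: NoiseConfig,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """One sample: ground + baseline jitter + ``age`` noise additions.

    In clamped mode values are clipped to [0, 1] after every addition; in
    logit mode jitter and noise are added in logit space and the result is
    mapped back through expit; in unbounded mode nothing is clipped.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if cfg.mode == "logit" and np.any((ground.values <= 0) | (ground.values >= 1)):
        if cfg.logit_eps <= 0:
            raise ValueError("logit mode requires values in (0, 1) or logit_eps > 0")
    return _accumulate(ground.values, int(age), cfg, rng)


def generate_dataset(ground: GroundState, max_age: int, n_sets: int,
                     cfg: NoiseConfig, age_start: int = 1) -> LabeledDataset:
    """``n_sets`` independent replicate sets, one sample per age.

    Ages run ``age_start .. age_start + max_age - 1`` (1..100 by default;
    the standard 6x100 design uses ``max_age=100, n_sets=6``).  Every
    sample gets an independent RNG stream spawned from ``cfg.seed`` so
    replicate sets are reproducible in isolation.
    """
    if max_age < 1 or n_sets < 1:
        raise ValueError("max_age and n_sets must be >= 1")
    ages = np.arange(age_start, age_start + max_age)
    streams = np.random.SeedSequence(cfg.seed).spawn(n_sets * len(ages))
    rows, out_ages, out_sets = [], [], []
    k = 0
    for s in range(n_sets):
        for a in ages:
            rng = np.random.default_rng(streams[k]); k += 1
            rows.append(_accumulate(ground.values, int(a), cfg, rng))
            out_ages.append(a)
            out_sets.append(s)
    return LabeledDataset(np.asarray(rows), np.asarray(out_ages),
                          np.asarray(out_sets), ground.feature_ids, cfg.mode)
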