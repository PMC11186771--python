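"""Elastic-net aging clocks and invertible age transforms.

A clock is a penalized linear model: predicted (transformed) age =
intercept + sum(coefficient_i * value_i), fit with cross-validated
elastic net (sklearn ``ElasticNetCV``).  Penalization shrinks many
coefficients exactly to zero, so trained clocks are sparse.  The model
optionally predicts a transformed age — a min-max rescaling to a
human-like year range, a constant rescaling, or the relative-age
double-log transform -log(-log(age / max_age)) with inverse
exp(-exp(-x)) — and predictions are mapped back through the inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNetCV

from .bulk import LabeledDataset

__all__ = [
    "AgeTransform",
    "IdentityTransform",
    "MinMaxScaleTransform",
    "MultiplyTransform",
    "LogLogTransform",
    "ClockModel",
    "train_clock",
    "predict",
    "load_clock_coefficients",
    "DEFAULT_L1_RATIOS",
]

DEFAULT_L1_RATIOS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)

INTERCEPT_ROW = "__intercept__"
TRANSFORM_ROW = "__transform__"


class AgeTransform:
    """Invertible mapping between raw ages and regression targets."""

    name = "identity"

    def fit(self, ages: np.ndarray) -> "AgeTransform":
        return self

    def forward(self, ages):
        raise NotImplementedError

    def inverse(self, values):
        raise NotImplementedError

    def params(self) -> dict:
        return {}

    @staticmethod
    def from_params(name: str, params: dict) -> "AgeTransform":
        cls = {t.name: t for t in (IdentityTransform, MinMaxScaleTransform,
                                   MultiplyTransform, LogLogTransform)}[name]
        return cls(**params)


class IdentityTransform(AgeTransform):
    name = "identity"

    def forward(self, ages):
        return np.asarray(ages, dtype=float)

    def inverse(self, values):
        return np.asarray(values, dtype=float)


class MinMaxScaleTransform(AgeTransform):
    """Min-max rescale ages to [0, 1] then affine map (default x400 - 120).

    The min/max are fit on the training ages and stored so validation
    uses identical scaling.
    """

    name = "minmax_scale"

    def __init__(self, scale: float = 400.0, shift: float = -120.0,
                 age_min: float | None = None, age_max: float | None = None):
        self.scale, self.shift = scale, shift
        self.age_min, self.age_max = age_min, age_max

    def fit(self, ages):
        ages = np.asarray(ages, dtype=float)
        self.age_min, self.age_max = float(ages.min()), float(ages.max())
        if self.age_min == self.age_max:
            raise ValueError("min-max transform needs >= 2 distinct ages")
        return self

    def _check(self):
        if self.age_min is None or self.age_max is None:
            raise ValueError("transform not fitted: age_min/age_max unset")

    def forward(self, ages):
        self._check()
        rel = (np.asarray(ages, dtype=float) - self.age_min) / (
            self.age_max - self.age_min)
        return rel * self.scale + self.shift

    def inverse(self, values):
        self._check()
        rel = (np.asarray(values, dtype=float) - self.shift) / self.scale
        return rel * (self.age_max - self.age_min) + self.age_min

    def params(self):
        return {"scale": self.scale, "shift": self.shift,
                "age_min": self.age_min, "age_max": self.age_max}


class MultiplyTransform(AgeTransform):
    """Constant rescaling of the arbitrary simulated time-steps (default x2)."""

    name = "multiply"

    def __init__(self, k: float = 2.0):
        if k == 0:
            raise ValueError("k must be nonzero")
        self.k = k

    def forward(self, ages):
        return np.asarray(ages, dtype=float) * self.k

    def inverse(self, values):
        return np.asarray(values, dtype=float) / self.k

    def params(self):
        return {"k": self.k}


class LogLogTransform(AgeTransform):
    """Relative-age transform -log(-log(age / max_age)).

    The inverse, exp(-exp(-x)), returns *relative* age in (0, 1).
    Relative ages are clipped to [eps, 1 - eps] before the double log.
    """

    name = "loglog"

    def __init__(self, max_age: float, eps: float = 1e-6):
        if max_age <= 0:
            raise ValueError("max_age must be > 0")
        self.max_age, self.eps = max_age, eps

    def forward(self, ages):
        rel = np.asarray(ages, dtype=float) / self.max_age
        rel = np.clip(rel, self.eps, 1.0 - self.eps)
        return -np.log(-np.log(rel))

    def inverse(self, values):
        return np.exp(-np.exp(-np.asarray(values, dtype=float)))

    def params(self):
        return {"max_age": self.max_age, "eps": self.eps}


@dataclass
class ClockModel:
    """Elastic-net coefficients, intercept, and the age transform they predict."""

    feature_ids: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    transform: AgeTransform = field(default_factory=IdentityTransform)
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.feature_ids) != self.coefficients.size:
            raise ValueError("coefficients must align with feature_ids")

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coefficients))

    def _design(self, samples) -> np.ndarray:
        if isinstance(samples, LabeledDataset):
            have = dict(zip(samples.feature_ids,
                            range(len(samples.feature_ids))))
            missing = [f for f in self.feature_ids if f not in have]
            if missing:
                raise ValueError(f"samples missing model features: {missing[:5]}"
                                 + ("..." if len(missing) > 5 else ""))
            cols = [have[f] for f in self.feature_ids]
            return samples.matrix[:, cols]
        if isinstance(samples, pd.DataFrame):
            missing = [f for f in self.feature_ids if f not in samples.columns]
            if missing:
                raise ValueError(f"samples missing model features: {missing[:5]}"
                                 + ("..." if len(missing) > 5 else ""))
            return samples[list(self.feature_ids)].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(samples, dtype=float))
        if X.shape[1] != len(self.feature_ids):
            raise ValueError("sample width does not match model features")
        return X

    def predict(self, samples) -> np.ndarray:
        X = self._design(samples)
        return self.transform.inverse(self.intercept + X @ self.coefficients)

    def to_tsv(self, path) -> None:
        rows = [{"feature_id": f, "coefficient": c}
                for f, c in zip(self.feature_ids, self.coefficients)]
        rows.append({"feature_id": INTERCEPT_ROW, "coefficient": self.intercept})
        import json

        rows.append({"feature_id": TRANSFORM_ROW,
                     "coefficient": json.dumps(
                         {"name": self.transform.name,
                          "params": self.transform.params()})})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ClockModel":
        return load_clock_coefficients(pd.read_csv(path, sep="\t"))


def train_clock(train: LabeledDataset, transform: AgeTransform | None = None,
                l1_ratios: Sequence[float] = DEFAULT_L1_RATIOS,
                alphas=None, cv: int = 5, seed: int = 0,
                max_iter: int = 5000) -> ClockModel:
    """Cross-validated elastic net predicting (transformed) simulated age.

    ``alphas`` follows sklearn's convention (None = automatic grid;
    a list pins the grid, e.g. ``[1.0]`` for the human-style clock).
    """
    transform = transform or IdentityTransform()
    if np.unique(train.ages).size < 2:
        raise ValueError("training data needs >= 2 distinct ages")
    transform.fit(train.ages)
    y = transform.forward(train.ages)
    if np.ptp(y) == 0:
        raise ValueError("constant target after transform")
    kwargs = {}
    if alphas is not None:
        kwargs["alphas"] = alphas
    model = ElasticNetCV(l1_ratio=list(l1_ratios), cv=cv, random_state=seed,
                         max_iter=max_iter, **kwargs)
    import warnings
    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(train.matrix, y)
    meta = {"l1_ratios": list(l1_ratios), "alphas": alphas, "cv_folds": cv,
            "seed": seed, "chosen_alpha": float(model.alpha_),
            "chosen_l1_ratio": float(model.l1_ratio_)}
    return ClockModel(train.feature_ids, model.coef_, float(model.intercept_),
                      transform, meta)


def predict(model: ClockModel, samples) -> np.ndarray:
    """Inverse-transformed linear predictor (module-level alias)."""
    return model.predict(samples)


def load_clock_coefficients(table, transform: AgeTransform | None = None,
                            ) -> ClockModel:
    """Build a usable clock from a published coefficient table.

    Accepts a path or DataFrame with feature-id and coefficient columns
    (first two columns if unnamed); an ``__intercept__`` row supplies the
    intercept (missing -> warn and assume 0); a ``__transform__`` row (or
    the ``transform`` argument) supplies any published post-transform.
    """
    import json
    import warnings

    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep=None, engine="python")
    if table.shape[0] == 0:
        raise ValueError("empty coefficient table")
    cols = list(table.columns)
    fcol = "feature_id" if "feature_id" in cols else cols[0]
    ccol = "coefficient" if "coefficient" in cols else cols[1]
    ids = table[fcol].astype(str)
    tmask = ids == TRANSFORM_ROW
    if tmask.any():
        spec = json.loads(table.loc[tmask, ccol].iloc[0])
        transform = AgeTransform.from_params(spec["name"], spec["params"])
    table = table[~tmask]
    ids = table[fcol].astype(str)
    imask = ids == INTERCEPT_ROW
    if imask.any():
        intercept = float(table.loc[imask, ccol].iloc[0])
    else:
        warnings.warn("coefficient table has no intercept row; assuming 0")
        intercept = 0.0
    feats = table[~imask]
    fids = tuple(feats[fcol].astype(str))
    if len(set(fids)) != len(fids):
        raise ValueError("duplicate feature ids in coefficient table")
    if len(fids) == 0:
        raise ValueError("coefficient table has no feature rows")
    return ClockModel(fids, feats[ccol].to_numpy(dtype=float), intercept,
                      transform or IdentityTransform(),
                      {"source": "coefficient-table"})
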