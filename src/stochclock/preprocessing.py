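"""Transcriptome binarization and cell-type-aware adjustments.

Binarization (BiT-style): per sample, log10(count + 1), min-max
normalize over genes, drop all-zero genes, mask zeros when taking the
per-sample median, and set genes strictly above the median to 1
(everything else, ties and masked zeros included, to 0).

Cell-type adjustment regresses each CpG's beta values on blood cell-type
fractions (B, NK, CD4T, CD8T, Mono, Neutro, Eosino) and keeps
feature mean + residual — the cell-type-independent variance.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bulk import GroundState, LabeledDataset, NoiseConfig, generate_dataset

__all__ = [
    "CELL_TYPES",
    "binarize_expression",
    "simulate_transcriptome_aging",
    "validate_fractions",
    "celltype_adjust",
    "covariate_regression",
]

CELL_TYPES = ("B", "NK", "CD4T", "CD8T", "Mono", "Neutro", "Eosino")


def binarize_expression(counts: pd.DataFrame) -> pd.DataFrame:
    """Binarize a genes x samples raw-count matrix.

    Min-max normalization is per sample (over its genes).  The zero mask
    applies only to the median computation; zeros still binarize as their
    min-max value, hence 0.
    """
    counts = counts.astype(float)
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    keep = counts.sum(axis=1) > 0
    counts = counts.loc[keep]
    logged = np.log10(counts + 1.0)
    lo, hi = logged.min(axis=0), logged.max(axis=0)
    degenerate = (hi - lo) == 0
    if degenerate.any():
        bad = list(counts.columns[degenerate])
        raise ValueError(f"min-max undefined for samples with <2 distinct values: {bad}")
    norm = (logged - lo) / (hi - lo)
    masked = norm.where(counts > 0)
    medians = masked.median(axis=0)
    return (norm.gt(medians, axis=1)).astype(int)


def simulate_transcriptome_aging(ground: GroundState, per_step_sd: float = 0.01,
                                 max_age: int = 16, n_per_age: int = 10,
                                 seed: int = 0, rescale: float = 1.0,
                                 baseline_sd: float = 0.01) -> LabeledDataset:
    """Clamped stochastic-variation aging of a binarized-normalized sample.

    ``n_per_age`` independent samples per time-step 1..max_age (160 in
    the default design).  ``rescale`` multiplies the arbitrary simulated
    time-steps before clock training (a factor of 2 was found helpful for
    matching external biological-age predictors).
    """
    cfg = NoiseConfig(per_step_sd=per_step_sd, baseline_sd=baseline_sd,
                      mode="clamped", seed=seed)
    ds = generate_dataset(ground, max_age=max_age, n_sets=n_per_age, cfg=cfg)
    if rescale != 1.0:
        ds = LabeledDataset(ds.matrix, ds.ages * rescale, ds.set_labels,
                            ds.feature_ids, ds.mode)
    return ds


def validate_fractions(fractions: pd.DataFrame) -> pd.DataFrame:
    """Check a samples x cell-types fraction table (sums within [0.95, 1.05])."""
    arr = fractions.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("cell-type fractions must be nonnegative")
    sums = arr.sum(axis=1)
    bad = (sums < 0.95) | (sums > 1.05)
    if bad.any():
        raise ValueError(
            f"fraction rows must sum to ~1; offending samples: "
            f"{list(fractions.index[bad])[:5]}")
    return fractions


def celltype_adjust(betas: pd.DataFrame, fractions: pd.DataFrame) -> pd.DataFrame:
    """Cell-type-composition adjustment of a samples x features beta matrix.

    Per feature: OLS beta ~ fractions (with intercept); adjusted value =
    feature mean + residual, clipped to [0, 1].  Per-feature means are
    preserved exactly (residuals sum to zero).
    """
    validate_fractions(fractions)
    if not betas.index.equals(fractions.index):
        fractions = fractions.loc[betas.index]
    X = sm.add_constant(fractions.to_numpy(dtype=float), has_constant="add")
    if betas.shape[0] < fractions.shape[1] + 2:
        raise ValueError("need at least n_celltypes + 2 samples")
    Y = betas.to_numpy(dtype=float)
    # one shared design: least-squares projection for all features at once;
    # a rank-deficient fraction matrix (e.g. identical rows) degrades to the
    # intercept-only projection, leaving the betas unchanged
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    adjusted = Y.mean(axis=0, keepdims=True) + resid
    return pd.DataFrame(np.clip(adjusted, 0.0, 1.0), index=betas.index,
                        columns=betas.columns)


def covariate_regression(response, predictors: pd.DataFrame,
                         interactions: Sequence[tuple[str, str]] = (),
                         ) -> pd.DataFrame:
    """OLS of a response on covariates plus optional interaction terms.

    The workhorse behind designs such as
    Age ~ PredictedAge + CellTypeFractions and
    PredictedAge ~ ChronologicalAge + Treatment + ChronologicalAge x Treatment.
    Returns a term/coef/se/t/p table (two-sided t-tests on residual
    degrees of freedom).
    """
    X = predictors.copy()
    for a, b in interactions:
        X[f"{a}:{b}"] = X[a] * X[b]
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(np.asarray(response, dtype=float),
                 X.astype(float)).fit()
    return pd.DataFrame({
        "term": X.columns,
        "coef": fit.params.to_numpy(),
        "se": fit.bse.to_numpy(),
        "t": fit.tvalues.to_numpy(),
        "p": fit.pvalues.to_numpy(),
    })
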