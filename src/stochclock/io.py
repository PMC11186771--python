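"""Beta-matrix reading, fixture generation, and run manifests.

TSV is the canonical dialect (tab-separated, UTF-8, '.' decimal); CSV is
accepted on read.  Beta matrices may be oriented either way: a
``feature_id`` header cell pins rows as features, otherwise the longer
axis is assumed to be features (with a warning).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .bulk import GroundState
from .methylation import MaintenanceRates, estimate_rates, init_population, \
    simulate_methylation_dataset
from .preprocessing import CELL_TYPES

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_rates",
    "write_rates",
    "make_fixture",
    "write_manifest",
]


def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def read_beta_matrix(path):
    """Read a beta matrix; returns (features x samples DataFrame, ages Series).

    Values are validated to [0, 1] (missing values are allowed and
    propagated); an ``age`` row/column, if present, is split off as
    per-sample ages (else ages is None).
    """
    df = _read_table(path)
    if df.index.name != "feature_id" and "feature_id" not in df.columns:
        if df.shape[1] > df.shape[0]:
            warnings.warn("no feature_id header; assuming the longer axis "
                          "(columns) holds features and transposing")
            df = df.T
    ages = None
    if "age" in df.index:
        ages = df.loc["age"].astype(float)
        df = df.drop(index="age")
    df = df.astype(float)
    arr = df.to_numpy()
    bad = (arr < 0) | (arr > 1)
    if np.any(bad & np.isfinite(arr)):
        i, j = np.argwhere(bad & np.isfinite(arr))[0]
        raise ValueError(
            f"beta values must lie in [0, 1]; offending entry: "
            f"feature {df.index[i]!r}, sample {df.columns[j]!r} = {arr[i, j]}")
    return df, ages


def write_beta_matrix(path, betas: pd.DataFrame, ages=None) -> None:
    out = betas.copy()
    out.index.name = "feature_id"
    if ages is not None:
        out = pd.concat([pd.DataFrame([ages], index=["age"]), out])
    out.to_csv(path, sep="\t")


def read_rates(path) -> MaintenanceRates:
    df = pd.read_csv(path, sep="\t")
    return MaintenanceRates(df["e_m"].to_numpy(), df["e_d"].to_numpy(),
                            provenance=str(path))


def write_rates(path, rates: MaintenanceRates, feature_ids=None) -> None:
    ids = feature_ids or [f"f{i:05d}" for i in range(rates.n_features)]
    pd.DataFrame({"feature_id": ids, "e_m": rates.e_m, "e_d": rates.e_d}
                 ).to_csv(path, sep="\t", index=False)


def _bimodal_betas(n_features: int, rng) -> np.ndarray:
    """Bimodal beta-distributed values: most sites near 0 or 1, fewer mid-range.

    Extreme sites get less between-sample variance than mid-range sites,
    matching the young-vs-old variance profile of methylation arrays.
    """
    comp = rng.uniform(size=n_features)
    vals = np.where(comp < 0.4, rng.beta(0.6, 8.0, n_features),
                    np.where(comp < 0.8, rng.beta(8.0, 0.6, n_features),
                             rng.beta(4.0, 4.0, n_features)))
    return np.clip(vals, 0.0, 1.0)


def make_fixture(kind: str, outdir, seed: int = 0, n_features: int = 200,
                 n_samples: int = 20) -> dict:
    """Generate small synthetic fixture files; returns {name: path}.

    ``beta_matrix``: a bimodal beta matrix with a young/old sample pair
    produced by running the methylation simulator forward, so rate
    estimation has a self-consistent target.  ``counts``:
    negative-binomial gene counts.  ``fractions``: Dirichlet rows over
    the blood cell types.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths = {}
    if kind == "beta_matrix":
        ground_vals = _bimodal_betas(n_features, rng)
        ground = GroundState(ground_vals, origin="synthetic-fixture")
        # per-site equilibria slightly toward 0.5, with extreme sites
        # pulled least: old-vs-young displacement mirrors the observed
        # low variance of near-0/1 methylation sites
        from .methylation import IMPROVED_LIMITS

        shrink = 0.8 * ground_vals * (1 - ground_vals)
        # clip targets away from 0/1: equilibria that extreme need E_d
        # resolution beyond the validity limits and would stall estimation
        target = np.clip(ground_vals + shrink * (0.5 - ground_vals),
                         0.01, 0.99)
        rates = estimate_rates(target, IMPROVED_LIMITS, seed=seed + 1)
        ds = simulate_methylation_dataset(ground, rates, max_age=100,
                                          n_sets=1, n_cells=1000,
                                          seed=seed + 2)
        young = ds.matrix[0]
        old = ds.matrix[-1]
        site_sd = 0.1 * np.sqrt(ground_vals * (1 - ground_vals)) + 0.002
        extra = np.clip(
            ground_vals[:, None]
            + rng.normal(0, site_sd[:, None], (n_features, n_samples - 2)),
            0, 1)
        mat = np.column_stack([young, extra, old])
        cols = [f"s{i:03d}" for i in range(n_samples)]
        betas = pd.DataFrame(mat, index=ground.feature_ids, columns=cols)
        ages = pd.Series([0.0] + list(rng.uniform(20, 80, n_samples - 2))
                         + [100.0], index=cols)
        p = outdir / "beta_matrix.tsv"
        write_beta_matrix(p, betas, ages)
        paths["beta_matrix"] = p
    elif kind == "counts":
        counts = rng.negative_binomial(5, 0.05, (n_features, n_samples))
        p = outdir / "counts.tsv"
        df = pd.DataFrame(counts, index=[f"g{i:05d}" for i in range(n_features)],
                          columns=[f"s{i:03d}" for i in range(n_samples)])
        df.index.name = "feature_id"
        df.to_csv(p, sep="\t")
        paths["counts"] = p
    elif kind == "fractions":
        frac = rng.dirichlet(np.array([2, 2, 6, 4, 3, 20, 1.0]), n_samples)
        p = outdir / "fractions.tsv"
        pd.DataFrame(frac, columns=list(CELL_TYPES),
                     index=[f"s{i:03d}" for i in range(n_samples)]
                     ).to_csv(p, sep="\t")
        paths["fractions"] = p
    else:
        raise ValueError(f"unknown fixture kind: {kind}")
    return paths


def write_manifest(path, config: dict) -> None:
    """Record the full run configuration (seed included) for reproducibility."""
    import sklearn

    meta = dict(config)
    meta["versions"] = {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }
    Path(path).write_text(json.dumps(meta, indent=2, default=str) + "\n")
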