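"""Case-control differential expression with covariate adjustment.

Each probe's expression is regressed on disease status together with sex,
age and post-mortem interval; the status coefficient is tested two-sided
with the residual-degrees-of-freedom t distribution. Probes are collapsed
to one result per gene (keeping the probe with the smallest raw p-value)
and gene-level p-values are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = ("status", "sex", "age", "pmi")


@dataclass
class ExpressionStudy:
    """A probe-by-sample expression matrix with per-sample covariates.

    ``values`` is indexed by probe id with one column per sample;
    ``covariates`` is indexed by sample id with columns status (0/1), sex
    (0/1), age (years) and pmi (post-mortem interval, hours).
    ``probe_map`` optionally maps probe id to gene id.
    """

    values: pd.DataFrame
    covariates: pd.DataFrame
    probe_map: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        missing = set(COVARIATE_COLUMNS) - set(self.covariates.columns)
        if missing:
            raise ValueError(f"covariate table missing columns: {sorted(missing)}")
        if list(self.values.columns) != list(self.covariates.index):
            self.covariates = self.covariates.loc[list(self.values.columns)]
        if self.covariates[list(COVARIATE_COLUMNS)].isna().any().any():
            raise ValueError("covariates must be complete for all samples")
        counts = self.covariates["status"].value_counts()
        if counts.min() < 2 or len(counts) != 2:
            raise ValueError("need at least 2 samples in each of two status groups")
        constant = [
            c for c in COVARIATE_COLUMNS
            if self.covariates[c].nunique() == 1
        ]
        if constant:
            raise ValueError(f"degenerate (constant) covariate column(s): {constant}")


def _design_matrix(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    names = ["intercept", *COVARIATE_COLUMNS]
    x = np.column_stack(
        [np.ones(len(covariates))]
        + [covariates[c].to_numpy(dtype=float) for c in COVARIATE_COLUMNS]
    )
    return x, names


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        collinear = [
            names[j]
            for j in range(x.shape[1])
            if np.linalg.matrix_rank(np.delete(x, j, axis=1)) == rank
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")


def fit_gene(values: np.ndarray, covariates: pd.DataFrame) -> tuple[float, float, float]:
    """OLS fit of one probe; returns (beta, se, p) for the status term."""
    x, names = _design_matrix(covariates)
    _check_rank(x, names)
    y = np.asarray(values, dtype=float)
    beta, se, p = _ols_status(x, y[None, :])
    return float(beta[0]), float(se[0]), float(p[0])


def _ols_status(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised OLS over rows of *y*; statistics for the status column (1)."""
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    hat = xtx_inv @ x.T                     # p x n
    betas = y @ hat.T                       # genes x p
    resid = y - betas @ x.T
    dof = n - p
    sigma2 = np.sum(resid**2, axis=1) / dof
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    se = np.where(se > 0, se, np.nan)
    t = betas[:, 1] / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df=dof)
    return betas[:, 1], se, pvals


def fit_all(study: ExpressionStudy) -> pd.DataFrame:
    """Fit every probe; returns columns probe, beta, se, p_raw."""
    x, names = _design_matrix(study.covariates)
    _check_rank(x, names)
    y = study.values.to_numpy(dtype=float)
    beta, se, p = _ols_status(x, y)
    return pd.DataFrame(
        {"probe": study.values.index, "beta": beta, "se": se, "p_raw": p}
    ).reset_index(drop=True)


def collapse_probes(results: pd.DataFrame, mapping: Mapping[str, str] | None) -> pd.DataFrame:
    """One result row per gene: the probe with the smallest raw p-value.

    Ties break by smallest standard error, then lexicographic probe id.
    Without a mapping every probe is its own gene.
    """
    df = results.copy()
    if mapping is None:
        df["gene"] = df["probe"]
        return df.sort_values("gene").reset_index(drop=True)
    unmapped = [p for p in df["probe"] if p not in mapping]
    if unmapped:
        raise ValueError(f"probe map does not cover: {unmapped[:5]}")
    df["gene"] = [mapping[p] for p in df["probe"]]
    df = df.sort_values(["gene", "p_raw", "se", "probe"], kind="mergesort")
    return df.groupby("gene", as_index=False).first()


def flag_significant(results: pd.DataFrame, fdr_alpha: float = 0.05) -> pd.DataFrame:
    """BH-adjust collapsed results and flag genes with p_fdr strictly < alpha."""
    from statsmodels.stats.multitest import multipletests

    df = results.copy()
    if len(df):
        df["p_fdr"] = multipletests(df["p_raw"], method="fdr_bh")[1]
    else:
        df["p_fdr"] = []
    df["significant"] = df["p_fdr"] < fdr_alpha
    return df


def run_dge(study: ExpressionStudy, fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Fit, collapse to genes, and FDR-flag; the full stage in one call."""
    fitted = fit_all(study)
    collapsed = collapse_probes(fitted, study.probe_map)
    out = flag_significant(collapsed, fdr_alpha=fdr_alpha)
    cols = ["gene", "probe", "beta", "se", "p_raw", "p_fdr", "significant"]
    return out[cols].sort_values("p_raw", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression(
    expr_path: str | Path,
    covariate_path: str | Path,
    probe_map_path: str | Path | None = None,
) -> ExpressionStudy:
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    covariates = pd.read_csv(covariate_path, sep="\t", index_col=0)
    probe_map = None
    if probe_map_path is not None:
        pm = pd.read_csv(probe_map_path, sep="\t")
        probe_map = dict(zip(pm["probe"].astype(str), pm["gene"].astype(str)))
    return ExpressionStudy(values=values, covariates=covariates, probe_map=probe_map)


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False)
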