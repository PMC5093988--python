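"""Probe-wise linear-model association (EWAS) of methylation with a phenotype.

Each probe's beta is regressed on the phenotype plus covariates by ordinary
least squares; the reported P value is the two-sided t-test on the
phenotype coefficient. Because the design matrix is shared by all probes
with complete data, the fits are computed as one multi-response least
squares solve (the standard EWAS vectorization); probes with missing
values fall back to individual complete-case fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import BetaMatrix, MethylationError

__all__ = ["EwasResult", "fit_probewise_linear", "count_significant",
           "probewise_ols"]


@dataclass
class EwasResult:
    """Per-probe coefficient, SE, t, two-sided P and n for one term."""

    table: pd.DataFrame  # columns: coef, se, t, p, n, defined
    phenotype: str

    def write(self, path) -> None:
        out = self.table.rename(columns={"coef": "beta_coef"})
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t", float_format="%.8g")


def _ols_stats(x: np.ndarray, y: np.ndarray, term_idx: int):
    """OLS of multi-response y (n x m) on shared design x (n x p).

    Returns coef, se, t, p (length m) for the ``term_idx`` column and the
    defined mask (False for zero-variance or otherwise degenerate probes).
    """
    n, p = x.shape
    if n <= p:
        raise MethylationError(f"{n} samples cannot identify {p} parameters")
    if np.linalg.matrix_rank(x) < p:
        m = y.shape[1]
        nan = np.full(m, np.nan)
        return nan, nan, nan, nan, np.zeros(m, dtype=bool)
    xtx_inv = np.linalg.inv(x.T @ x)
    coefs = xtx_inv @ (x.T @ y)  # p x m
    resid = y - x @ coefs
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[term_idx, term_idx], 0.0))
    coef = coefs[term_idx]
    defined = (y.std(axis=0) > 0) & (se > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(defined, coef / se, np.nan)
    pval = np.where(defined, 2.0 * stats.t.sf(np.abs(t), dof), np.nan)
    return coef, se, t, pval, defined


def probewise_ols(beta: BetaMatrix, design: pd.DataFrame, term: str) -> pd.DataFrame:
    """Fit beta_probe ~ design for every probe; report the ``term`` column.

    ``design`` must contain an intercept column and be indexed by sample ID;
    only samples present in both the design and the matrix are used.
    Complete-case analysis per probe.
    """
    samples = [s for s in design.index if s in set(beta.sample_ids)]
    x_df = design.loc[samples].astype(float)
    if x_df.isna().any().any():
        raise MethylationError("design matrix contains missing values")
    term_idx = list(x_df.columns).index(term)
    x = x_df.to_numpy()
    y = beta.data[samples].to_numpy().T  # n_samples x n_probes

    out = pd.DataFrame(index=beta.probe_ids,
                       columns=["coef", "se", "t", "p", "n", "defined"])
    complete = ~np.isnan(y).any(axis=0)
    if complete.any():
        coef, se, t, pval, defined = _ols_stats(x, y[:, complete], term_idx)
        cols = np.asarray(beta.probe_ids, dtype=object)[complete]
        out.loc[cols, "coef"] = coef
        out.loc[cols, "se"] = se
        out.loc[cols, "t"] = t
        out.loc[cols, "p"] = pval
        out.loc[cols, "n"] = x.shape[0]
        out.loc[cols, "defined"] = defined
    for j in np.nonzero(~complete)[0]:
        pid = beta.probe_ids[j]
        ok = ~np.isnan(y[:, j])
        if ok.sum() <= x.shape[1]:
            out.loc[pid] = [np.nan, np.nan, np.nan, np.nan, int(ok.sum()), False]
            continue
        coef, se, t, pval, defined = _ols_stats(x[ok], y[ok, j:j + 1], term_idx)
        out.loc[pid] = [coef[0], se[0], t[0], pval[0], int(ok.sum()), bool(defined[0])]
    return out.astype({"coef": float, "se": float, "t": float, "p": float,
                       "n": float, "defined": bool})


def fit_probewise_linear(
    beta: BetaMatrix,
    samples: pd.DataFrame,
    phenotype: str,
    covariates=(),
) -> EwasResult:
    """EWAS: per-probe OLS of beta on ``phenotype`` adjusting for ``covariates``.

    Samples with a missing phenotype or covariate are dropped up front
    (complete-case). A constant phenotype is a global error; constant or
    rank-deficient probe fits are flagged undefined, not dropped.
    """
    cols = [phenotype] + list(covariates)
    missing = [c for c in cols if c not in samples.columns]
    if missing:
        raise MethylationError(f"sample table lacks columns: {missing}")
    pheno_df = samples[cols].apply(pd.to_numeric, errors="raise")
    keep = pheno_df.dropna().index
    keep = [s for s in keep if s in set(beta.sample_ids)]
    if len(keep) < len(cols) + 2:
        raise MethylationError(f"only {len(keep)} complete samples for {len(cols)} terms")
    pheno_df = pheno_df.loc[keep]
    if pheno_df[phenotype].nunique() < 2:
        raise MethylationError(f"phenotype {phenotype!r} is constant")
    design = pheno_df.copy()
    design.insert(0, "_intercept", 1.0)
    table = probewise_ols(beta.subset_samples(keep), design, phenotype)
    return EwasResult(table=table, phenotype=phenotype)


def count_significant(result: EwasResult, alpha: float) -> int:
    """Number of probes with a defined P strictly below ``alpha``."""
    if not 0 < alpha < 1:
        raise MethylationError("alpha must lie in (0, 1)")
    t = result.table
    return int(((t["p"] < alpha) & t["defined"]).sum())
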