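"""Downstream associations: Spearman correlations and HPA-axis interaction models.

Continuous phenotype pairs (biosignature score vs myeloid fraction, IL-6,
perceived stress, ...) are tested with Spearman rank correlation; an
Anderson-Darling normality check on both inputs is reported alongside,
since non-normal inputs mandate the non-parametric test (normal ones still
get Spearman by default, for comparability).

HPA-axis reactivity is modeled as ordinary least squares of a cortisol
outcome (post-stress-test AUC cortisol, or the natural log of day-2
cortisol after dexamethasone suppression) on the biosignature score,
childhood-trauma (CTQ) score, their interaction and optional covariates,
with the whole-model F test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import normal_ad

from .core import MethylationError

__all__ = ["AssociationResult", "HpaModelFit", "spearman_assoc",
           "hpa_interaction_model"]

AD_ALPHA = 0.05


@dataclass
class AssociationResult:
    statistic: str            # "spearman_rho"
    estimate: float
    p: float
    n: int
    x_normal: bool | None = None   # Anderson-Darling at alpha=0.05
    y_normal: bool | None = None
    undefined: bool = False


@dataclass
class HpaModelFit:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    f_statistic: float
    df_num: int
    df_den: int
    model_p: float
    n: int
    outcome: str

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "n": self.n,
            "f_statistic": self.f_statistic,
            "df": f"{self.df_num}/{self.df_den}",
            "model_p": self.model_p,
            "coefficients": {k: {"estimate": float(self.params[k]),
                                 "se": float(self.bse[k]),
                                 "p": float(self.pvalues[k])}
                             for k in self.params.index},
        }


def spearman_assoc(x, y) -> AssociationResult:
    """Spearman rank correlation (average-rank ties, t-approximation P)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise MethylationError("inputs differ in length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 5:
        raise MethylationError(f"need >= 5 complete pairs, got {len(x)}")
    x_norm = bool(normal_ad(x)[1] >= AD_ALPHA) if np.std(x) > 0 else None
    y_norm = bool(normal_ad(y)[1] >= AD_ALPHA) if np.std(y) > 0 else None
    if np.std(x) == 0 or np.std(y) == 0:
        return AssociationResult("spearman_rho", float("nan"), float("nan"),
                                 len(x), x_norm, y_norm, undefined=True)
    rho, p = stats.spearmanr(x, y)
    return AssociationResult("spearman_rho", float(rho), float(p), len(x),
                             x_norm, y_norm)


def hpa_interaction_model(samples: pd.DataFrame, outcome: str,
                          covariates=()) -> HpaModelFit:
    """OLS of a cortisol outcome on biosignature + CTQ + their interaction.

    ``outcome`` is ``"cortisol_auc_posttest"`` or ``"ln_dst_day2"`` (the
    latter ln-transforms ``dst_day2_cortisol`` and rejects nonpositive
    values, naming the offending samples). ``samples`` must carry a
    ``biosignature`` column of projected scores and ``ctq``.
    """
    for col in ("biosignature", "ctq"):
        if col not in samples.columns:
            raise MethylationError(f"sample table lacks column {col!r}")
    if outcome == "ln_dst_day2":
        raw = pd.to_numeric(samples["dst_day2_cortisol"], errors="coerce")
        bad = raw.index[(raw <= 0) & raw.notna()]
        if len(bad):
            raise MethylationError(
                f"nonpositive day-2 cortisol for samples {list(bad)[:5]}; "
                "ln transform undefined"
            )
        y = np.log(raw)
    elif outcome in samples.columns:
        y = pd.to_numeric(samples[outcome], errors="coerce")
    else:
        raise MethylationError(f"unknown outcome {outcome!r}")

    design = pd.DataFrame({
        "biosignature": pd.to_numeric(samples["biosignature"], errors="coerce"),
        "ctq": pd.to_numeric(samples["ctq"], errors="coerce"),
    })
    design["biosignature_x_ctq"] = design["biosignature"] * design["ctq"]
    for cov in covariates:
        if cov not in samples.columns:
            raise MethylationError(f"covariate {cov!r} missing")
        design[cov] = pd.to_numeric(samples[cov], errors="coerce")
    frame = design.assign(_y=y).dropna()
    n, k = len(frame), design.shape[1]
    if n <= k + 1:
        raise MethylationError(f"n={n} too small for {k} predictors")
    x = sm.add_constant(frame.drop(columns="_y"), prepend=True)
    res = sm.OLS(frame["_y"], x).fit()
    return HpaModelFit(
        params=res.params.drop("const"),
        bse=res.bse.drop("const"),
        pvalues=res.pvalues.drop("const"),
        f_statistic=float(res.fvalue),
        df_num=int(res.df_model),
        df_den=int(res.df_resid),
        model_p=float(res.f_pvalue),
        n=n,
        outcome=outcome,
    )
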