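"""SKA2 suicide prediction model, ROC/AUC machinery and Monte Carlo nulls.

The prediction model is a logistic regression of a binary suicidal outcome
on the SKA2 trait components (rs7208505 CpG methylation and genotype,
plus their product) and a pluggable state term that interacts with SKA2
methylation:

    logit P(outcome) = b0 + b1*ska2m + b2*geno + b3*ska2m*geno
                       + b4*term + b5*term*ska2m

The state term is any per-sample numeric vector — a PCA biosignature
score, the myeloid-derived cell fraction, or a single probe's beta.
Accuracy is summarized by the rank-based ROC AUC with a stratified
percentile-bootstrap confidence interval, and significance by a Monte
Carlo permutation null built from PCA scores of randomly drawn same-size
probe sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .core import BetaMatrix, MethylationError

__all__ = ["ModelFit", "RocResult", "fit_prediction_model", "compute_auc",
           "bootstrap_auc_ci", "monte_carlo_probe_null", "evaluate_cohort"]

MAX_ITER = 50  # Newton iteration cap for the logistic fit

TERM_COLUMNS = ["intercept", "ska2_methylation", "ska2_genotype",
                "ska2m_x_genotype", "term", "term_x_ska2m"]


@dataclass
class ModelFit:
    params: pd.Series
    bse: pd.Series
    fitted: pd.Series            # per-sample risk scores in [0, 1]
    labels: pd.Series
    converged: bool
    separation: bool
    n: int


@dataclass
class RocResult:
    auc: float
    ci_lower: float
    ci_upper: float
    roc_points: pd.DataFrame     # columns fpr, tpr
    monte_carlo_p: float | None = None
    n_permutations: int = 0
    term: str = ""
    n_cases: int = 0
    n_controls: int = 0
    degenerate_permutations: int = 0

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "roc_points"}
        return d


def _design(samples: pd.DataFrame, outcome: str, interaction_values) -> pd.DataFrame:
    term = pd.Series(np.asarray(interaction_values, dtype=float),
                     index=samples.index, name="term")
    df = pd.DataFrame({
        "outcome": pd.to_numeric(samples[outcome], errors="coerce"),
        "ska2_methylation": samples["ska2_methylation"],
        "ska2_genotype": samples["ska2_genotype"],
        "term": term,
    })
    df["ska2m_x_genotype"] = df["ska2_methylation"] * df["ska2_genotype"]
    df["term_x_ska2m"] = df["term"] * df["ska2_methylation"]
    return df.dropna()


def fit_prediction_model(samples: pd.DataFrame, outcome: str,
                         interaction_values) -> ModelFit:
    """Fit the logistic prediction model; returns per-sample risk scores.

    Complete-case over the SKA2 fields, the outcome and the state term
    (samples with genotype 0 have no rs7208505 CpG and drop out). Perfect
    separation is detected and flagged; the fitted probabilities from the
    last iterate are still returned.
    """
    for col in ("ska2_methylation", "ska2_genotype", outcome):
        if col not in samples.columns:
            raise MethylationError(f"sample table lacks column {col!r}")
    df = _design(samples, outcome, interaction_values)
    y = df["outcome"].to_numpy()
    if len(y) == 0:
        raise MethylationError("no complete cases")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise MethylationError(f"outcome {outcome!r} is not binary")
    if y.sum() == 0 or y.sum() == len(y):
        raise MethylationError(f"outcome {outcome!r} has a single class")
    x = sm.add_constant(df[TERM_COLUMNS[1:]], prepend=True, has_constant="add")
    x = x.rename(columns={"const": "intercept"}).astype(float)

    separation = False
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, x.to_numpy()).fit(
                method="newton", maxiter=MAX_ITER, disp=0, warn_convergence=False
            )
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:  # PerfectSeparation or singular Hessian
            res = sm.Logit(y, x.to_numpy()).fit(
                method="lbfgs", maxiter=200, disp=0
            )
            separation = True
    fitted = np.clip(res.predict(x.to_numpy()), 0.0, 1.0)
    if not separation and (np.abs(res.params) > 50).any():
        separation = True  # coefficients diverging toward a separating plane
    return ModelFit(
        params=pd.Series(res.params, index=x.columns),
        bse=pd.Series(res.bse, index=x.columns),
        fitted=pd.Series(fitted, index=df.index),
        labels=pd.Series(y.astype(int), index=df.index),
        converged=converged,
        separation=separation,
        n=len(y),
    )


def compute_auc(scores, labels) -> float:
    """Rank-based ROC AUC: (concordant + 0.5*tied) / (cases * controls).

    Identical to the normalized Mann-Whitney U statistic; ties in the
    scores contribute half weight via average ranks.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    if s.shape != lab.shape:
        raise MethylationError("scores and labels differ in length")
    n1 = int((lab == 1).sum())
    n0 = int((lab == 0).sum())
    if n1 == 0 or n0 == 0:
        raise MethylationError("need at least one case and one control")
    ranks = rankdata(s, method="average")
    u = ranks[lab == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _auc_rows(score_matrix: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row-wise AUC for a (n_boot x n) score matrix against fixed labels."""
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    ranks = rankdata(score_matrix, method="average", axis=1)
    u = ranks[:, labels == 1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def bootstrap_auc_ci(scores, labels, n_boot: int = 1000, seed: int = 0):
    """Stratified percentile-bootstrap 95% CI for the AUC.

    Cases and controls are resampled separately so every replicate has both
    classes; the interval is the 2.5/97.5 percentile of bootstrap AUCs,
    upper capped at 1.
    """
    if n_boot < 100:
        raise MethylationError("n_boot must be >= 100")
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(lab == 1)
    ctrl_idx = np.flatnonzero(lab == 0)
    if len(case_idx) == 0 or len(ctrl_idx) == 0:
        raise MethylationError("need both classes to bootstrap")
    boot_cases = rng.choice(case_idx, size=(n_boot, len(case_idx)), replace=True)
    boot_ctrls = rng.choice(ctrl_idx, size=(n_boot, len(ctrl_idx)), replace=True)
    matrix = np.concatenate([s[boot_cases], s[boot_ctrls]], axis=1)
    lab_row = np.concatenate([np.ones(len(case_idx), dtype=int),
                              np.zeros(len(ctrl_idx), dtype=int)])
    aucs = _auc_rows(matrix, lab_row)
    lower, upper = np.percentile(aucs, [2.5, 97.5])
    return float(lower), float(min(upper, 1.0))


def monte_carlo_probe_null(
    beta: BetaMatrix,
    samples: pd.DataFrame,
    outcome: str,
    observed_auc: float,
    k: int = 72,
    n_perm: int = 1000,
    seed: int = 0,
):
    """Monte Carlo null: AUC of the model driven by random k-probe PCA scores.

    Each permutation draws k probes uniformly without replacement, trains a
    first-eigenvector PCA biosignature on them, uses the scores as the
    state term, refits the prediction model and records the in-sample AUC.
    Empirical P = (1 + #{null AUC >= observed}) / (1 + n_perm) — the
    plus-one estimator, so P never reaches 0 and the floor at 1000
    permutations is 1/1001 (reported in practice as P < 0.001).

    Degenerate permutation fits (zero-variance probe draws, inestimable
    models) are recorded as AUC 0.5 and counted, never dropped.
    """
    from .biosignature import train_biosignature_pca  # local: avoid cycle

    if k > len(beta.probe_ids):
        raise MethylationError(f"k={k} exceeds probe count {len(beta.probe_ids)}")
    rng = np.random.default_rng(seed)
    probe_arr = np.asarray(beta.probe_ids, dtype=object)
    null_aucs = np.empty(n_perm)
    degenerate = 0
    for i in range(n_perm):
        chosen = probe_arr[rng.choice(len(probe_arr), size=k, replace=False)]
        try:
            model = train_biosignature_pca(beta, chosen)
            scores = model.training_scores.reindex(samples.index)
            fit = fit_prediction_model(samples, outcome, scores)
            null_aucs[i] = compute_auc(fit.fitted.to_numpy(),
                                       fit.labels.to_numpy())
        except MethylationError:
            null_aucs[i] = 0.5
            degenerate += 1
    p = (1.0 + np.sum(null_aucs >= observed_auc)) / (1.0 + n_perm)
    return float(p), null_aucs, degenerate


def evaluate_cohort(
    cohort,
    term,
    biosignature_model=None,
    reference=None,
    outcome: str = "suicidal_ideation",
    subset: str | None = None,
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
) -> RocResult:
    """Full cohort evaluation: assemble the state term, fit, AUC + CI + Monte Carlo P.

    ``term`` is one of ``"biosignature"`` (requires ``biosignature_model``),
    ``"myeloid"`` (requires a cell ``reference``; the term is the
    deconvolved granulocyte+monocyte fraction) or ``"probe:<id>"`` (a single
    probe's beta). ``subset`` is a pandas query string (e.g.
    ``"ptsd==0 & substance_use==0"``) applied to the sample table before
    fitting.
    """
    from .biosignature import project_biosignature
    from .deconvolution import estimate_proportions, myeloid_fraction

    samples = cohort.samples
    if subset:
        samples = samples.query(subset)
        if samples.empty:
            raise MethylationError(f"subset {subset!r} excluded every sample")

    if term == "biosignature":
        if biosignature_model is None:
            raise MethylationError("term 'biosignature' requires a trained model")
        values = project_biosignature(biosignature_model, cohort.beta)
    elif term == "myeloid":
        if reference is None:
            raise MethylationError("term 'myeloid' requires a cell reference")
        values = myeloid_fraction(estimate_proportions(cohort.beta, reference))
    elif isinstance(term, str) and term.startswith("probe:"):
        pid = term.split(":", 1)[1]
        if pid not in set(cohort.beta.probe_ids):
            raise MethylationError(f"probe {pid!r} not present in cohort")
        values = cohort.beta.data.loc[pid]
    else:
        raise MethylationError(f"unresolvable interaction term {term!r}")

    values = pd.Series(values).reindex(samples.index)
    fit = fit_prediction_model(samples, outcome, values)
    scores = fit.fitted.to_numpy()
    labels = fit.labels.to_numpy()
    auc = compute_auc(scores, labels)
    lo, hi = bootstrap_auc_ci(scores, labels, n_boot=n_boot, seed=seed)
    fpr, tpr, _ = roc_curve(labels, scores)
    mc_p, _, degenerate = monte_carlo_probe_null(
        cohort.beta, samples, outcome, observed_auc=auc,
        k=len(biosignature_model.probes) if biosignature_model is not None else 72,
        n_perm=n_perm, seed=seed + 1,
    )
    return RocResult(
        auc=auc, ci_lower=lo, ci_upper=hi,
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        monte_carlo_p=mc_p, n_permutations=n_perm, term=str(term),
        n_cases=int(labels.sum()), n_controls=int((1 - labels).sum()),
        degenerate_permutations=degenerate,
    )
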