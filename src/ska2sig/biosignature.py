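"""Brain-to-peripheral interaction-biosignature discovery.

The discovery algorithm, stage by stage:

1. **Interaction screen** (brain neurons): per probe, a linear model of
   probe beta on suicide status, rs7208505 CpG methylation and their
   interaction, controlling for age, sex and rs7208505 genotype; the
   screened statistic is the interaction term's two-sided P. An alternative
   orientation (probe ~ ska2 methylation x genotype + age + sex) is
   available since the source description admits both readings.
2. **Candidate selection**: probes with screen P below a cutoff
   (default 0.005).
3. **AUC filter** (peripheral training cohort): each candidate probe's
   beta is used as the state term of the SKA2 prediction model; candidates
   whose in-sample ROC AUC lies strictly above the empirical 75th
   percentile of candidate AUCs (the "top 25th percentile") are retained.
4. **PCA biosignature**: the retained probes' training betas are centered
   per probe (no scaling) and the first eigenvector of the sample
   covariance is kept; new cohorts are scored by projecting centered
   betas onto those loadings. The eigenvector sign is fixed so that
   training scores correlate nonnegatively with per-sample mean
   methylation over the retained probes.
5. **Driver probes**: retained probes whose beta correlates (Spearman
   P < 0.05) with the biosignature score in every cohort.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import BetaMatrix, MethylationError
from .ewas import probewise_ols
from .prediction import compute_auc, fit_prediction_model

__all__ = [
    "InteractionScreenResult",
    "BiosignatureModel",
    "interaction_screen",
    "select_candidates",
    "probewise_auc_filter",
    "train_biosignature_pca",
    "project_biosignature",
    "driver_probe_correlations",
]

DEFAULT_P_CUTOFF = 0.005
DEFAULT_AUC_PERCENTILE = 75.0
MIN_COMPLETE_CASES = 10


@dataclass
class InteractionScreenResult:
    table: pd.DataFrame  # per probe: coef, se, t, p, n, defined
    orientation: str

    def write(self, path) -> None:
        out = self.table.copy()
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t", float_format="%.8g")


@dataclass
class BiosignatureModel:
    """Frozen PCA biosignature: probes, centering means, PC1 loadings."""

    probes: list
    means: np.ndarray
    loadings: np.ndarray           # unit norm
    explained_variance: float
    sign_flipped: bool
    training_cohort: str = ""
    training_scores: pd.Series | None = None

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        if not (len(self.probes) == len(self.means) == len(self.loadings)):
            raise MethylationError("probes, means and loadings must align")
        norm = np.linalg.norm(self.loadings)
        if not np.isclose(norm, 1.0, atol=1e-8):
            raise MethylationError(f"loadings must be unit norm (got {norm:.6f})")

    def to_json(self, path=None) -> str:
        payload = {
            "probes": list(self.probes),
            "means": self.means.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance": self.explained_variance,
            "sign_flipped": self.sign_flipped,
            "training_cohort": self.training_cohort,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "BiosignatureModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(probes=payload["probes"], means=payload["means"],
                   loadings=payload["loadings"],
                   explained_variance=payload["explained_variance"],
                   sign_flipped=payload["sign_flipped"],
                   training_cohort=payload.get("training_cohort", ""))


def interaction_screen(brain, orientation: str = "suicide_x_ska2m") -> InteractionScreenResult:
    """Probe-wise interaction screen in the brain cohort.

    Default orientation ``"suicide_x_ska2m"``::

        probe ~ suicide + ska2m + suicide*ska2m + age + sex + genotype

    Alternative ``"ska2m_x_genotype"``::

        probe ~ ska2m + genotype + ska2m*genotype + age + sex

    Samples lacking rs7208505 CpG methylation (genotype 0) are excluded;
    the screen needs at least 10 complete cases.
    """
    samples = brain.samples
    required = {"suicide_x_ska2m": ["suicide_death", "ska2_methylation",
                                    "ska2_genotype", "age", "sex"],
                "ska2m_x_genotype": ["ska2_methylation", "ska2_genotype",
                                     "age", "sex"]}
    if orientation not in required:
        raise MethylationError(f"unknown screen orientation {orientation!r}")
    cols = required[orientation]
    missing = [c for c in cols if c not in samples.columns]
    if missing:
        raise MethylationError(f"brain sample table lacks {missing}")
    df = samples[cols].apply(pd.to_numeric, errors="coerce").dropna()
    if df.empty or samples["ska2_methylation"].notna().sum() == 0:
        raise MethylationError(
            "no samples with defined rs7208505 CpG methylation (all genotype 0?)"
        )
    if len(df) < MIN_COMPLETE_CASES:
        raise MethylationError(f"only {len(df)} complete cases (need >= "
                               f"{MIN_COMPLETE_CASES})")
    design = pd.DataFrame(index=df.index)
    design["_intercept"] = 1.0
    if orientation == "suicide_x_ska2m":
        design["suicide"] = df["suicide_death"]
        design["ska2m"] = df["ska2_methylation"]
        design["interaction"] = df["suicide_death"] * df["ska2_methylation"]
        design["age"] = df["age"]
        design["sex"] = df["sex"]
        design["genotype"] = df["ska2_genotype"]
    else:
        design["ska2m"] = df["ska2_methylation"]
        design["genotype"] = df["ska2_genotype"]
        design["interaction"] = df["ska2_methylation"] * df["ska2_genotype"]
        design["age"] = df["age"]
        design["sex"] = df["sex"]
    table = probewise_ols(brain.beta.subset_samples(list(df.index)),
                          design, "interaction")
    return InteractionScreenResult(table=table, orientation=orientation)


def select_candidates(screen: InteractionScreenResult,
                      p_cutoff: float = DEFAULT_P_CUTOFF) -> list:
    """Probes with defined screen P strictly below the cutoff, ID-sorted."""
    if not 0 < p_cutoff < 1:
        raise MethylationError("p_cutoff must lie in (0, 1)")
    t = screen.table
    chosen = sorted(t.index[(t["p"] < p_cutoff) & t["defined"]])
    if not chosen:
        raise MethylationError(
            f"no probes pass P < {p_cutoff}; consider relaxing the cutoff"
        )
    return chosen


def probewise_auc_filter(
    candidates,
    training,
    outcome: str = "suicide_attempt",
    percentile: float = DEFAULT_AUC_PERCENTILE,
    probe_alone: bool = False,
):
    """Retain candidates whose prediction AUC is in the top tail.

    For each candidate probe the full SKA2 prediction model is fitted with
    that probe's beta as the state term and its in-sample ROC AUC recorded
    (``probe_alone=True`` ranks by the AUC of the raw probe beta instead).
    The retention threshold is the linear-interpolation empirical
    ``percentile`` of the candidate AUC distribution; retention is strict
    (>), so an all-equal AUC set retains nothing.

    Returns ``(retained_probe_ids, auc_table)``.
    """
    samples = training.samples
    if outcome not in samples.columns:
        raise MethylationError(f"training cohort lacks outcome {outcome!r}")
    vals = pd.to_numeric(samples[outcome], errors="coerce")
    if vals.dropna().nunique() < 2:
        raise MethylationError(f"outcome {outcome!r} needs both classes")
    aucs = {}
    degenerate = []
    beta = training.beta
    present = set(beta.probe_ids)
    for pid in candidates:
        if pid not in present:
            degenerate.append(pid)
            continue
        probe_beta = beta.data.loc[pid]
        try:
            if probe_alone:
                keep = probe_beta.notna() & vals.notna()
                aucs[pid] = compute_auc(probe_beta[keep].to_numpy(),
                                        vals[keep].to_numpy())
            else:
                fit = fit_prediction_model(samples, outcome, probe_beta)
                aucs[pid] = compute_auc(fit.fitted.to_numpy(),
                                        fit.labels.to_numpy())
        except MethylationError:
            degenerate.append(pid)
    if not aucs:
        raise MethylationError("no candidate probe yielded an estimable model")
    table = pd.DataFrame({"auc": pd.Series(aucs)})
    table.index.name = "probe_id"
    # type-6 (Weibull) plotting positions: the (n+1)p-th order statistic,
    # linearly interpolated
    threshold = float(np.percentile(table["auc"], percentile, method="weibull"))
    retained = sorted(table.index[table["auc"] > threshold])
    if not retained:
        warnings.warn("no candidate AUC strictly above the percentile threshold")
    table["retained"] = table.index.isin(retained)
    table.attrs["threshold"] = threshold
    table.attrs["degenerate"] = degenerate
    return retained, table


def _resolve_beta(source) -> BetaMatrix:
    return source if isinstance(source, BetaMatrix) else source.beta


def train_biosignature_pca(training, probes, cohort_name: str = "") -> BiosignatureModel:
    """Train the first-eigenvector PCA biosignature on the retained probes.

    Centering is per-probe by the training mean, with no scaling. Missing
    values are mean-imputed (with a warning). The sign is oriented so the
    training scores correlate nonnegatively with per-sample mean
    methylation over the retained probes; a zero correlation falls back to
    making the first nonzero loading positive.
    """
    beta = _resolve_beta(training)
    probes = list(probes)
    if len(probes) < 2:
        raise MethylationError("need at least 2 probes for a PCA biosignature")
    missing = [p for p in probes if p not in set(beta.probe_ids)]
    if missing:
        raise MethylationError(f"training matrix lacks probes {missing[:5]}")
    sub = beta.data.loc[probes]
    if sub.shape[1] < 3:
        raise MethylationError("need at least 3 training samples")
    if sub.isna().any().any():
        warnings.warn("mean-imputing missing probe values before PCA")
        sub = sub.T.fillna(sub.mean(axis=1)).T
    x = sub.to_numpy().T                      # samples x probes
    means = x.mean(axis=0)
    centered = x - means
    if not (centered.std(axis=0) > 0).any():
        raise MethylationError("zero-variance probe submatrix")
    # SVD of the centered matrix: right singular vectors = eigenvectors of
    # the sample covariance
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    loadings = vt[0]
    explained = float(s[0] ** 2 / np.sum(s ** 2))
    scores = centered @ loadings
    mean_meth = x.mean(axis=1)
    corr = np.corrcoef(scores, mean_meth)[0, 1] if scores.std() > 0 else np.nan
    flipped = False
    if np.isnan(corr) or np.isclose(corr, 0.0):
        nz = loadings[np.nonzero(loadings)[0]]
        if nz.size and nz[0] < 0:
            flipped = True
    elif corr < 0:
        flipped = True
    if flipped:
        loadings = -loadings
        scores = -scores
    return BiosignatureModel(
        probes=probes,
        means=means,
        loadings=loadings,
        explained_variance=explained,
        sign_flipped=flipped,
        training_cohort=cohort_name or getattr(training, "name", ""),
        training_scores=pd.Series(scores, index=beta.sample_ids),
    )


def project_biosignature(model: BiosignatureModel, cohort,
                         missing_probes: str = "error") -> pd.Series:
    """Score a cohort: loadings . (sample beta - training means).

    Probes absent from the cohort are an error by default;
    ``missing_probes="mean_fill"`` substitutes the training means (i.e. a
    zero contribution) with a warning, but more than 20% missing is always
    a hard error. Projecting the training cohort reproduces the training
    scores.
    """
    beta = _resolve_beta(cohort)
    present = set(beta.probe_ids)
    absent = [p for p in model.probes if p not in present]
    if len(absent) > 0.2 * len(model.probes):
        raise MethylationError(
            f"{len(absent)}/{len(model.probes)} model probes missing from cohort"
        )
    if absent:
        if missing_probes != "mean_fill":
            raise MethylationError(
                f"cohort lacks model probes {absent[:5]} "
                "(pass missing_probes='mean_fill' to impute)"
            )
        warnings.warn(f"mean-filling {len(absent)} missing model probes")
    x = np.empty((len(beta.sample_ids), len(model.probes)))
    for j, (pid, mu) in enumerate(zip(model.probes, model.means)):
        if pid in present:
            col = beta.data.loc[pid].to_numpy(dtype=float)
            col = np.where(np.isfinite(col), col, mu)
            x[:, j] = col
        else:
            x[:, j] = mu
    scores = (x - model.means) @ model.loadings
    return pd.Series(scores, index=beta.sample_ids, name="biosignature")


def driver_probe_correlations(model: BiosignatureModel, cohorts: dict,
                              alpha: float = 0.05, min_samples: int = 5):
    """Spearman correlation of each retained probe with the score, per cohort.

    Consistent drivers are probes with P < ``alpha`` in *every* included
    cohort (cohorts below ``min_samples`` samples are excluded, with a
    warning). Returns ``(long_table, consistent_probe_ids)``.
    """
    rows = []
    used_cohorts = []
    for name, cohort in cohorts.items():
        beta = _resolve_beta(cohort)
        if len(beta.sample_ids) < min_samples:
            warnings.warn(f"cohort {name!r} has fewer than {min_samples} "
                          "samples; excluded from driver analysis")
            continue
        used_cohorts.append(name)
        scores = project_biosignature(model, cohort)
        for pid in model.probes:
            x = beta.data.loc[pid].to_numpy(dtype=float)
            ok = np.isfinite(x)
            if ok.sum() < min_samples or np.std(x[ok]) == 0:
                rows.append((pid, name, np.nan, np.nan, int(ok.sum())))
                continue
            rho, p = stats.spearmanr(x[ok], scores.to_numpy()[ok])
            rows.append((pid, name, float(rho), float(p), int(ok.sum())))
    if len(used_cohorts) < 2:
        raise MethylationError("driver analysis needs at least 2 usable cohorts")
    table = pd.DataFrame(rows, columns=["probe_id", "cohort", "rho", "p", "n"])
    sig = table.assign(hit=(table["p"] < alpha))
    per_probe = sig.groupby("probe_id")["hit"].agg(["sum", "count"])
    consistent = sorted(per_probe.index[
        (per_probe["sum"] == len(used_cohorts))
        & (per_probe["count"] == len(used_cohorts))
    ])
    return table, consistent
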