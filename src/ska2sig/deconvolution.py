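"""Reference-based cell-type deconvolution of methylation profiles.

Blood and saliva methylation is a mixture of cell-type-specific profiles;
following the Houseman approach, per-sample cell proportions are estimated
by constrained projection of the observed beta vector onto a reference
matrix of cell-type mean profiles (here: nonnegative least squares, with
the sum of weights held at or below 1). The myeloid-derived fraction
(granulocytes + monocytes) serves downstream as an immune-state proxy.

The reference can be augmented with a buccal epithelial column (the mean of
a panel of buccal profiles) so that saliva samples, which contain buccal
cells, deconvolve sensibly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, nnls

from .core import BetaMatrix, MethylationError, _check_unique

__all__ = [
    "CellReference",
    "ProportionEstimate",
    "estimate_proportions",
    "augment_reference_with_buccal",
    "myeloid_fraction",
]

SUM_TOLERANCE = 0.05


@dataclass
class CellReference:
    """Loci x cell-types matrix of mean beta values."""

    profile: pd.DataFrame  # index: loci, columns: cell types

    def __post_init__(self) -> None:
        self.profile = pd.DataFrame(self.profile, dtype=float)
        _check_unique(self.profile.index, "reference loci")
        _check_unique(self.profile.columns, "cell types")
        vals = self.profile.to_numpy()
        if (vals < 0).any() or (vals > 1).any():
            raise MethylationError("reference profiles must lie in [0, 1]")

    @property
    def loci(self) -> list:
        return list(self.profile.index)

    @property
    def cell_types(self) -> list:
        return list(self.profile.columns)

    @classmethod
    def read(cls, path) -> "CellReference":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def write(self, path) -> None:
        df = self.profile.copy()
        df.index.name = "locus"
        df.to_csv(path, sep="\t", float_format="%.12g")


@dataclass
class ProportionEstimate:
    """Per-sample cell-type weights from constrained projection."""

    proportions: pd.DataFrame  # samples x cell types
    residual_norm: pd.Series
    flagged: list = field(default_factory=list)  # samples that could not be estimated

    def write(self, path) -> None:
        out = self.proportions.copy()
        out["residual_norm"] = self.residual_norm
        out.index.name = "sample_id"
        out.to_csv(path)


def _solve_weights(ref: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Minimize ||ref w - y||^2 s.t. w >= 0 and sum(w) <= 1 + tol.

    NNLS first; only when its solution overshoots the simplex is the
    sum-constrained problem solved explicitly (SLSQP from the clipped NNLS
    start). Deterministic for fixed input.
    """
    w, _ = nnls(ref, y)
    if w.sum() <= 1.0 + SUM_TOLERANCE:
        return w
    w0 = w / w.sum()
    res = minimize(
        lambda v: 0.5 * np.sum((ref @ v - y) ** 2),
        w0,
        jac=lambda v: ref.T @ (ref @ v - y),
        bounds=[(0.0, None)] * ref.shape[1],
        constraints=[{"type": "ineq", "fun": lambda v: 1.0 - v.sum()}],
        method="SLSQP",
        options={"maxiter": 200, "ftol": 1e-12},
    )
    return np.maximum(res.x, 0.0)


def estimate_proportions(beta: BetaMatrix, reference: CellReference) -> ProportionEstimate:
    """Estimate per-sample cell-type proportions by constrained projection.

    Loci are intersected by probe ID; at least as many shared loci as cell
    types are required. Samples whose shared-locus values are all missing
    are flagged rather than estimated.
    """
    shared = [p for p in reference.loci if p in set(beta.probe_ids)]
    k = len(reference.cell_types)
    if len(shared) < k:
        raise MethylationError(
            f"only {len(shared)} shared loci for {k} cell types; need at least {k}"
        )
    ref_full = reference.profile.loc[shared].to_numpy()
    obs = beta.data.loc[shared]

    weights = np.full((len(beta.sample_ids), k), np.nan)
    resid = np.full(len(beta.sample_ids), np.nan)
    flagged = []
    for i, sid in enumerate(beta.sample_ids):
        y = obs[sid].to_numpy()
        ok = np.isfinite(y)
        if not ok.any() or ok.sum() < k:
            flagged.append(sid)
            continue
        w = _solve_weights(ref_full[ok], y[ok])
        weights[i] = w
        resid[i] = np.linalg.norm(ref_full[ok] @ w - y[ok])
    return ProportionEstimate(
        proportions=pd.DataFrame(weights, index=beta.sample_ids,
                                 columns=reference.cell_types),
        residual_norm=pd.Series(resid, index=beta.sample_ids),
        flagged=flagged,
    )


def augment_reference_with_buccal(
    reference: CellReference,
    buccal_profiles: BetaMatrix,
    n_loci: int = 500,
) -> CellReference:
    """Append a buccal column (mean of buccal profiles) and trim loci.

    The buccal column at each locus is the mean over the buccal samples.
    The augmented reference is restricted to the ``n_loci`` most
    discriminating shared loci, ranked by the between-cell-type spread
    (variance of the augmented profile row across columns, the numerator of
    a one-way F over cell types). Fewer than ``n_loci`` shared loci: all
    are used, with a warning.
    """
    shared = [p for p in reference.loci if p in set(buccal_profiles.probe_ids)]
    if len(shared) == 0:
        raise MethylationError("no shared loci between reference and buccal profiles")
    if len(shared) < n_loci:
        warnings.warn(
            f"only {len(shared)} shared loci (< {n_loci}); using all of them"
        )
        n_loci = len(shared)
    buccal_mean = buccal_profiles.data.loc[shared].mean(axis=1, skipna=True)
    aug = reference.profile.loc[shared].copy()
    aug["buccal"] = buccal_mean
    spread = aug.var(axis=1, ddof=1)
    keep = spread.sort_values(ascending=False).index[:n_loci]
    # preserve original locus order among the retained loci
    keep = [p for p in shared if p in set(keep)]
    return CellReference(aug.loc[keep])


def myeloid_fraction(estimate: ProportionEstimate) -> pd.Series:
    """Granulocyte + monocyte weight per sample (the myeloid-derived fraction)."""
    for col in ("granulocyte", "monocyte"):
        if col not in estimate.proportions.columns:
            raise MethylationError(f"cell type {col!r} missing from proportion estimate")
    return estimate.proportions["granulocyte"] + estimate.proportions["monocyte"]
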