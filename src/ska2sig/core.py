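"""Core data model and preprocessing for HM450-style methylation cohorts.

Beta values are methylation fractions computed from the two channel
intensities of an Infinium probe as ``M / (M + U + 100)``; the +100 offset
regularizes low-intensity probes and keeps the fraction strictly below 1.
Channel intensities are quantile normalized separately (methylated and
unmethylated channels each get a common empirical distribution across
samples) before beta computation, and cross-reactive probes — probes whose
50-mer maps to multiple genomic locations — are dropped before analysis.

Matrices are probes-as-rows, samples-as-columns throughout. Genomic
positions are 1-based; the genome assembly is carried as a tag and never
converted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "MethylationError",
    "ChannelMatrices",
    "BetaMatrix",
    "read_probe_annotation",
    "read_sample_table",
    "SAMPLE_COLUMNS",
    "compute_beta",
    "channel_quantile_normalize",
    "remove_cross_reactive",
    "read_beta_table",
    "write_beta_table",
]

BETA_OFFSET = 100.0

#: Column dictionary for sample sheets (CSV, one row per sample).
SAMPLE_COLUMNS = {
    "sample_id": "unique sample identifier",
    "age": "age in years",
    "sex": "binary indicator (0/1)",
    "tissue": "one of brain_neuron / blood / saliva",
    "suicide_death": "binary outcome (postmortem cohorts)",
    "suicidal_ideation": "binary outcome",
    "suicide_attempt": "binary outcome",
    "ska2_methylation": "beta at the rs7208505 CpG; defined only when ska2_genotype >= 1",
    "ska2_genotype": "count in {0,1,2} of CpG-preserving alleles at rs7208505",
    "ctq": "Childhood Trauma Questionnaire total score",
    "cortisol_auc": "area under the waking cortisol curve (arbitrary units)",
    "cortisol_auc_posttest": "post-stress-test AUC cortisol",
    "dst_day2_cortisol": "day-2 cortisol after dexamethasone suppression (positive)",
    "il6": "interleukin-6, pg/mL; 0 encodes below detection limit",
    "perceived_stress": "perceived stress scale score",
    "ptsd": "binary flag",
    "substance_use": "binary flag",
}


class MethylationError(ValueError):
    """Invalid methylation data or parameters."""


def _check_unique(ids, what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise MethylationError(f"duplicate {what}: {sorted(set(dups))[:5]}")


@dataclass
class ChannelMatrices:
    """Methylated / unmethylated signal intensities, probes x samples."""

    methylated: np.ndarray
    unmethylated: np.ndarray
    probe_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.methylated = np.asarray(self.methylated, dtype=float)
        self.unmethylated = np.asarray(self.unmethylated, dtype=float)
        if self.methylated.shape != self.unmethylated.shape:
            raise MethylationError(
                f"channel shape mismatch: {self.methylated.shape} vs "
                f"{self.unmethylated.shape}"
            )
        if (self.methylated < 0).any() or (self.unmethylated < 0).any():
            raise MethylationError("negative channel intensity")
        n_probes, n_samples = self.methylated.shape
        if len(self.probe_ids) != n_probes or len(self.sample_ids) != n_samples:
            raise MethylationError("identifier lengths do not match matrix shape")
        _check_unique(self.probe_ids, "probe IDs")
        _check_unique(self.sample_ids, "sample IDs")


@dataclass
class BetaMatrix:
    """Methylation fractions in [0, 1), probes x samples.

    Backed by a pandas DataFrame (index = probe IDs, columns = sample IDs);
    missing values are NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = pd.DataFrame(self.data, dtype=float)
        _check_unique(self.data.index, "probe IDs")
        _check_unique(self.data.columns, "sample IDs")
        vals = self.data.to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and ((finite < 0).any() or (finite >= 1).any()):
            raise MethylationError("beta values must lie in [0, 1)")

    @classmethod
    def from_arrays(cls, values, probe_ids, sample_ids) -> "BetaMatrix":
        return cls(pd.DataFrame(np.asarray(values, dtype=float),
                                index=list(probe_ids), columns=list(sample_ids)))

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def probe_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self):
        return self.data.shape

    def subset_probes(self, probes) -> "BetaMatrix":
        return BetaMatrix(self.data.loc[list(probes)])

    def subset_samples(self, samples) -> "BetaMatrix":
        return BetaMatrix(self.data[list(samples)])


def compute_beta(methylated, unmethylated):
    """Beta value: M / (M + U + 100).

    Accepts scalars or arrays; negative intensities are rejected. The result
    is bounded in [0, 1), monotone increasing in M and decreasing in U.
    """
    m = np.asarray(methylated, dtype=float)
    u = np.asarray(unmethylated, dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise MethylationError("negative channel intensity")
    beta = m / (m + u + BETA_OFFSET)
    return float(beta) if beta.ndim == 0 else beta


def _quantile_normalize_matrix(x: np.ndarray) -> np.ndarray:
    """Map each column onto the mean-of-sorted-columns reference.

    Ties receive the average of the reference quantiles at their rank span
    (average-rank convention), so the operation is deterministic and
    idempotent.
    """
    n_rows, n_cols = x.shape
    if n_cols == 1:
        return x.copy()
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x, dtype=float)
    positions = np.arange(1, n_rows + 1, dtype=float)
    for j in range(n_cols):
        ranks = rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, ref)
    return out


def channel_quantile_normalize(channels: ChannelMatrices) -> ChannelMatrices:
    """Quantile normalize the methylated and unmethylated channels separately.

    After normalization every sample column within a channel shares the same
    empirical distribution (the mean of the sorted columns) while the within-
    column ranking is preserved.
    """
    if np.isnan(channels.methylated).any() or np.isnan(channels.unmethylated).any():
        raise MethylationError("missing intensities are not supported")
    return ChannelMatrices(
        methylated=_quantile_normalize_matrix(channels.methylated),
        unmethylated=_quantile_normalize_matrix(channels.unmethylated),
        probe_ids=list(channels.probe_ids),
        sample_ids=list(channels.sample_ids),
    )


def remove_cross_reactive(
    beta: BetaMatrix,
    annotation: pd.DataFrame,
    unannotated: str = "keep",
) -> BetaMatrix:
    """Drop probes flagged cross-reactive in the annotation.

    ``unannotated`` controls probes absent from the annotation table:
    ``"keep"`` (default) retains them, ``"drop"`` removes them.
    """
    if unannotated not in ("keep", "drop"):
        raise MethylationError(f"unannotated must be 'keep' or 'drop', got {unannotated!r}")
    ann = annotation.set_index("probe_id") if "probe_id" in annotation.columns else annotation
    flagged = set(ann.index[ann["cross_reactive"].astype(bool)])
    keep = []
    for p in beta.probe_ids:
        if p in flagged:
            continue
        if p not in ann.index and unannotated == "drop":
            continue
        keep.append(p)
    if not keep:
        warnings.warn("all probes removed as cross-reactive; returning empty matrix")
        return BetaMatrix(beta.data.iloc[0:0])
    return beta.subset_probes(keep)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_beta_table(path) -> BetaMatrix:
    """Read a beta matrix TSV: first column probe_id, header of sample IDs.

    '.' or empty cells are missing. Values outside [0, 1) raise a parse
    error naming the offending probe and sample.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["."], dtype=str)
    _check_unique(df.index, "probe IDs")
    _check_unique(df.columns, "sample IDs")
    parsed = df.apply(pd.to_numeric, errors="coerce")
    # cells that were non-empty strings but failed to parse
    bad_parse = parsed.isna() & df.notna() & (df != "")
    vals = parsed.to_numpy()
    with np.errstate(invalid="ignore"):
        bad_range = (vals < 0) | (vals >= 1)
    bad = bad_parse.to_numpy() | np.nan_to_num(bad_range, nan=False)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise MethylationError(
            f"invalid beta value {df.iat[i, j]!r} at probe {df.index[i]!r}, "
            f"sample {df.columns[j]!r} in {path}"
        )
    return BetaMatrix(parsed)


def write_beta_table(beta: BetaMatrix, path) -> None:
    """Write a beta matrix as TSV (probe_id first column, '.' for missing)."""
    df = beta.data.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", na_rep=".", float_format="%.12g")


def read_probe_annotation(path) -> pd.DataFrame:
    """Read probe annotation TSV.

    Columns: probe_id, chrom, pos (1-based), assembly, gene_symbol (may be
    empty), cross_reactive (0/1).
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str,
                                            "assembly": str, "gene_symbol": str})
    required = {"probe_id", "chrom", "pos", "assembly", "gene_symbol", "cross_reactive"}
    missing = required - set(df.columns)
    if missing:
        raise MethylationError(f"annotation missing columns: {sorted(missing)}")
    _check_unique(df["probe_id"], "probe IDs")
    pos = pd.to_numeric(df["pos"], errors="coerce")
    if (pos.dropna() < 1).any():
        raise MethylationError("positions must be >= 1")
    df["gene_symbol"] = df["gene_symbol"].fillna("")
    df["cross_reactive"] = df["cross_reactive"].astype(int)
    return df


def read_sample_table(path) -> pd.DataFrame:
    """Read a per-sample phenotype sheet (CSV, one row per sample)."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise MethylationError("sample sheet must have a sample_id column")
    _check_unique(df["sample_id"], "sample IDs")
    if "ska2_methylation" in df.columns and "ska2_genotype" in df.columns:
        bad = df["ska2_methylation"].notna() & (df["ska2_genotype"] == 0)
        if bad.any():
            raise MethylationError(
                "ska2_methylation defined for genotype-0 samples: "
                f"{df.loc[bad, 'sample_id'].tolist()[:5]}"
            )
    return df.set_index("sample_id", drop=False)
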