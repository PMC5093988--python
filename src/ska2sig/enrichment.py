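"""Gene-level overlap and binomial overrepresentation between EWAS results.

Probes are collapsed to genes by minimum P; for a significance tier t, the
question is whether genes significant in the query analysis overlap genes
significant in the target analysis more often than chance. With background
B (genes in both universes), target-significant set T and query-significant
set Q, the expected probability is p0 = |T|/|B|, the probability estimate
is |Q∩T|/|Q|, and significance is the exact one-sided (greater) binomial
test of |Q∩T| successes in |Q| trials at p0. Default tiers: 0.05, 0.01,
0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import MethylationError
from .ewas import EwasResult

__all__ = ["GeneSignificance", "EnrichmentResult", "probes_to_genes",
           "overrepresentation_test", "enrichment_report", "DEFAULT_TIERS"]

DEFAULT_TIERS = (0.05, 0.01, 0.001)

_GENE_SEPARATORS = ";,"


@dataclass
class GeneSignificance:
    """Per-gene minimum probe P and probe count."""

    table: pd.DataFrame  # index gene symbol; columns: min_p, n_probes

    @property
    def genes(self) -> set:
        return set(self.table.index)

    def significant(self, tier: float) -> set:
        return set(self.table.index[self.table["min_p"] < tier])


@dataclass
class EnrichmentResult:
    tier: float
    expected_probability: float
    probability_estimate: float
    overlap: int
    query_size: int
    background_size: int
    binomial_p: float
    undefined: bool = False
    two_sided: bool = False


def probes_to_genes(result: EwasResult, annotation: pd.DataFrame) -> GeneSignificance:
    """Collapse probe-level P values to gene level by minimum P.

    A probe annotated to several genes (separator ';' or ',') contributes
    to each; probes without a gene symbol are excluded.
    """
    ann = annotation.set_index("probe_id") if "probe_id" in annotation.columns else annotation
    rows = []
    tab = result.table
    for pid in tab.index:
        if pid not in ann.index:
            continue
        symbols = str(ann.at[pid, "gene_symbol"] or "")
        for sep in _GENE_SEPARATORS:
            symbols = symbols.replace(sep, "|")
        p = tab.at[pid, "p"]
        if not np.isfinite(p):
            continue
        for gene in filter(None, (g.strip() for g in symbols.split("|"))):
            rows.append((gene, p))
    if not rows:
        raise MethylationError("no annotated probes with defined P values")
    df = pd.DataFrame(rows, columns=["gene", "p"])
    agg = df.groupby("gene")["p"].agg(min_p="min", n_probes="size")
    return GeneSignificance(agg)


def overrepresentation_test(
    query: GeneSignificance,
    target: GeneSignificance,
    tier: float,
    two_sided: bool = False,
) -> EnrichmentResult:
    """Exact binomial test of query/target gene-set overlap at one tier."""
    background = query.genes & target.genes
    if not background:
        raise MethylationError("query and target share no background genes")
    q = query.significant(tier) & background
    t = target.significant(tier) & background
    p0 = len(t) / len(background)
    if len(q) == 0:
        return EnrichmentResult(tier, p0, float("nan"), 0, 0, len(background),
                                float("nan"), undefined=True, two_sided=two_sided)
    overlap = len(q & t)
    estimate = overlap / len(q)
    alternative = "two-sided" if two_sided else "greater"
    pval = stats.binomtest(overlap, len(q), p0, alternative=alternative).pvalue
    return EnrichmentResult(tier, p0, estimate, overlap, len(q),
                            len(background), float(pval), two_sided=two_sided)


def enrichment_report(
    query: GeneSignificance,
    target: GeneSignificance,
    tiers=DEFAULT_TIERS,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Overrepresentation at each tier, as a tidy table."""
    rows = [overrepresentation_test(query, target, t, two_sided=two_sided)
            for t in tiers]
    return pd.DataFrame([r.__dict__ for r in rows])
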