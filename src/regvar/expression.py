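"""Spatio-temporal expression of target-gene sets and cell-type specificity.

A gene set's expression trajectory across developmental stages is summarized
by the per-stage median RPKM over the set's genes; trajectories are compared
with Wilcoxon rank-sum tests (target vs background across stages, and
prenatal vs postnatal stages within the target set). Cell-type involvement is
counted as the number of set genes whose expression-specificity score exceeds
a strict cutoff (default 0.1) in each cell type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyGeneSetError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StageExpressionMatrix:
    """gene x stage RPKM values with an explicit prenatal/postnatal split.

    ``values`` is a DataFrame indexed by gene with stages as (ordered)
    columns; ``prenatal_mask`` marks the prenatal stages.
    """

    values: pd.DataFrame
    prenatal_mask: np.ndarray

    def __post_init__(self):
        if self.values.shape[1] == 0:
            raise ValueError("expression matrix has no stages")
        if len(self.prenatal_mask) != self.values.shape[1]:
            raise ValueError("prenatal mask length != number of stages")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("RPKM values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def stages(self) -> list[str]:
        return list(self.values.columns)


def stage_medians(matrix: StageExpressionMatrix, gene_set) -> pd.Series:
    """Per-stage median RPKM over the gene set (set semantics: duplicates and
    gene order do not matter). Genes absent from the matrix are logged."""
    genes = set(gene_set)
    present = [g for g in matrix.genes if g in genes]
    missing = genes - set(present)
    if missing:
        logger.info("%d gene-set genes absent from expression matrix", len(missing))
    if not present:
        raise EmptyGeneSetError("gene set does not intersect the expression matrix")
    return matrix.values.loc[present].median(axis=0)


def rank_sum_test(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) with exact small-sample p-values
    when there are no ties, normal approximation with tie correction
    otherwise. Degenerate comparisons (zero rank variance) report p = 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "asymptotic" if ties else ("exact" if max(len(x), len(y)) <= 25 else "auto")
    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    p = float(res.pvalue)
    if np.isnan(p):  # all observations tied: no evidence either way
        p = 1.0
    return float(res.statistic), p


def compare_gene_sets(
    matrix: StageExpressionMatrix,
    target_set,
    background_set,
    alternative: str = "two-sided",
) -> dict[str, dict[str, float]]:
    """Two comparisons on per-stage medians:

    * ``target_vs_background``: target medians vs background medians across
      all stages;
    * ``prenatal_vs_postnatal``: the target set's prenatal vs postnatal
      stage medians.
    """
    target_medians = stage_medians(matrix, target_set)
    background_medians = stage_medians(matrix, background_set)
    stat_tb, p_tb = rank_sum_test(
        target_medians.to_numpy(), background_medians.to_numpy(), alternative
    )
    pre = target_medians.to_numpy()[matrix.prenatal_mask]
    post = target_medians.to_numpy()[~matrix.prenatal_mask]
    if len(pre) and len(post):
        stat_pp, p_pp = rank_sum_test(pre, post, alternative)
    else:
        stat_pp, p_pp = float("nan"), float("nan")
    return {
        "target_vs_background": {"statistic": stat_tb, "p": p_tb},
        "prenatal_vs_postnatal": {"statistic": stat_pp, "p": p_pp},
    }


def celltype_counts(
    spec: pd.DataFrame, gene_set, cutoff: float = 0.1
) -> pd.DataFrame:
    """Per cell type, the number of gene-set genes with specificity strictly
    above the cutoff (a gene specific in two cell types counts in both)."""
    genes = set(gene_set)
    sub = spec[spec["gene"].isin(genes) & (spec["specificity"] > cutoff)]
    counts = sub.groupby("cell_type")["gene"].nunique()
    all_types = sorted(spec["cell_type"].unique())
    rows = [
        {"cell_type": ct, "n_genes": int(counts.get(ct, 0))} for ct in all_types
    ]
    return pd.DataFrame(rows, columns=["cell_type", "n_genes"])
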