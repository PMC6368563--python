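"""eQTL target-gene tiering, allele-specific-expression tests and LD partners.

Target genes of disrupting variants are tiered by how many independent eQTL
datasets support the same SNP-gene association, each dataset under its own
published significance rule (CMC FDR < 0.05, LIBD FDR < 0.01, GTEx nominal
P < 0.001; a dataset counts once however many of its tissues pass). Allelic
imbalance at heterozygous expressed sites is tested with an exact two-sided
binomial test against a 0.5 null. LD partners of an index variant are the
variants within a physical window whose squared dosage correlation (composite
LD) reaches r2_min.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

#: per-dataset significance rules: dataset -> (column, threshold), value < threshold
DEFAULT_DATASET_RULES: dict[str, tuple[str, float]] = {
    "CMC": ("fdr", 0.05),
    "LIBD": ("fdr", 0.01),
    "GTEX": ("p", 0.001),
}

TIER_LABELS = {0: "none", 1: "any", 2: "replicated", 3: "full"}


@dataclass(frozen=True)
class LDResult:
    snp_a: str
    snp_b: str
    r2: float
    distance_bp: int


def tier_targets(
    disrupting_snp_ids,
    eqtl: pd.DataFrame,
    rules: dict[str, tuple[str, float]] | None = None,
) -> pd.DataFrame:
    """Per (snp, gene): number of datasets whose own rule passes, the dataset
    list, and the tier label (any >=1, replicated >=2, full =3)."""
    rules = dict(DEFAULT_DATASET_RULES if rules is None else rules)
    snp_ids = set(disrupting_snp_ids)
    sub = eqtl[eqtl["snp_id"].isin(snp_ids)].copy()
    unknown = set(sub["dataset"].str.upper()) - {d.upper() for d in rules}
    if unknown:
        raise ConfigurationError(
            f"eQTL datasets without a configured rule: {sorted(unknown)}"
        )
    rules_upper = {d.upper(): rule for d, rule in rules.items()}

    def passes(row) -> bool:
        column, threshold = rules_upper[row.dataset.upper()]
        value = getattr(row, column)
        return value is not None and not pd.isna(value) and value < threshold

    sub["passes"] = [passes(r) for r in sub.itertuples(index=False)]
    sub = sub[sub["passes"]]
    rows = []
    for (snp, gene), grp in sub.groupby(["snp_id", "gene"], sort=True):
        datasets = sorted(set(grp["dataset"].str.upper()))
        n = len(datasets)
        rows.append(
            {
                "snp_id": snp,
                "gene": gene,
                "n_supporting_datasets": n,
                "datasets": ",".join(datasets),
                "tier": TIER_LABELS[min(n, 3)],
            }
        )
    return pd.DataFrame(
        rows, columns=["snp_id", "gene", "n_supporting_datasets", "datasets", "tier"]
    )


def binomial_ase(ref_count: int, alt_count: int, null_ratio: float = 0.5) -> float:
    """Exact two-sided binomial p-value for allelic imbalance.

    Two-sidedness uses the minimum-likelihood rule (sum P(k) over outcomes no
    more likely than the observation), which at a 0.5 null equals symmetric
    tail doubling.
    """
    ref_count, alt_count = int(ref_count), int(alt_count)
    if ref_count < 0 or alt_count < 0:
        raise ValueError("allele counts must be non-negative")
    n = ref_count + alt_count
    if n == 0:
        raise ValueError("both allele counts are zero; nothing to test")
    return float(stats.binomtest(ref_count, n, p=null_ratio).pvalue)


def ase_table(
    ase: pd.DataFrame, null_ratio: float = 0.5, alpha: float = 0.001
) -> pd.DataFrame:
    """Add binom_p and a significance flag to an allelic-count table.

    Rows with both counts zero are dropped with a log message; other rows are
    unaffected.
    """
    out = ase.copy()
    zero = (out["ref_count"] + out["alt_count"]) == 0
    if zero.any():
        logger.warning("dropping %d ASE rows with zero total reads", int(zero.sum()))
        out = out[~zero].copy()
    out["binom_p"] = [
        binomial_ase(r, a, null_ratio)
        for r, a in zip(out["ref_count"], out["alt_count"])
    ]
    out["imbalanced"] = out["binom_p"] < alpha
    return out.reset_index(drop=True)


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float | None:
    """Squared Pearson correlation of dosage vectors over pairwise-complete
    samples (missing coded < 0); None when either vector is monomorphic."""
    ok = (x >= 0) & (y >= 0)
    if ok.sum() < 2:
        return None
    xs, ys = x[ok].astype(float), y[ok].astype(float)
    if xs.std() == 0 or ys.std() == 0:
        return None
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def ld_partners(
    snp_ids: list[str],
    positions: np.ndarray,
    dosages: np.ndarray,
    index_snp: str,
    r2_min: float = 0.3,
    window_kb: int = 1000,
    contigs: list[str] | None = None,
) -> list[LDResult]:
    """Partners of ``index_snp`` with r2 >= r2_min within window_kb, sorted by
    r2 descending. Dosages are a (snp x sample) 0/1/2 matrix with missing < 0;
    monomorphic candidates are skipped with a log entry."""
    try:
        i = snp_ids.index(index_snp)
    except ValueError:
        raise KeyError(f"index SNP {index_snp!r} not in genotype matrix")
    window = window_kb * 1000
    results: list[LDResult] = []
    for j, other in enumerate(snp_ids):
        if j == i:
            continue
        if contigs is not None and contigs[j] != contigs[i]:
            continue
        dist = int(abs(int(positions[j]) - int(positions[i])))
        if dist > window:
            continue
        r2 = _pairwise_r2(dosages[i], dosages[j])
        if r2 is None:
            logger.info("skipping monomorphic/undersampled partner %s", other)
            continue
        if r2 >= r2_min:
            results.append(LDResult(snp_a=index_snp, snp_b=other, r2=r2, distance_bp=dist))
    results.sort(key=lambda r: (-r.r2, r.distance_bp, r.snp_b))
    return results


def ld_to_frame(results: list[LDResult]) -> pd.DataFrame:
    rows = [
        {"snp_a": r.snp_a, "snp_b": r.snp_b, "r2": r.r2, "distance_bp": r.distance_bp}
        for r in results
    ]
    return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2", "distance_bp"])
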