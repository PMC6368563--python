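"""Per-locus consensus prioritization of functional SNPs.

Five annotators are consumed as precomputed per-SNP values: four continuous
"bigger is better" scores (CADD, Eigen, GWAVA, LINSIGHT) and one ordinal
rating (RegulomeDB, "1a" strongest ... "6" weakest). Within each risk locus
the top SNP per scoring method is the argmax (ties kept as sets) and per
rating the argmin. A SNP is a consensus ("overlapping top functional") SNP
when it tops at least two scoring methods, or tops at least one scoring
method and is also the RegulomeDB argmin. Scores are never compared across
loci.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import FormatError

SCORE_METHODS = ("cadd", "eigen", "gwava", "linsight")
RATING_METHOD = "regulomedb"

_RATING_RE = re.compile(r"^([1-6])([a-f])?$")


@dataclass(frozen=True)
class AnnotationScoreRow:
    snp_id: str
    locus_id: str
    cadd: float | None = None
    eigen: float | None = None
    gwava: float | None = None
    linsight: float | None = None
    regulomedb: str | None = None

    def __post_init__(self):
        if all(
            getattr(self, m) is None for m in SCORE_METHODS + (RATING_METHOD,)
        ):
            raise FormatError(f"SNP {self.snp_id}: all annotation fields missing")
        if self.regulomedb is not None:
            parse_rating(self.regulomedb)  # validates


@dataclass
class LocusPriority:
    locus_id: str
    top_by_method: dict[str, set[str]] = field(default_factory=dict)
    consensus_snps: set[str] = field(default_factory=set)

    @property
    def has_consensus(self) -> bool:
        return bool(self.consensus_snps)


def parse_rating(text: str) -> tuple[int, str]:
    """Parse a RegulomeDB rating into an orderable (category, letter) key.

    Categories 1-3 carry a mandatory sub-letter a-f; categories 4-6 are bare.
    A bare "1" is rejected as ambiguous. Ordering: category ascending, then
    letter ascending, so "1a" < "1f" < "2a" < ... < "6".
    """
    m = _RATING_RE.match(str(text).strip().lower())
    if not m:
        raise FormatError(f"unparseable RegulomeDB rating {text!r}")
    category = int(m.group(1))
    letter = m.group(2)
    if category <= 3 and letter is None:
        raise FormatError(
            f"RegulomeDB rating {text!r}: categories 1-3 require a sub-letter"
        )
    if category > 3 and letter is not None:
        raise FormatError(
            f"RegulomeDB rating {text!r}: categories 4-6 take no sub-letter"
        )
    return category, letter or ""


def rows_from_frame(df: pd.DataFrame) -> list[AnnotationScoreRow]:
    rows = []
    for r in df.itertuples(index=False):
        def _num(v):
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

        rating = getattr(r, RATING_METHOD, None)
        if rating is not None and (not isinstance(rating, str)) and pd.isna(rating):
            rating = None
        rows.append(
            AnnotationScoreRow(
                snp_id=str(r.snp_id),
                locus_id=str(r.locus_id),
                cadd=_num(r.cadd),
                eigen=_num(r.eigen),
                gwava=_num(r.gwava),
                linsight=_num(r.linsight),
                regulomedb=None if rating is None else str(rating),
            )
        )
    return rows


def top_by_score(rows: list[AnnotationScoreRow], method: str) -> dict[str, set[str]]:
    """Per locus, the argmax set of one scoring method over non-missing
    values. Loci where every SNP is missing that score are absent."""
    if method not in SCORE_METHODS:
        raise ValueError(f"method {method!r} not one of {SCORE_METHODS}")
    best: dict[str, tuple[float, set[str]]] = {}
    for row in rows:
        value = getattr(row, method)
        if value is None:
            continue
        cur = best.get(row.locus_id)
        if cur is None or value > cur[0]:
            best[row.locus_id] = (value, {row.snp_id})
        elif value == cur[0]:
            cur[1].add(row.snp_id)
    return {locus: snps for locus, (_, snps) in best.items()}


def top_by_rating(rows: list[AnnotationScoreRow]) -> dict[str, set[str]]:
    """Per locus, the argmin set under the RegulomeDB ordinal ordering."""
    best: dict[str, tuple[tuple[int, str], set[str]]] = {}
    for row in rows:
        if row.regulomedb is None:
            continue
        key = parse_rating(row.regulomedb)
        cur = best.get(row.locus_id)
        if cur is None or key < cur[0]:
            best[row.locus_id] = (key, {row.snp_id})
        elif key == cur[0]:
            cur[1].add(row.snp_id)
    return {locus: snps for locus, (_, snps) in best.items()}


def consensus(rows: list[AnnotationScoreRow]) -> list[LocusPriority]:
    """Consensus SNP per locus: argmax of >=2 scoring methods, or argmax of
    >=1 scoring method plus the RegulomeDB argmin."""
    score_tops = {m: top_by_score(rows, m) for m in SCORE_METHODS}
    rating_tops = top_by_rating(rows)
    loci = sorted({row.locus_id for row in rows})
    out: list[LocusPriority] = []
    for locus in loci:
        top_by_method = {
            m: set(score_tops[m].get(locus, set())) for m in SCORE_METHODS
        }
        top_by_method[RATING_METHOD] = set(rating_tops.get(locus, set()))
        snp_score_wins: dict[str, int] = {}
        for m in SCORE_METHODS:
            for snp in top_by_method[m]:
                snp_score_wins[snp] = snp_score_wins.get(snp, 0) + 1
        winners = {
            snp
            for snp, wins in snp_score_wins.items()
            if wins >= 2 or (wins >= 1 and snp in top_by_method[RATING_METHOD])
        }
        out.append(
            LocusPriority(
                locus_id=locus, top_by_method=top_by_method, consensus_snps=winners
            )
        )
    return out


def consensus_to_frames(priorities: list[LocusPriority]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per consensus-SNP rows, per-locus summary) in deterministic order."""
    snp_rows = [
        {"locus_id": p.locus_id, "consensus_snp": snp}
        for p in priorities
        for snp in sorted(p.consensus_snps)
    ]
    locus_rows = [
        {
            "locus_id": p.locus_id,
            "has_consensus": p.has_consensus,
            "n_consensus_snps": len(p.consensus_snps),
        }
        for p in priorities
    ]
    return (
        pd.DataFrame(snp_rows, columns=["locus_id", "consensus_snp"]),
        pd.DataFrame(locus_rows, columns=["locus_id", "has_consensus", "n_consensus_snps"]),
    )
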