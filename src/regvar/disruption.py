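"""Allele-aware disruption calling inside ChIP-Seq peak-summit neighbourhoods.

A candidate variant is paired with every retained peak whose summit lies
within ``flank_summit`` (default 50 bp) of it. For each paired TF motif the
variant's reference and alternative sequence contexts (default +/- 20 bp) are
scanned over every window that overlaps the variant by at least one base, on
both strands, and the variant is called disrupting when at least one allele
attains a match p-value below ``alpha`` (default 1e-3). The definition is
deliberately one-sided over alleles: the presence of a strong site under
either allele, inside a bound region, is the evidence; ``delta_llr`` records
the direction and size of the allelic effect for downstream interpretation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import BoundaryError, NoScorableWindowError, ReferenceMismatchError
from .io import GeneModelInterval, GenomeSequence, PeakRecord, SNVRecord
from .pwm import (
    PWM,
    LogOddsMatrix,
    ScoreDistribution,
    _minus_strand_matrix,
    _window_int_scores,
    build_log_odds,
    encode_sequence,
    exact_pvalue_table,
)

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 1e-3
DEFAULT_FLANK_SUMMIT = 50
DEFAULT_FLANK_CONTEXT = 20


@dataclass(frozen=True)
class AlleleScanResult:
    """Best motif match for one allele over all windows covering the SNP."""

    allele: str
    best_score: float
    best_pvalue: float
    best_window_start: int  # relative to the context sequence
    best_strand: str
    n_windows_scored: int


@dataclass(frozen=True)
class DisruptionCall:
    snp_id: str
    tf_name: str
    motif: str
    ref_result: AlleleScanResult
    alt_result: AlleleScanResult
    disrupts: bool
    delta_llr: float
    peak_id: str

    @property
    def min_pvalue(self) -> float:
        return min(self.ref_result.best_pvalue, self.alt_result.best_pvalue)


def snps_in_summit_windows(
    snps: list[SNVRecord],
    peaks: list[PeakRecord],
    flank: int = DEFAULT_FLANK_SUMMIT,
) -> list[tuple[SNVRecord, PeakRecord]]:
    """Pairs (snp, peak) with |snp.position - summit| <= flank on the same
    contig. A SNP may pair with several peaks (and hence several TFs)."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    by_contig: dict[str, list[PeakRecord]] = {}
    for p in peaks:
        by_contig.setdefault(p.contig, []).append(p)
    summits = {
        contig: np.array([p.summit for p in plist])
        for contig, plist in by_contig.items()
    }
    pairs: list[tuple[SNVRecord, PeakRecord]] = []
    for snp in snps:
        plist = by_contig.get(snp.contig)
        if not plist:
            continue
        hits = np.nonzero(np.abs(summits[snp.contig] - snp.position) <= flank)[0]
        for i in hits:
            pairs.append((snp, plist[i]))
    return pairs


def allele_context(
    genome: dict[str, GenomeSequence],
    snp: SNVRecord,
    flank: int = DEFAULT_FLANK_CONTEXT,
) -> tuple[str, str]:
    """(ref_seq, alt_seq): the +/-flank genomic context around the SNP with the
    centre base set to each allele. The genome base must equal the declared
    reference allele; mismatches are an error rather than silently flipped."""
    contig = genome[snp.contig]
    if snp.position - flank < 0 or snp.position + flank + 1 > len(contig):
        raise BoundaryError(
            f"SNP {snp.snp_id} at {snp.contig}:{snp.position} is within "
            f"{flank} bp of a contig end"
        )
    window = contig.fetch(snp.position - flank, snp.position + flank + 1)
    genome_base = window[flank]
    if genome_base != snp.ref_allele:
        raise ReferenceMismatchError(
            f"SNP {snp.snp_id}: genome has {genome_base!r} at "
            f"{snp.contig}:{snp.position} but ref allele is {snp.ref_allele!r}"
        )
    alt_seq = window[:flank] + snp.alt_allele + window[flank + 1 :]
    return window, alt_seq


def _best_allele_result(
    lom: LogOddsMatrix,
    dist: ScoreDistribution,
    seq: str,
    snp_index: int,
    allele: str,
) -> AlleleScanResult | None:
    """Score every window covering position snp_index on both strands and
    keep the best (lowest p, then highest score, '+' before '-', leftmost)."""
    w = lom.width
    idx = encode_sequence(seq)
    lo = max(0, snp_index - w + 1)
    hi = min(len(seq) - w, snp_index)
    if hi < lo:
        return None
    sub = idx[lo : hi + w]
    best = None
    n_scored = 0
    sentinel = np.iinfo(np.int64).min
    for strand, int_m, float_m in (
        ("+", lom.int_entries, lom.entries),
        ("-", _minus_strand_matrix(lom.int_entries), _minus_strand_matrix(lom.entries)),
    ):
        scores = _window_int_scores(int_m, sub)
        for j, s in enumerate(scores):
            if s == sentinel:  # window contains N
                continue
            n_scored += 1
            p = dist.pvalue(int(s))
            start = lo + j
            window = idx[start : start + w]
            fscore = float(float_m[np.arange(w), window].sum())
            key = (p, -fscore, strand, start)
            if best is None or key < best[0]:
                best = (key, p, fscore, start, strand)
    if best is None:
        return None
    _, p, fscore, start, strand = best
    return AlleleScanResult(
        allele=allele,
        best_score=fscore,
        best_pvalue=p,
        best_window_start=start,
        best_strand=strand,
        n_windows_scored=n_scored,
    )


def call_disruption(
    lom: LogOddsMatrix,
    dist: ScoreDistribution,
    ref_seq: str,
    alt_seq: str,
    snp_index: int,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[AlleleScanResult, AlleleScanResult, bool, float]:
    """Per-allele best matches over SNP-covering windows, plus the verdict:
    disrupts iff min(ref_p, alt_p) < alpha."""
    if len(ref_seq) != len(alt_seq):
        raise ValueError("ref and alt contexts differ in length")
    ref_res = _best_allele_result(lom, dist, ref_seq, snp_index, ref_seq[snp_index])
    alt_res = _best_allele_result(lom, dist, alt_seq, snp_index, alt_seq[snp_index])
    if ref_res is None or alt_res is None:
        raise NoScorableWindowError(
            "no window covering the SNP could be scored (ambiguous bases?)"
        )
    disrupts = ref_res.best_pvalue < alpha or alt_res.best_pvalue < alpha
    delta_llr = ref_res.best_score - alt_res.best_score
    return ref_res, alt_res, disrupts, delta_llr


def run_disruption_screen(
    genome: dict[str, GenomeSequence],
    snps: list[SNVRecord],
    peaks: list[PeakRecord],
    motifs: list[PWM],
    alpha: float = DEFAULT_ALPHA,
    flank_summit: int = DEFAULT_FLANK_SUMMIT,
    flank_context: int = DEFAULT_FLANK_CONTEXT,
    pseudocount_frac: float = 0.1,
    scale: int = 1000,
) -> list[DisruptionCall]:
    """Full screen: pair SNPs with peak summits, scan both alleles against the
    paired TF's motif, call disruption, deduplicate per (snp, tf) keeping the
    call with the smallest min-allele p-value. Per-record failures (reference
    mismatch, contig edge, unscorable windows) are logged and skipped."""
    motif_by_tf: dict[str, tuple[LogOddsMatrix, ScoreDistribution]] = {}
    for pwm in motifs:
        lom = build_log_odds(pwm, pseudocount_frac=pseudocount_frac, scale=scale)
        motif_by_tf[pwm.name] = (lom, exact_pvalue_table(lom))

    pairs = snps_in_summit_windows(snps, peaks, flank=flank_summit)
    logger.info("disruption screen: %d SNP-peak pairs from %d SNPs, %d peaks",
                len(pairs), len(snps), len(peaks))

    best: dict[tuple[str, str], DisruptionCall] = {}
    n_skipped = 0
    for snp, peak in pairs:
        engine = motif_by_tf.get(peak.tf_name)
        if engine is None:
            logger.warning("no motif for TF %s; peak %s skipped", peak.tf_name, peak.peak_id)
            continue
        lom, dist = engine
        try:
            ref_seq, alt_seq = allele_context(genome, snp, flank=flank_context)
            ref_res, alt_res, disrupts, delta = call_disruption(
                lom, dist, ref_seq, alt_seq, flank_context, alpha=alpha
            )
        except (ReferenceMismatchError, BoundaryError, NoScorableWindowError) as exc:
            logger.warning("SNP %s vs peak %s skipped: %s", snp.snp_id, peak.peak_id, exc)
            n_skipped += 1
            continue
        call = DisruptionCall(
            snp_id=snp.snp_id,
            tf_name=peak.tf_name,
            motif=lom.source,
            ref_result=ref_res,
            alt_result=alt_res,
            disrupts=disrupts,
            delta_llr=delta,
            peak_id=peak.peak_id,
        )
        key = (snp.snp_id, peak.tf_name)
        if key not in best or call.min_pvalue < best[key].min_pvalue:
            best[key] = call
    if n_skipped:
        logger.info("disruption screen: %d SNP-peak pairs skipped", n_skipped)
    return [best[k] for k in sorted(best)]


def calls_to_frame(calls: list[DisruptionCall]) -> pd.DataFrame:
    """Flatten calls into the output table contract."""
    rows = [
        {
            "snp_id": c.snp_id,
            "tf_name": c.tf_name,
            "motif": c.motif,
            "ref_best_score": c.ref_result.best_score,
            "ref_best_p": c.ref_result.best_pvalue,
            "alt_best_score": c.alt_result.best_score,
            "alt_best_p": c.alt_result.best_pvalue,
            "delta_llr": c.delta_llr,
            "disrupts": c.disrupts,
            "peak_id": c.peak_id,
            "window_start": c.ref_result.best_window_start,
            "strand": c.ref_result.best_strand,
        }
        for c in calls
    ]
    columns = [
        "snp_id", "tf_name", "motif", "ref_best_score", "ref_best_p",
        "alt_best_score", "alt_best_p", "delta_llr", "disrupts", "peak_id",
        "window_start", "strand",
    ]
    return pd.DataFrame(rows, columns=columns)


def summarize_by_tf(calls: list[DisruptionCall]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-TF count of distinct disrupting SNPs, plus pairwise co-disruption
    counts (SNPs disrupting two TFs at once)."""
    snps_per_tf: dict[str, set[str]] = {}
    tfs_per_snp: dict[str, set[str]] = {}
    for c in calls:
        if not c.disrupts:
            continue
        snps_per_tf.setdefault(c.tf_name, set()).add(c.snp_id)
        tfs_per_snp.setdefault(c.snp_id, set()).add(c.tf_name)
    per_tf = pd.DataFrame(
        [{"tf_name": tf, "n_disrupting_snps": len(s)} for tf, s in sorted(snps_per_tf.items())],
        columns=["tf_name", "n_disrupting_snps"],
    )
    pair_counts: dict[tuple[str, str], int] = {}
    for tfs in tfs_per_snp.values():
        for a, b in combinations(sorted(tfs), 2):
            pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
    pairs = pd.DataFrame(
        [{"tf_a": a, "tf_b": b, "n_shared_snps": n} for (a, b), n in sorted(pair_counts.items())],
        columns=["tf_a", "tf_b", "n_shared_snps"],
    )
    return per_tf, pairs


# ---------------------------------------------------------------------------
# Genomic-context classification (simplified annotator)
# ---------------------------------------------------------------------------

CONTEXT_CATEGORIES = ["exonic", "UTR", "intronic", "upstream", "downstream", "intergenic"]


def genomic_context(
    snps: list[SNVRecord],
    gene_model: list[GeneModelInterval],
    margin: int = 1000,
) -> pd.DataFrame:
    """Assign each SNP one category by fixed precedence: exonic > UTR >
    intronic > upstream > downstream > intergenic (margin 1 kb for up/down,
    oriented by gene strand). This is a deliberately simplified annotator,
    not a re-implementation of a full transcript-model tool; output metadata
    should carry the ``simplified`` label.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for iv in gene_model:
        trees.setdefault((iv.contig, iv.feature), IntervalTree()).addi(
            iv.start, iv.end, iv
        )
    up_trees: dict[str, IntervalTree] = {}
    down_trees: dict[str, IntervalTree] = {}
    for iv in gene_model:
        if iv.feature != "gene":
            continue
        if iv.strand == "-":
            up_iv, down_iv = (iv.end, iv.end + margin), (iv.start - margin, iv.start)
        else:
            up_iv, down_iv = (iv.start - margin, iv.start), (iv.end, iv.end + margin)
        if up_iv[0] < up_iv[1]:
            up_trees.setdefault(iv.contig, IntervalTree()).addi(max(0, up_iv[0]), up_iv[1])
        if down_iv[0] < down_iv[1]:
            down_trees.setdefault(iv.contig, IntervalTree()).addi(max(0, down_iv[0]), down_iv[1])

    def classify(snp: SNVRecord) -> str:
        pos = snp.position
        for feature, label in (("exon", "exonic"), ("utr", "UTR")):
            tree = trees.get((snp.contig, feature))
            if tree is not None and tree.overlaps_point(pos):
                return label
        gene_tree = trees.get((snp.contig, "gene"))
        if gene_tree is not None and gene_tree.overlaps_point(pos):
            return "intronic"
        if snp.contig in up_trees and up_trees[snp.contig].overlaps_point(pos):
            return "upstream"
        if snp.contig in down_trees and down_trees[snp.contig].overlaps_point(pos):
            return "downstream"
        return "intergenic"

    rows = [{"snp_id": s.snp_id, "category": classify(s)} for s in snps]
    return pd.DataFrame(rows, columns=["snp_id", "category"])


def context_fractions(context: pd.DataFrame) -> pd.DataFrame:
    """Category counts and fractions in the fixed category order."""
    counts = context["category"].value_counts()
    total = max(len(context), 1)
    rows = [
        {
            "category": cat,
            "n_snps": int(counts.get(cat, 0)),
            "fraction": counts.get(cat, 0) / total,
        }
        for cat in CONTEXT_CATEGORIES
    ]
    return pd.DataFrame(rows, columns=["category", "n_snps", "fraction"])
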