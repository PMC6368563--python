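"""Ground-truth synthetic data for every input the pipeline consumes.

The generator emulates the study geometry end to end: a random genome with
planted motif consensus sites, ChIP-Seq-like peaks whose summits sit on those
sites, SNPs planted inside motifs (alt allele = the column's worst base, the
strongest possible disruption), benign SNPs inside peak windows but outside
motifs, SNPs far from every peak, five-annotator score tables with a planted
per-locus consensus SNP, eQTL tables in which disrupting SNPs carry an
elevated significance rate, binomial allelic read counts with planted
imbalance, genotype matrices with planted LD partners, and a stage x gene
expression matrix with a planted prenatal elevation of the target genes.

Every generator is a pure function of (parameters, seed). Defaults follow
the study conditions where stated (three TFs x 10 sites, 50 disrupting +
150 benign SNPs on a 1 Mb genome; base eQTL rate 0.3 with 2x planted
enrichment; ~50-read ASE counts); remaining defaults are documented in
docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .errors import PlacementError
from .io import GeneModelInterval, GenomeSequence, PeakRecord, SNVRecord
from .pwm import ALPHABET, PWM, reverse_complement

_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}

RATING_POOL = [f"{c}{l}" for c in "123" for l in "abcdef"] + ["4", "5", "6"]


@dataclass
class SyntheticTruth:
    """What was planted, for parameter-recovery tests."""

    seed: int
    planted_motif_sites: list = field(default_factory=list)  # (tf, contig, start, strand)
    disrupting_snp_ids: set = field(default_factory=set)
    benign_in_peak_snp_ids: set = field(default_factory=set)
    outside_peak_snp_ids: set = field(default_factory=set)
    consensus_snp_by_locus: dict = field(default_factory=dict)
    enriched_eqtl_rate: float = 0.0
    background_eqtl_rate: float = 0.0
    imbalanced_ase_snp_ids: set = field(default_factory=set)
    target_gene_by_snp: dict = field(default_factory=dict)
    target_genes: list = field(default_factory=list)
    background_genes: list = field(default_factory=list)
    prenatal_shift: float = 0.0
    ld_partner_by_index: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def default(o):
            if isinstance(o, set):
                return sorted(o)
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(type(o))

        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=default, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        for key in (
            "disrupting_snp_ids",
            "benign_in_peak_snp_ids",
            "outside_peak_snp_ids",
            "imbalanced_ase_snp_ids",
        ):
            d[key] = set(d[key])
        d["planted_motif_sites"] = [tuple(s) for s in d["planted_motif_sites"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# Genome, motifs, peaks
# ---------------------------------------------------------------------------

def make_genome(
    n_contigs: int = 1,
    length_bp: int = 1_000_000,
    gc: float = 0.41,
    seed: int = 0,
) -> dict[str, GenomeSequence]:
    """I.i.d. random genome at the stated GC content."""
    if length_bp < 10_000:
        raise ValueError("contigs must be >= 10 kb")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    out = {}
    for i in range(n_contigs):
        idx = rng.choice(4, size=length_bp, p=probs)
        seq = bases[idx].tobytes().decode()
        name = f"chrS{i + 1}"
        out[name] = GenomeSequence(name, seq)
    return out


def make_pwms(
    tf_names=("TFA", "TFB", "TFC"),
    width: int = 10,
    dominant: float = 0.9,
    seed: int = 0,
) -> list[PWM]:
    """Informative PWMs: one dominant base per column at probability
    ``dominant``, the rest split evenly. Dominant bases are drawn per seed so
    each TF has a distinct consensus."""
    rng = np.random.default_rng(seed)
    pwms = []
    for name in tf_names:
        cols = rng.integers(0, 4, size=width)
        probs = np.full((width, 4), (1 - dominant) / 3)
        probs[np.arange(width), cols] = dominant
        pwms.append(PWM.from_rows(name, probs))
    return pwms


def plant_motifs_and_peaks(
    genome: dict[str, GenomeSequence],
    pwms: list[PWM],
    n_sites_per_tf: int = 10,
    summit_jitter_bp: int = 5,
    peak_half_width: int = 150,
    neg_log10_q: float = 3.0,
    min_separation: int = 400,
    seed: int = 0,
) -> tuple[dict[str, GenomeSequence], list[PeakRecord], SyntheticTruth]:
    """Write each PWM's consensus at random non-overlapping positions on
    random strands and centre one peak on each site, with the summit jittered
    by at most ``summit_jitter_bp``."""
    if summit_jitter_bp > 10:
        raise ValueError("summit jitter must be <= 10 bp")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)
    contigs = {name: list(g.sequence) for name, g in genome.items()}
    names = sorted(contigs)
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    peaks: list[PeakRecord] = []
    margin = peak_half_width + 100

    for pwm in pwms:
        consensus = pwm.consensus()
        w = pwm.width
        for k in range(n_sites_per_tf):
            placed = False
            for _ in range(2000):
                contig = names[rng.integers(len(names))]
                length = len(contigs[contig])
                start = int(rng.integers(margin, length - margin - w))
                if any(
                    start < e + min_separation and s - min_separation < start + w
                    for s, e in occupied[contig]
                ):
                    continue
                strand = "+" if rng.random() < 0.5 else "-"
                site_seq = consensus if strand == "+" else reverse_complement(consensus)
                contigs[contig][start : start + w] = list(site_seq)
                occupied[contig].append((start, start + w))
                centre = start + w // 2
                jitter = int(rng.integers(-summit_jitter_bp, summit_jitter_bp + 1))
                summit = centre + jitter
                peak_start = summit - peak_half_width
                peak_end = summit + peak_half_width
                peaks.append(
                    PeakRecord(
                        contig=contig,
                        start=peak_start,
                        end=peak_end,
                        summit_offset=summit - peak_start,
                        neg_log10_q=neg_log10_q,
                        tf_name=pwm.name,
                        peak_id=f"{pwm.name}:{contig}:{peak_start}",
                    )
                )
                truth.planted_motif_sites.append((pwm.name, contig, start, strand))
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place site {k + 1} for {pwm.name}; genome too crowded"
                )
    edited = {n: GenomeSequence(n, "".join(chars)) for n, chars in contigs.items()}
    peaks.sort(key=lambda p: (p.contig, p.start, p.tf_name))
    truth.planted_motif_sites.sort(key=lambda s: (s[1], s[2]))
    return edited, peaks, truth


# ---------------------------------------------------------------------------
# SNPs
# ---------------------------------------------------------------------------

def plant_snps(
    truth: SyntheticTruth,
    genome: dict[str, GenomeSequence],
    pwms: list[PWM],
    n_disrupting: int = 50,
    n_benign_in_peak: int = 75,
    n_outside_peak: int = 75,
    flank_summit: int = 50,
    seed: int = 0,
) -> tuple[list[SNVRecord], SyntheticTruth]:
    """Plant three SNP classes against the planted sites.

    Disrupting SNPs sit at informative motif columns with the alt allele set
    to the column's lowest-probability base; benign-in-peak SNPs sit inside
    summit windows but outside every motif footprint; outside-peak SNPs sit
    far from every summit. MAFs are drawn uniform(0.05, 0.5).
    """
    rng = np.random.default_rng(seed)
    pwm_by_name = {p.name: p for p in pwms}
    sites = truth.planted_motif_sites
    if not sites:
        raise PlacementError("no planted sites; run plant_motifs_and_peaks first")
    max_per_site = min(p.width for p in pwms)
    if n_disrupting > len(sites) * max_per_site:
        raise PlacementError("more disrupting SNPs requested than motif columns")

    snvs: list[SNVRecord] = []
    used_positions: set[tuple[str, int]] = set()
    used_cols: dict[int, set[int]] = {i: set() for i in range(len(sites))}

    def new_maf() -> float:
        return float(rng.uniform(0.05, 0.5))

    # --- disrupting: worst-base swaps at informative motif columns ---------
    for i in range(n_disrupting):
        site_idx = i % len(sites)
        tf, contig, start, strand = sites[site_idx]
        pwm = pwm_by_name[tf]
        order = np.argsort(-pwm.probs.max(axis=1))  # most informative first
        col = next(int(c) for c in order if int(c) not in used_cols[site_idx])
        used_cols[site_idx].add(col)
        # column col of the motif: genomic offset depends on strand
        offset = col if strand == "+" else pwm.width - 1 - col
        pos = start + offset
        ref = genome[contig].sequence[pos]
        worst = ALPHABET[int(pwm.probs[col].argmin())]
        alt = worst if strand == "+" else _COMPLEMENT_BASE[worst]
        if alt == ref:  # pick the next-worst base instead
            for b in np.argsort(pwm.probs[col]):
                cand = ALPHABET[int(b)]
                cand = cand if strand == "+" else _COMPLEMENT_BASE[cand]
                if cand != ref:
                    alt = cand
                    break
        snp_id = f"snpD{i + 1:04d}"
        snvs.append(
            SNVRecord(snp_id, contig, pos, ref, alt, maf=new_maf())
        )
        used_positions.add((contig, pos))
        truth.disrupting_snp_ids.add(snp_id)

    # --- benign in peak: inside summit windows, outside motif footprints ---
    site_spans = {}
    for tf, contig, start, strand in sites:
        w = pwm_by_name[tf].width
        site_spans.setdefault(contig, []).append((start, start + w))
    summits = [
        (contig, start + pwm_by_name[tf].width // 2)
        for tf, contig, start, strand in sites
    ]
    for i in range(n_benign_in_peak):
        for _ in range(1000):
            contig, summit = summits[int(rng.integers(len(summits)))]
            pos = int(summit + rng.integers(-flank_summit, flank_summit + 1))
            if (contig, pos) in used_positions:
                continue
            if any(s <= pos < e for s, e in site_spans.get(contig, [])):
                continue
            break
        else:
            raise PlacementError("could not place a benign in-peak SNP")
        ref = genome[contig].sequence[pos]
        alt = str(rng.choice([b for b in ALPHABET if b != ref]))
        snp_id = f"snpB{i + 1:04d}"
        snvs.append(SNVRecord(snp_id, contig, pos, ref, alt, maf=new_maf()))
        used_positions.add((contig, pos))
        truth.benign_in_peak_snp_ids.add(snp_id)

    # --- outside every summit window ---------------------------------------
    summit_arr = {}
    for contig, summit in summits:
        summit_arr.setdefault(contig, []).append(summit)
    summit_arr = {c: np.array(v) for c, v in summit_arr.items()}
    names = sorted(genome)
    for i in range(n_outside_peak):
        for _ in range(1000):
            contig = names[int(rng.integers(len(names)))]
            pos = int(rng.integers(100, len(genome[contig]) - 100))
            if (contig, pos) in used_positions:
                continue
            near = summit_arr.get(contig)
            if near is not None and np.abs(near - pos).min() <= flank_summit + 50:
                continue
            break
        else:
            raise PlacementError("could not place an outside-peak SNP")
        ref = genome[contig].sequence[pos]
        alt = str(rng.choice([b for b in ALPHABET if b != ref]))
        snp_id = f"snpO{i + 1:04d}"
        snvs.append(SNVRecord(snp_id, contig, pos, ref, alt, maf=new_maf()))
        used_positions.add((contig, pos))
        truth.outside_peak_snp_ids.add(snp_id)

    snvs.sort(key=lambda s: (s.contig, s.position))
    return snvs, truth


# ---------------------------------------------------------------------------
# Annotation score tables
# ---------------------------------------------------------------------------

def make_annotation_scores(
    snp_ids: list[str] | None = None,
    n_loci: int = 100,
    snps_per_locus: int = 5,
    planted_consensus_fraction: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Five-annotator score table with one planted consensus SNP per planted
    locus: that SNP leads at least two scoring methods by a clear margin (and
    in half the planted loci also carries the best rating). Returns the table
    and the planted snp-by-locus truth map."""
    rng = np.random.default_rng(seed)
    if snp_ids is None:
        snp_ids = [f"snpL{i + 1:05d}" for i in range(n_loci * snps_per_locus)]
    if len(snp_ids) < n_loci * 2:
        raise ValueError("each locus needs at least 2 SNPs")
    per_locus = len(snp_ids) // n_loci
    rows = []
    planted: dict[str, str] = {}
    methods = ["cadd", "eigen", "gwava", "linsight"]
    for li in range(n_loci):
        locus = f"locus{li + 1:04d}"
        members = snp_ids[li * per_locus : (li + 1) * per_locus]
        scores = {m: rng.uniform(0, 10, size=len(members)) for m in methods}
        ratings = [RATING_POOL[int(r)] for r in rng.integers(1, len(RATING_POOL), size=len(members))]
        if rng.random() < planted_consensus_fraction:
            star = int(rng.integers(len(members)))
            n_methods = int(rng.integers(2, 5))
            lead = rng.choice(len(methods), size=n_methods, replace=False)
            for mi in lead:
                m = methods[mi]
                scores[m][star] = scores[m].max() + rng.uniform(1.0, 2.0)
            if rng.random() < 0.5:
                ratings[star] = "1a"
            planted[locus] = members[star]
        for j, snp in enumerate(members):
            rows.append(
                {
                    "snp_id": snp,
                    "locus_id": locus,
                    "cadd": scores["cadd"][j],
                    "eigen": scores["eigen"][j],
                    "gwava": scores["gwava"][j],
                    "linsight": scores["linsight"][j],
                    "regulomedb": ratings[j],
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["snp_id", "locus_id", "cadd", "eigen", "gwava", "linsight", "regulomedb"],
    )
    return df, planted


# ---------------------------------------------------------------------------
# SNP pool for the resampling nulls
# ---------------------------------------------------------------------------

def make_snp_pool(
    n_pool: int = 5000,
    eqtl_rate: float = 0.3,
    tf_names=("TFA", "TFB", "TFC"),
    tf_shares=None,
    seed: int = 0,
) -> pd.DataFrame:
    """A labelled SNP universe (snp_id, maf, eqtl_flag, tf) for the
    MAF-matched and per-TF nulls; one TF label per SNP."""
    rng = np.random.default_rng(seed)
    if tf_shares is None:
        tf_shares = np.full(len(tf_names), 1 / len(tf_names))
    tf_shares = np.asarray(tf_shares, dtype=float)
    tf_shares = tf_shares / tf_shares.sum()
    return pd.DataFrame(
        {
            "snp_id": [f"pool{i + 1:06d}" for i in range(n_pool)],
            "maf": rng.uniform(0.05, 0.5, size=n_pool),
            "eqtl_flag": rng.random(n_pool) < eqtl_rate,
            "tf": rng.choice(list(tf_names), size=n_pool, p=tf_shares),
        }
    )


# ---------------------------------------------------------------------------
# eQTL / ASE / expression
# ---------------------------------------------------------------------------

def make_eqtl_ase_expression(
    truth: SyntheticTruth,
    snvs: list[SNVRecord],
    enriched_eqtl_rate: float = 0.6,
    background_eqtl_rate: float = 0.3,
    datasets=("CMC", "LIBD", "GTEX"),
    ase_imbalance_ratio: float = 0.9,
    ase_imbalanced_fraction: float = 0.3,
    ase_mean_depth: int = 50,
    prenatal_shift: float = 1.0,
    n_background_genes: int = 200,
    n_stages: int = 16,
    n_prenatal: int = 8,
    seed: int = 0,
):
    """eQTL tables per dataset, allelic read counts, and a stage x gene
    expression matrix, all tied to the planted disruption truth.

    Disrupting SNPs are flagged significant in each dataset at
    ``enriched_eqtl_rate`` (independently per dataset), every other SNP at
    ``background_eqtl_rate``. A fraction of disrupting SNPs receives allelic
    counts at ``ase_imbalance_ratio`` instead of 0.5. Target genes (one per
    disrupting SNP, shared across SNPs of the same TF site) are elevated
    2**prenatal_shift-fold in prenatal stages.
    """
    rng = np.random.default_rng(seed)
    truth.enriched_eqtl_rate = enriched_eqtl_rate
    truth.background_eqtl_rate = background_eqtl_rate
    truth.prenatal_shift = prenatal_shift

    disrupting = sorted(truth.disrupting_snp_ids)
    target_genes = [f"GENE{i + 1:04d}" for i in range(len(disrupting))]
    truth.target_genes = target_genes
    truth.target_gene_by_snp = dict(zip(disrupting, target_genes))
    background_genes = [f"BGGENE{i + 1:04d}" for i in range(n_background_genes)]
    truth.background_genes = background_genes

    thresholds = {"CMC": ("fdr", 0.05), "LIBD": ("fdr", 0.01), "GTEX": ("p", 0.001)}
    eqtl_rows = []
    for snp in snvs:
        gene = truth.target_gene_by_snp.get(
            snp.snp_id,
            background_genes[zlib.crc32(snp.snp_id.encode()) % n_background_genes],
        )
        rate = (
            enriched_eqtl_rate
            if snp.snp_id in truth.disrupting_snp_ids
            else background_eqtl_rate
        )
        for ds in datasets:
            column, thresh = thresholds[ds]
            significant = rng.random() < rate
            if significant:
                p = float(rng.uniform(1e-8, min(thresh, 1e-3) if column == "p" else 1e-4))
                fdr = float(rng.uniform(1e-6, thresh))
            else:
                p = float(rng.uniform(0.01, 1.0))
                fdr = float(rng.uniform(thresh, 1.0))
            eqtl_rows.append(
                {
                    "snp_id": snp.snp_id,
                    "gene": gene,
                    "dataset": ds,
                    "tissue": "brain",
                    "p": p,
                    "fdr": fdr,
                }
            )
    eqtl = pd.DataFrame(
        eqtl_rows, columns=["snp_id", "gene", "dataset", "tissue", "p", "fdr"]
    )

    # --- ASE counts ---------------------------------------------------------
    n_imbalanced = int(round(ase_imbalanced_fraction * len(disrupting)))
    imbalanced = set(
        rng.choice(disrupting, size=n_imbalanced, replace=False) if n_imbalanced else []
    )
    truth.imbalanced_ase_snp_ids = set(map(str, imbalanced))
    ase_rows = []
    for snp_id in disrupting:
        depth = max(1, int(rng.poisson(ase_mean_depth)))
        ratio = ase_imbalance_ratio if snp_id in imbalanced else 0.5
        ref = int(rng.binomial(depth, ratio))
        ase_rows.append(
            {
                "snp_id": snp_id,
                "tissue": "brain",
                "ref_count": ref,
                "alt_count": depth - ref,
            }
        )
    ase = pd.DataFrame(ase_rows, columns=["snp_id", "tissue", "ref_count", "alt_count"])

    # --- expression ---------------------------------------------------------
    all_genes = target_genes + background_genes
    stages = [f"stage{i + 1:02d}" for i in range(n_stages)]
    prenatal_mask = np.arange(n_stages) < n_prenatal
    base = rng.lognormal(mean=1.0, sigma=0.5, size=(len(all_genes), n_stages))
    factor = np.ones((len(all_genes), n_stages))
    factor[: len(target_genes), prenatal_mask] = 2.0 ** prenatal_shift
    expr = pd.DataFrame(base * factor, index=all_genes, columns=stages)
    expr.index.name = "gene"
    stage_meta = pd.DataFrame(
        {
            "stage": stages,
            "order": np.arange(n_stages),
            "prenatal": prenatal_mask.astype(int),
        }
    )
    return eqtl, ase, expr, stage_meta, truth


def make_specificity_table(
    genes: list[str],
    cell_types=("pyramidal", "interneuron", "astrocyte", "microglia"),
    high_fraction: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene, per-cell-type specificity scores in [0, 1]; a fraction of
    genes is specific (> 0.1) in exactly one cell type."""
    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes:
        specific_ct = (
            cell_types[int(rng.integers(len(cell_types)))]
            if rng.random() < high_fraction
            else None
        )
        for ct in cell_types:
            if ct == specific_ct:
                value = float(rng.uniform(0.15, 0.8))
            else:
                value = float(rng.uniform(0.0, 0.1))
            rows.append({"gene": gene, "cell_type": ct, "specificity": value})
    return pd.DataFrame(rows, columns=["gene", "cell_type", "specificity"])


# ---------------------------------------------------------------------------
# Genotypes with planted LD
# ---------------------------------------------------------------------------

def make_genotypes(
    index_snps: list[SNVRecord],
    n_partners_per_index: int = 2,
    n_independent: int = 20,
    n_samples: int = 500,
    partner_flip_prob: float = 0.02,
    seed: int = 0,
) -> tuple[list[str], list[str], np.ndarray, np.ndarray, dict[str, list[str]]]:
    """0/1/2 genotype matrix around each index SNP: a few high-LD partners
    (copies of the index dosages with rare flips) and independent SNPs
    nearby. Returns (snp_ids, contigs, positions, dosages, truth partners)."""
    rng = np.random.default_rng(seed)
    ids: list[str] = []
    contigs: list[str] = []
    positions: list[int] = []
    rows: list[np.ndarray] = []
    partner_truth: dict[str, list[str]] = {}
    for snp in index_snps:
        maf = snp.maf or 0.3
        dos = rng.binomial(2, maf, size=n_samples)
        ids.append(snp.snp_id)
        contigs.append(snp.contig)
        positions.append(snp.position)
        rows.append(dos)
        partners = []
        for j in range(n_partners_per_index):
            pid = f"{snp.snp_id}_ld{j + 1}"
            flip = rng.random(n_samples) < partner_flip_prob
            pdos = np.where(flip, rng.binomial(2, maf, size=n_samples), dos)
            ids.append(pid)
            contigs.append(snp.contig)
            positions.append(snp.position + 1000 * (j + 1))
            rows.append(pdos)
            partners.append(pid)
        for j in range(n_independent):
            iid = f"{snp.snp_id}_rand{j + 1}"
            ids.append(iid)
            contigs.append(snp.contig)
            positions.append(snp.position + 5000 + 500 * j)
            rows.append(rng.binomial(2, float(rng.uniform(0.1, 0.5)), size=n_samples))
        partner_truth[snp.snp_id] = partners
    return ids, contigs, np.array(positions), np.array(rows), partner_truth


# ---------------------------------------------------------------------------
# Full fixture on disk
# ---------------------------------------------------------------------------

def generate_fixture(
    outdir: str | Path,
    seed: int = 0,
    length_bp: int = 1_000_000,
    tf_names=("TFA", "TFB", "TFC"),
    n_sites_per_tf: int = 10,
    n_disrupting: int = 50,
    n_benign_in_peak: int = 75,
    n_outside_peak: int = 75,
    n_loci: int = 100,
    **kwargs,
) -> SyntheticTruth:
    """Write the complete input bundle (FASTA, MEME, narrowPeak, VCF, TSVs)
    plus truth JSON under ``outdir``; child seeds are derived deterministically
    from ``seed``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    child = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]

    genome = make_genome(length_bp=length_bp, seed=child[0], **{
        k: v for k, v in kwargs.items() if k in ("n_contigs", "gc")
    })
    pwms = make_pwms(tf_names=tf_names, seed=child[1])
    genome, peaks, truth = plant_motifs_and_peaks(
        genome, pwms, n_sites_per_tf=n_sites_per_tf, seed=child[2]
    )
    truth.seed = seed
    snvs, truth = plant_snps(
        truth,
        genome,
        pwms,
        n_disrupting=n_disrupting,
        n_benign_in_peak=n_benign_in_peak,
        n_outside_peak=n_outside_peak,
        seed=child[3],
    )
    scores, planted_consensus = make_annotation_scores(n_loci=n_loci, seed=child[4])
    truth.consensus_snp_by_locus = planted_consensus
    eqtl, ase, expr, stage_meta, truth = make_eqtl_ase_expression(
        truth, snvs, seed=child[5]
    )
    pool = make_snp_pool(tf_names=tf_names, seed=child[6])
    index_snps = [s for s in snvs if s.snp_id in truth.disrupting_snp_ids][:5]
    gt_ids, gt_contigs, gt_pos, gt_dos, partner_truth = make_genotypes(
        index_snps, seed=child[7]
    )
    truth.ld_partner_by_index = partner_truth
    spec_table = make_specificity_table(
        truth.target_genes + truth.background_genes, seed=child[6]
    )
    gene_model = make_gene_model(genome, seed=child[4])

    rio.write_fasta(genome.values(), outdir / "genome.fa")
    rio.write_meme_motifs(pwms, outdir / "motifs.meme")
    rio.write_narrowpeak(peaks, outdir / "peaks.narrowPeak")
    rio.write_vcf(snvs, outdir / "snps.vcf")
    snp_tsv = pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in snvs],
            "contig": [s.contig for s in snvs],
            "pos0": [s.position for s in snvs],
            "ref": [s.ref_allele for s in snvs],
            "alt": [s.alt_allele for s in snvs],
            "maf": [s.maf for s in snvs],
        }
    )
    rio.write_dataframe(snp_tsv, outdir / "snps.tsv")
    rio.write_dataframe(scores, outdir / "annotation_scores.tsv")
    rio.write_dataframe(eqtl, outdir / "eqtl.tsv")
    rio.write_dataframe(ase, outdir / "ase.tsv")
    rio.write_dataframe(pool, outdir / "snp_pool.tsv")
    expr.reset_index().to_csv(outdir / "expression.tsv", sep="\t", index=False, float_format="%.6g")
    rio.write_dataframe(stage_meta, outdir / "stages.tsv")
    rio.write_dataframe(spec_table, outdir / "specificity.tsv")
    gt = pd.DataFrame(gt_dos, columns=[f"S{i + 1:03d}" for i in range(gt_dos.shape[1])])
    gt.insert(0, "pos0", gt_pos)
    gt.insert(0, "contig", gt_contigs)
    gt.insert(0, "snp_id", gt_ids)
    rio.write_dataframe(gt, outdir / "genotypes.tsv")
    with open(outdir / "gene_model.tsv", "w") as fh:
        for iv in gene_model:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.feature}\t{iv.strand}\t{iv.name}\n")
    truth.to_json(outdir / "truth.json")
    return truth


def make_gene_model(
    genome: dict[str, GenomeSequence],
    n_genes: int = 20,
    seed: int = 0,
) -> list[GeneModelInterval]:
    """Toy gene model: evenly sprinkled genes with a few exons each and UTRs
    at both ends, for genomic-context classification."""
    rng = np.random.default_rng(seed)
    intervals: list[GeneModelInterval] = []
    for contig, g in sorted(genome.items()):
        length = len(g)
        spacing = length // (n_genes + 1)
        for i in range(n_genes):
            start = spacing * (i + 1)
            gene_len = int(rng.integers(4000, 12000))
            end = min(start + gene_len, length - 1000)
            strand = "+" if rng.random() < 0.5 else "-"
            name = f"{contig}_g{i + 1}"
            intervals.append(GeneModelInterval(contig, start, end, "gene", strand, name))
            n_exons = int(rng.integers(2, 5))
            exon_starts = np.sort(rng.choice(np.arange(start, end - 400, 200), size=n_exons, replace=False))
            for j, es in enumerate(exon_starts):
                ee = int(min(es + int(rng.integers(100, 300)), end))
                intervals.append(GeneModelInterval(contig, int(es), ee, "exon", strand, name))
                if j == 0 and int(es) - 50 > start:
                    # disjoint 5' UTR stub just upstream of the first exon
                    intervals.append(GeneModelInterval(contig, int(es) - 50, int(es), "utr", strand, name))
    return intervals
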