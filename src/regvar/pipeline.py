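"""End-to-end orchestration: configuration, stage wiring, manifest.

``run_all`` executes the full analysis in order — format readers, the
allele-aware disruption screen, per-locus consensus prioritization, the
resampling nulls, eQTL tiering + ASE + LD, and the expression comparisons —
writing one deterministic TSV/JSON per stage plus a manifest with the config
hash, seed and per-stage row counts. Outputs are a pure function of
(inputs, config, seed): stage RNG seeds are derived from the master seed by
stage name, and every writer renders floats at fixed precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import disruption as ddm
from . import enrichment as enr
from . import eqtl_ase as ea
from . import expression as expr
from . import io as rio
from . import prioritize as pri
from .errors import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All input paths and analysis parameters.

    The numeric defaults are the study's operating points: match p-value
    cutoff 1e-3, summit flank 50 bp, context flank 20 bp, peak FDR 5%,
    10,000 simulations for the MAF-matched null and 1000 for the per-TF
    null, MAF bin 0.05, LD r2 cutoff 0.3 with a 1 Mb window, ASE alpha
    0.001, and the per-dataset eQTL rules CMC FDR<0.05 / LIBD FDR<0.01 /
    GTEx P<0.001.
    """

    genome: str = ""
    motifs: str = ""
    peaks: str = ""
    snps: str = ""
    snp_dialect: str = "vcf"
    annotation: str = ""
    eqtl: str = ""
    ase: str = ""
    snp_pool: str = ""
    genotypes: str = ""
    expression: str = ""
    stages: str = ""
    specificity: str = ""
    gene_model: str = ""

    alpha: float = 1e-3
    flank_summit: int = 50
    flank_context: int = 20
    peak_fdr: float = 0.05
    eqtl_rules: dict = field(
        default_factory=lambda: {"CMC": ["fdr", 0.05], "LIBD": ["fdr", 0.01], "GTEX": ["p", 0.001]}
    )
    n_sims_eqtl: int = 10_000
    n_sims_tf: int = 1000
    maf_bin: float = 0.05
    r2_min: float = 0.3
    ld_window_kb: int = 1000
    ase_alpha: float = 0.001
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("alpha", "peak_fdr", "ase_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigurationError(f"{name} = {v} outside (0, 1]")
        if self.flank_summit < 0 or self.flank_context < 0:
            raise ConfigurationError("flanks must be >= 0")
        for name in ("genome", "motifs", "peaks", "snps"):
            path = getattr(self, name)
            if not path:
                raise ConfigurationError(f"required input {name!r} not set")
            if not Path(path).exists():
                raise ConfigurationError(f"{name} path {path!r} does not exist")
        for name in (
            "annotation", "eqtl", "ase", "snp_pool", "genotypes",
            "expression", "stages", "specificity", "gene_model",
        ):
            path = getattr(self, name)
            if path and not Path(path).exists():
                raise ConfigurationError(f"{name} path {path!r} does not exist")

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, derived by stage name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunResult:
    outdir: Path
    manifest: dict
    calls: list
    tf_summary: pd.DataFrame
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    stats: dict = field(default_factory=dict)


def run_all(config: PipelineConfig, outdir: str | Path) -> RunResult:
    """Execute every configured stage; optional stages are skipped when their
    input paths are unset. Writes stage outputs and ``manifest.json``."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages": {},
        "files": [],
        "annotator_note": "genomic-context categories from the simplified built-in annotator",
    }
    tables: dict[str, pd.DataFrame] = {}
    stats: dict = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        rio.write_dataframe(df, path)
        manifest["files"].append(path.name)
        manifest["stages"][name] = {"rows": int(len(df))}
        tables[name] = df
        logger.info("stage %s: %d rows", name, len(df))

    # ------------------------------------------------------------------ load
    genome = rio.read_fasta(config.genome)
    motifs = rio.read_meme_motifs(config.motifs)
    peaks = rio.read_narrowpeak(config.peaks, q_threshold=config.peak_fdr)
    snv_result = rio.read_snvs(config.snps, dialect=config.snp_dialect, with_stats=True)
    snvs = snv_result.records
    manifest["stages"]["inputs"] = {
        "contigs": len(genome),
        "motifs": len(motifs),
        "peaks_retained": len(peaks),
        "snps": len(snvs),
        "indels_skipped": snv_result.n_indels_skipped,
    }

    # ------------------------------------------------------------ disruption
    calls = ddm.run_disruption_screen(
        genome,
        snvs,
        peaks,
        motifs,
        alpha=config.alpha,
        flank_summit=config.flank_summit,
        flank_context=config.flank_context,
    )
    emit("disruption_calls", ddm.calls_to_frame(calls))
    per_tf, co_pairs = ddm.summarize_by_tf(calls)
    emit("tf_summary", per_tf)
    emit("tf_co_disruption", co_pairs)
    disrupting_ids = sorted({c.snp_id for c in calls if c.disrupts})
    stats["n_disrupting_snps"] = len(disrupting_ids)

    # --------------------------------------------------------------- context
    if config.gene_model:
        gene_model = rio.read_gene_model(config.gene_model)
        context = ddm.genomic_context(snvs, gene_model)
        emit("genomic_context", context)
        emit("context_fractions", ddm.context_fractions(context))

    # ------------------------------------------------------------ prioritize
    if config.annotation:
        rows = pri.rows_from_frame(rio.read_annotation_scores(config.annotation))
        priorities = pri.consensus(rows)
        snp_frame, locus_frame = pri.consensus_to_frames(priorities)
        emit("consensus_snps", snp_frame)
        emit("consensus_loci", locus_frame)

    # ------------------------------------------------------------ enrichment
    if config.snp_pool:
        pool_df = rio.read_snp_pool(config.snp_pool)
        pool = enr.SNPPool.from_frame(pool_df)
        snp_by_id = {s.snp_id: s for s in snvs}
        observed_mafs = [
            snp_by_id[s].maf for s in disrupting_ids
            if s in snp_by_id and snp_by_id[s].maf is not None
        ]
        if len(observed_mafs) == len(disrupting_ids) and disrupting_ids:
            observed_count = None
            if config.eqtl:
                # observed = disrupting SNPs CMC-significant in the eQTL table
                # (the screen's SNPs are not members of the reference pool)
                eqtl_df = rio.read_eqtl_table(config.eqtl)
                rules = {k: tuple(v) for k, v in config.eqtl_rules.items()}
                tiers_obs = ea.tier_targets(disrupting_ids, eqtl_df, rules)
                observed_count = int(
                    tiers_obs.loc[
                        tiers_obs["datasets"].str.contains("CMC"), "snp_id"
                    ].nunique()
                )
            result = enr.eqtl_enrichment_z(
                pool,
                disrupting_ids,
                n_sims=config.n_sims_eqtl,
                bin_width=config.maf_bin,
                seed=stage_seed(config.seed, "eqtl_enrichment"),
                observed_mafs=observed_mafs,
                observed_count=observed_count,
            )
            stats["eqtl_enrichment"] = result.to_dict()
            with open(outdir / "eqtl_enrichment.json", "w") as fh:
                json.dump(result.to_dict(), fh, indent=1, sort_keys=True)
            manifest["files"].append("eqtl_enrichment.json")
        if "tf" in pool_df.columns and pool_df["tf"].notna().all():
            observed_counts = {
                row.tf_name: int(row.n_disrupting_snps) for row in per_tf.itertuples()
            }
            tf_null = enr.tf_count_null(
                pool_df,
                m=max(len(disrupting_ids), 1),
                observed_counts=observed_counts,
                n_sims=config.n_sims_tf,
                seed=stage_seed(config.seed, "tf_count_null"),
            )
            emit("tf_count_null", enr.tf_null_to_frame(tf_null))

    # -------------------------------------------------------------- eqtl/ase
    if config.eqtl:
        eqtl_df = rio.read_eqtl_table(config.eqtl)
        rules = {k: tuple(v) for k, v in config.eqtl_rules.items()}
        tiers = ea.tier_targets(disrupting_ids, eqtl_df, rules)
        emit("target_tiers", tiers)
        stats["n_targets_any"] = int((tiers["n_supporting_datasets"] >= 1).sum())
        stats["n_targets_replicated"] = int((tiers["n_supporting_datasets"] >= 2).sum())
        stats["n_targets_full"] = int((tiers["n_supporting_datasets"] >= 3).sum())
    if config.ase:
        ase_df = rio.read_ase_table(config.ase)
        emit("ase_results", ea.ase_table(ase_df, alpha=config.ase_alpha))
    if config.genotypes:
        gt_ids, gt_contigs, gt_pos, gt_dos, = rio.read_genotypes(config.genotypes)
        ld_rows = []
        for snp_id in disrupting_ids:
            if snp_id not in gt_ids:
                continue
            ld_rows.extend(
                ea.ld_partners(
                    gt_ids,
                    gt_pos,
                    gt_dos,
                    snp_id,
                    r2_min=config.r2_min,
                    window_kb=config.ld_window_kb,
                    contigs=gt_contigs,
                )
            )
        emit("ld_partners", ea.ld_to_frame(ld_rows))

    # ------------------------------------------------------------ expression
    if config.expression and config.stages:
        matrix_df, prenatal_mask = rio.read_expression_matrix(config.expression, config.stages)
        matrix = expr.StageExpressionMatrix(matrix_df, prenatal_mask)
        if config.eqtl:
            target_genes = sorted(set(tables.get("target_tiers", pd.DataFrame(columns=["gene"]))["gene"]))
        else:
            target_genes = []
        background_genes = sorted(set(matrix.genes) - set(target_genes))
        if target_genes and background_genes:
            comparison = expr.compare_gene_sets(matrix, target_genes, background_genes)
            stats["expression_comparison"] = comparison
            with open(outdir / "expression_comparison.json", "w") as fh:
                json.dump(comparison, fh, indent=1, sort_keys=True)
            manifest["files"].append("expression_comparison.json")
        if config.specificity and target_genes:
            spec_df = rio.read_specificity_table(config.specificity)
            emit("celltype_counts", expr.celltype_counts(spec_df, target_genes))

    manifest["stats"] = stats
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return RunResult(
        outdir=outdir,
        manifest=manifest,
        calls=calls,
        tf_summary=per_tf,
        tables=tables,
        stats=stats,
    )


def fixture_config(fixture_dir: str | Path, seed: int = 0) -> PipelineConfig:
    """Config wired to the file layout ``synthetic.generate_fixture`` writes."""
    d = Path(fixture_dir)
    return PipelineConfig(
        genome=str(d / "genome.fa"),
        motifs=str(d / "motifs.meme"),
        peaks=str(d / "peaks.narrowPeak"),
        snps=str(d / "snps.vcf"),
        annotation=str(d / "annotation_scores.tsv"),
        eqtl=str(d / "eqtl.tsv"),
        ase=str(d / "ase.tsv"),
        snp_pool=str(d / "snp_pool.tsv"),
        genotypes=str(d / "genotypes.tsv"),
        expression=str(d / "expression.tsv"),
        stages=str(d / "stages.tsv"),
        specificity=str(d / "specificity.tsv"),
        gene_model=str(d / "gene_model.tsv"),
        seed=seed,
    )
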