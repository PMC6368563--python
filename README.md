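# regvar

Allele-aware motif scanning and downstream statistics for identifying
**transcription-factor binding–disrupting regulatory variants** — the class
of non-coding risk SNPs that sit inside ChIP-Seq-supported binding sites and
whose alleles create or destroy a strong motif match. The package is aimed
at regulatory-genomics analysts who have GWAS candidate SNPs, ChIP-Seq peaks
with summits, and binding motifs (PWMs), and want a reproducible, fully
seeded pipeline from raw inputs to prioritized variants, target genes and
expression context.

## The model

A binding motif of width *w* is a position weight matrix **M** of per-column
base probabilities over {A,C,G,T}. A window *x₁…x_w* is scored by the log2
likelihood ratio against a zero-order background **b**,

    S(x) = Σᵢ log2( (M[i, xᵢ] + c·b[xᵢ]) / ((1 + c)·b[xᵢ]) ),   c = 0.1,

and its match p-value is the exact tail probability P(S ≥ s) under the
background, computed by dynamic programming over a discretized score grid
(1000 units per bit); the table provably equals brute-force enumeration of
all 4^w windows on that grid.

A candidate SNP is screened when it lies within ±50 bp of a retained peak
summit (peak FDR ≤ 5%). Both alleles of its ±20 bp context are scanned over
every window overlapping the SNP by ≥1 bp, on both strands, and the SNP
**disrupts** the TF's binding when either allele attains match p < 10⁻³;
Δ-LLR (reference best score minus alternative best score) records the
allelic direction.

Downstream statistics:

* **consensus prioritization** — per risk locus, the SNP that is the argmax
  of ≥2 of four scoring annotators (CADD, Eigen, GWAVA, LINSIGHT), or of ≥1
  scorer plus the RegulomeDB rating argmin;
* **MAF-matched enrichment** — Z = (observed − null mean)/null sd over
  frequency-matched random SNP draws, P = Φ(−|Z|); plus a per-TF
  disruption-count null with add-one empirical p-values;
* **eQTL tiering** — target genes supported by ≥1/≥2/3 independent eQTL
  datasets, each under its own rule (CMC FDR<0.05, LIBD FDR<0.01, GTEx
  P<0.001);
* **allele-specific expression** — exact two-sided binomial test of ref/alt
  read counts, imbalance at P < 0.001;
* **LD partners** — dosage-correlation r² ≥ 0.3 within 1 Mb;
* **expression context** — per-stage gene-set median RPKM trajectories
  compared with Wilcoxon rank-sum tests, and cell-type counts at
  specificity > 0.1.

A seeded synthetic-data generator (`regvar.synthetic`) emulates every input
with planted ground truth, so the full pipeline is testable end to end
without any external download.

## Worked example

```python
from regvar import io as rio, synthetic
from regvar.disruption import run_disruption_screen, summarize_by_tf

truth = synthetic.generate_fixture("fixture", seed=7, length_bp=300_000,
                                   n_sites_per_tf=5, n_disrupting=15,
                                   n_benign_in_peak=20, n_outside_peak=20)
calls = run_disruption_screen(
    rio.read_fasta("fixture/genome.fa"),
    rio.read_snvs("fixture/snps.vcf"),
    rio.read_narrowpeak("fixture/peaks.narrowPeak"),
    rio.read_meme_motifs("fixture/motifs.meme"),
)
called = {c.snp_id for c in calls if c.disrupts}
print(len(called & truth.disrupting_snp_ids), "of", len(truth.disrupting_snp_ids))
```

prints

```
planted disrupting SNPs recovered: 15/15
calls among outside-peak SNPs: 0

disrupting SNPs per TF:
tf_name  n_disrupting_snps
    TFA                  5
    TFB                  5
    TFC                  5
```

All 15 SNPs planted at informative motif columns are flagged (their
reference allele carries a match at p ≪ 10⁻³), and no SNP outside every
summit window is ever called — those SNPs never enter the screen. The
`examples/` directory holds one short script per capability (motif
p-values, the screen, prioritization, enrichment nulls, ASE + LD,
expression stages), each printing the numbers it computes.

A thin CLI mirrors the library: `regvar simulate | scan | prioritize |
enrich | ase | ld | expression | run` (see `regvar --help`).

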