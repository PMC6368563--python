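# Methods

## Motif model and exact match p-values

Binding preferences are position weight matrices (PWMs): per-column base
probabilities over {A,C,G,T}, carried in MEME minimal motif format. Scores
are pseudocount-regularized log2 likelihood ratios against a zero-order
background (independent, position-free base frequencies): entry(i, a) =
log2((p[i,a] + c·b[a]) / ((1+c)·b[a])). The additive pseudocount c = 0.1
guarantees finite entries on zero-probability cells; because only p-values
cross module boundaries, the log base is internal.

Match significance is exact, not sampled: entries are discretized at
`scale` = 1000 grid units per bit and the null distribution of the integer
score is built by one convolution per motif column,
D_i(s) = Σ_a b[a] · D_{i−1}(s − e[i,a]), from D_0 = {0: 1}. The survival
function of that table is the match p-value. On the integer grid this equals
brute-force enumeration of all 4^w windows — bitwise for a uniform
background, whose probabilities are dyadic, and to ~1e-12 otherwise. The
absolute discretization error of a width-w score is at most w/(2·scale)
bits, i.e. the relative p-value error stays below ~1e-3 for w ≤ 25.
Threshold queries ("smallest score with p ≤ α") are answered on the
achievable support only. The background defaults to the motif file's stated
frequencies, else uniform; per-sequence background estimation is
deliberately not done (the null is a fixed zero-order model).

## Disruption screen

Candidate variants are gated by ChIP-Seq evidence first: a SNP is screened
against a TF only when it lies within ±50 bp of a retained peak summit
(peaks kept at FDR ≤ 5%, i.e. narrowPeak −log10 q ≥ 1.30103 under the ENCODE
encoding; a summit column of −1 falls back to the interval midpoint). For
each paired (SNP, TF), the ±20 bp reference and alternative contexts are
scored over every window start overlapping the SNP by at least one base
(starts in [pos−w+1, pos]), on both strands — the minus strand scores the
reverse complement against the forward matrix. The SNP disrupts when either
allele's best window reaches p < 10⁻³. The rule is intentionally one-sided
over alleles (presence of a strong site under either allele inside a bound
region); Δ-LLR = ref best score − alt best score records the allelic
direction, and an optional differential filter (exactly one allele passing
and |Δ| > 0) can be enabled in code but is off by default.

Degenerate inputs are skipped and logged rather than fatal: genome base ≠
declared reference allele (never silently strand/allele-flipped), SNPs
within a flank of a contig end, windows containing N. Multiple peaks for
one (SNP, TF) are deduplicated keeping the call with the smallest
min-allele p-value; output order is (snp_id, tf_name).

Genomic-context classification (exonic > UTR > intronic > upstream >
downstream > intergenic, 1 kb up/downstream margins oriented by gene
strand) is a deliberately simplified annotator over a gene-interval model;
its output is labelled as such in the run manifest.

## Consensus prioritization

Within each risk locus the four "bigger is better" annotators compete by
argmax over non-missing scores (ties kept as sets; the sources state no tie
rule) and RegulomeDB by argmin under the ordinal grammar: categories 1–3
require a sub-letter a–f, 4–6 are bare, "1a" < "1f" < "2a" < … < "6"; a
bare "1" is rejected as ambiguous. A SNP is a consensus SNP when it tops ≥2
scoring methods, or ≥1 scoring method while also holding the rating argmin.
A SNP topping RegulomeDB alone does not qualify. Scores are never compared
across loci, and a missing score excludes a SNP only from that method's
competition.

## Resampling nulls

**MAF-matched enrichment.** Minor-allele frequencies are binned at width
0.05 on (0, 0.5] (the right edge folds into the last bin; the width is
configurable since the matching tolerance is a free choice). A matched
random set draws one pool SNP per observed SNP, uniformly without
replacement within the observed SNP's bin; an under-populated bin raises an
explicit infeasibility error naming the bin. The test statistic is
Z = (observed eQTL-significant count − null mean)/null sd over n_sims =
10,000 simulations by default, converted one-tailed as P = Φ(−|Z|) (the
convention of the R call `pnorm(-abs(Z))`; a two-tailed flag doubles it).
Within a bin the count of flagged members of a matched draw is exactly
hypergeometric, so the null count vector is sampled per bin from that law —
identical in distribution to materializing each matched draw and counting,
and fast enough for replicate-level calibration experiments.
`maf_matched_sample` still materializes explicit draws where the actual SNP
identities are wanted. Observed SNPs are not excluded from the pool by
default (exclusion is a flag).

**Per-TF count null.** m SNPs (m = the observed disrupting-SNP count) are
drawn without replacement from the labelled disrupting-SNP pool n_sims =
1000 times via multivariate hypergeometric sampling; each TF reports the
null mean, sd and the add-one empirical p-value (r+1)/(n_sims+1), which
floors at 1/(n_sims+1) rather than zero. With one TF label per SNP the
per-TF null means sum to m exactly.

## eQTL tiering, ASE, LD

Each eQTL dataset keeps its own published significance rule — CMC FDR <
0.05, LIBD FDR < 0.01, GTEx nominal P < 0.001 — consumed precomputed, with
no cross-dataset FDR recomputation. A dataset counts once per (SNP, gene)
regardless of how many tissues pass; tiers are any (≥1), replicated (≥2),
full (=3).

Allelic imbalance uses the exact two-sided binomial test in its
minimum-likelihood form (sum of P(k) over outcomes no more likely than the
observation), which at the 0.5 null coincides with symmetric tail doubling;
imbalance is declared at P < 0.001. Rows with zero total reads are dropped
with a message.

LD is composite (dosage-correlation) r²: the squared Pearson correlation of
0/1/2 genotype vectors over pairwise-complete samples — a deliberate
simplification of haplotype-EM r², adequate for the ≥ 0.3 screening use.
Partners are reported within 1 Mb at r² ≥ 0.3, sorted by r² descending;
monomorphic candidates are skipped with a log entry.

## Expression comparisons

The unit of comparison is the per-stage median RPKM of a gene set (set
semantics; genes absent from the matrix are logged and ignored, an empty
intersection is an error). Wilcoxon rank-sum tests compare target vs
background trajectories across stages and, within the target set, prenatal
vs postnatal stage medians; the prenatal/postnatal split comes from
explicit stage metadata, never inferred from labels. Tests are exact for
small tie-free samples and tie-corrected normal otherwise; a comparison
with zero rank variance (identical tied samples) reports p = 1. Tests are
two-sided by default with one-sided variants available. Cell-type counts
use a strict specificity cutoff (> 0.1): a gene at exactly 0.1 does not
count, and a gene may count in several cell types.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study geometry end to end with planted truth.
Default conditions: a 1 Mb i.i.d. genome at GC 0.41; 3 TFs × 10
non-overlapping consensus sites on random strands, each under a 300 bp peak
whose summit sits at the site centre ± ≤5 bp jitter, q-value above the
retention threshold; 50 disrupting SNPs at maximally informative motif
columns with the alternative allele set to the column's worst base (the
strongest possible signal — power analyses vary this deliberately), 75
benign SNPs inside summit windows but outside motifs, 75 SNPs far from
every summit; MAFs uniform(0.05, 0.5). Annotation tables plant one
consensus leader per locus (margin ≥ 1 over the runner-up in ≥2 methods,
best rating in half of loci). eQTL tables flag disrupting SNPs significant
at rate 0.6 vs 0.3 elsewhere, independently per dataset — a 2× planted
enrichment. ASE counts are Binomial(~Poisson(50), 0.5), with 30% of
disrupting SNPs at ratio 0.9. Target genes are elevated 2-fold in the 8
prenatal of 16 stages. Genotypes plant 2 high-LD partners (2% flip rate)
and 20 independent neighbours per index SNP. Every generator is a pure
function of (parameters, seed); the pipeline derives stage seeds from the
master seed by stage name, and all writers render floats at 6 significant
digits, so whole runs are byte-reproducible.

What the generator does **not** emulate: realistic site-frequency spectra
(MAFs are uniform), LD structure beyond planted correlated columns,
sequence composition biases, overlapping or clustered binding sites, motif
variants diverging from the consensus, read-level noise, or covariate
structure in eQTL/ASE data (GTEx's ASE machinery corrects mapping bias and
covariates; here the plain binomial rule is the model). Passing tests
therefore demonstrate correctness of the algorithms under the stated
statistical model, not performance on real genomes.

## Problem sizes and other choices

The test suite and the acceptance script run the full fixture at the
default conditions above, the p-value oracle on 50 random PWMs of width
4–8, null calibration with 200 replicates of 500 simulations each at
m = 132 over a 4000-SNP pool, and power checks with 100 replicates — sizes
chosen so the whole suite completes in seconds while keeping Monte-Carlo
standard errors well inside the asserted bands. Known limitations: exact
numeric parity with any specific FIMO release is not promised (pseudocount
and discretization conventions are stated here, not inherited), only parity
with enumeration under this package's conventions; the genomic-context
annotator is a simplification; and the enrichment null assumes
exchangeability of SNPs within a MAF bin.
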