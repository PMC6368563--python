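"""Readers and writers for every external format the pipeline touches.

Internal coordinates are 0-based half-open everywhere; conversion to and from
1-based conventions (VCF) happens only here, at the I/O boundary.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConsistencyError, FormatError
from .pwm import PWM

VALID_BASES = frozenset("ACGT")
GENOME_ALPHABET = frozenset("ACGTN")
ALPHABET = "ACGT"


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSequence:
    """A single contig: upper-case sequence over {A,C,G,T,N}."""

    name: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise FormatError(f"contig {self.name!r} has empty sequence")
        bad = set(self.sequence) - GENOME_ALPHABET
        if bad:
            raise FormatError(
                f"contig {self.name!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        if start < 0 or end > len(self.sequence):
            raise IndexError(f"[{start}, {end}) outside contig {self.name!r}")
        return self.sequence[start:end]


@dataclass(frozen=True)
class PeakRecord:
    """One ChIP-Seq peak with its summit, 0-based half-open coordinates."""

    contig: str
    start: int
    end: int
    summit_offset: int
    neg_log10_q: float
    tf_name: str
    peak_id: str = ""

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise FormatError(
                f"peak {self.peak_id or self.tf_name}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if not 0 <= self.summit_offset < self.end - self.start:
            raise FormatError(
                f"peak {self.peak_id or self.tf_name}: summit offset "
                f"{self.summit_offset} outside [0, {self.end - self.start})"
            )

    @property
    def summit(self) -> int:
        """Absolute 0-based summit position."""
        return self.start + self.summit_offset


@dataclass(frozen=True)
class SNVRecord:
    """A biallelic single-nucleotide variant (indels are rejected)."""

    snp_id: str
    contig: str
    position: int  # 0-based
    ref_allele: str
    alt_allele: str
    maf: float | None = None
    locus_id: str | None = None

    def __post_init__(self):
        if self.ref_allele not in VALID_BASES or self.alt_allele not in VALID_BASES:
            raise FormatError(
                f"SNV {self.snp_id}: alleles must be single bases in ACGT, "
                f"got {self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise FormatError(f"SNV {self.snp_id}: ref and alt alleles are identical")
        if self.maf is not None and not 0.0 < self.maf <= 0.5:
            raise FormatError(f"SNV {self.snp_id}: MAF {self.maf} outside (0, 0.5]")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a (plain, uncompressed) FASTA file into contig records."""
    contigs: dict[str, GenomeSequence] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    contigs[name] = GenomeSequence(name, "".join(chunks))
                name = line[1:].split()[0]
                if not name:
                    raise FormatError("empty FASTA header", line=lineno)
                chunks = []
            else:
                if name is None:
                    raise FormatError("sequence before first FASTA header", line=lineno)
                chunks.append(line.upper())
    if name is not None:
        contigs[name] = GenomeSequence(name, "".join(chunks))
    if not contigs:
        raise FormatError(f"no sequences found in {path}")
    return contigs


def write_fasta(contigs: Iterable[GenomeSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for contig in contigs:
            fh.write(f">{contig.name}\n")
            seq = contig.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def read_meme_motifs(path: str | Path) -> list[PWM]:
    """Parse a MEME minimal motif file into PWMs.

    Background frequencies are taken from the file when a
    "Background letter frequencies" block is present, otherwise uniform.
    Probability rows are renormalized to sum to one; duplicate motif names
    are disambiguated with an ordinal suffix so that downstream joins on
    the motif name are unambiguous.
    """
    with open(path) as fh:
        lines = fh.readlines()

    background = (0.25, 0.25, 0.25, 0.25)
    motifs: list[PWM] = []
    seen_names: dict[str, int] = {}
    i = 0
    n = len(lines)
    saw_version = False

    def _floats(line: str, lineno: int, expected: int) -> list[float]:
        parts = line.split()
        try:
            vals = [float(p) for p in parts]
        except ValueError:
            raise FormatError(f"expected numeric fields, got {line.strip()!r}", line=lineno)
        if len(vals) != expected:
            raise FormatError(
                f"expected {expected} values, got {len(vals)}", line=lineno
            )
        for v in vals:
            if not 0.0 <= v <= 1.0 + 1e-9:
                raise FormatError(f"probability {v} outside [0, 1]", line=lineno)
        return vals

    while i < n:
        line = lines[i].strip()
        if line.startswith("MEME version"):
            saw_version = True
        elif line.startswith("Background letter frequencies"):
            i += 1
            if i >= n:
                raise FormatError("missing background frequency line", line=i)
            parts = lines[i].split()
            # format: "A 0.3 C 0.2 G 0.2 T 0.3"
            try:
                freq = {parts[j]: float(parts[j + 1]) for j in range(0, len(parts), 2)}
                background = tuple(freq[b] for b in ALPHABET)
            except (IndexError, KeyError, ValueError):
                raise FormatError(
                    f"malformed background line {lines[i].strip()!r}", line=i + 1
                )
        elif line.startswith("MOTIF"):
            fields = line.split()
            if len(fields) < 2:
                raise FormatError("MOTIF line without a name", line=i + 1)
            name = fields[1]
            if name in seen_names:
                seen_names[name] += 1
                name = f"{name}_{seen_names[fields[1]]}"
            else:
                seen_names[name] = 1
            # find the letter-probability header
            i += 1
            while i < n and not lines[i].strip().startswith("letter-probability matrix"):
                if lines[i].strip().startswith("MOTIF"):
                    raise FormatError(
                        f"MOTIF {name} has no letter-probability matrix", line=i + 1
                    )
                i += 1
            if i >= n:
                raise FormatError(f"MOTIF {name} has no letter-probability matrix")
            header = lines[i].strip()
            width = None
            tokens = header.replace("=", " = ").split()
            for j, tok in enumerate(tokens):
                if tok == "w" and j + 2 < len(tokens) and tokens[j + 1] == "=":
                    width = int(tokens[j + 2])
                if tok == "alength" and j + 2 < len(tokens) and tokens[j + 1] == "=":
                    if int(tokens[j + 2]) != 4:
                        raise FormatError(
                            f"alphabet length {tokens[j + 2]} != 4", line=i + 1
                        )
            rows: list[list[float]] = []
            if width is not None:
                for _ in range(width):
                    i += 1
                    if i >= n or not lines[i].strip():
                        raise FormatError(
                            f"MOTIF {name}: matrix shorter than declared width {width}",
                            line=i + 1,
                        )
                    rows.append(_floats(lines[i], i + 1, 4))
            else:
                # width undeclared: read rows until a blank line or new block
                while i + 1 < n:
                    nxt = lines[i + 1].strip()
                    if not nxt or nxt.startswith(("MOTIF", "Background", "URL")):
                        break
                    i += 1
                    rows.append(_floats(lines[i], i + 1, 4))
                if not rows:
                    raise FormatError(f"MOTIF {name}: empty matrix", line=i + 1)
            motifs.append(PWM.from_rows(name, rows, background))
        i += 1

    if not saw_version:
        raise FormatError("missing 'MEME version' header line", line=1)
    return motifs


def write_meme_motifs(motifs: Sequence[PWM], path: str | Path) -> None:
    """Write PWMs in MEME minimal motif format (version 4)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        if motifs:
            bg = motifs[0].background
            fh.write("Background letter frequencies\n")
            fh.write(
                " ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, bg)) + "\n\n"
            )
        for pwm in motifs:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width}\n")
            for row in pwm.probs:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# ENCODE narrowPeak
# ---------------------------------------------------------------------------

def read_narrowpeak(
    path: str | Path,
    q_threshold: float = 0.05,
    with_dropped: bool = False,
):
    """Read a 10-column narrowPeak file, keeping peaks at FDR <= q_threshold.

    The q-value column is interpreted as -log10(FDR) per ENCODE convention,
    so the filter is neg_log10_q >= -log10(q_threshold). A summit column of
    -1 falls back to the interval midpoint. The peak's name column is used
    as the TF label.
    """
    if not 0 < q_threshold <= 1:
        raise ValueError(f"q_threshold {q_threshold} outside (0, 1]")
    min_nlq = -math.log10(q_threshold)
    retained: list[PeakRecord] = []
    dropped: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) != 10:
                raise FormatError(
                    f"narrowPeak requires 10 columns, got {len(cols)}", line=lineno
                )
            try:
                start, end = int(cols[1]), int(cols[2])
                neg_log10_q = float(cols[8])
                summit = int(cols[9])
            except ValueError:
                raise FormatError(f"non-numeric coordinate field in {line!r}", line=lineno)
            if start < 0:
                raise FormatError(f"negative start coordinate {start}", line=lineno)
            if summit == -1:
                summit = (end - start) // 2
            peak = PeakRecord(
                contig=cols[0],
                start=start,
                end=end,
                summit_offset=summit,
                neg_log10_q=neg_log10_q,
                tf_name=cols[3].split(".")[0],
                peak_id=f"{cols[3]}:{lineno}",
            )
            if neg_log10_q >= min_nlq:
                retained.append(peak)
            else:
                dropped.append(peak)
    if with_dropped:
        return retained, dropped
    return retained


def write_narrowpeak(peaks: Sequence[PeakRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    [
                        p.contig,
                        str(p.start),
                        str(p.end),
                        p.tf_name,
                        "0",
                        ".",
                        "0",
                        "-1",
                        f"{p.neg_log10_q:g}",
                        str(p.summit_offset),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# SNVs: VCF-lite and TSV
# ---------------------------------------------------------------------------

@dataclass
class SNVReadResult:
    records: list[SNVRecord]
    n_indels_skipped: int = 0


def read_snvs(path: str | Path, dialect: str = "vcf", with_stats: bool = False):
    """Read SNVs from a VCF subset (CHROM/POS/ID/REF/ALT) or a TSV.

    VCF positions (1-based) are converted to the internal 0-based convention;
    multi-allelic rows are expanded to one record per alt allele; any record
    with an allele longer than one base (an indel) is skipped and counted.
    The TSV dialect requires a header with 0-based positions in a column
    named ``pos0`` (plus snp_id, contig, ref, alt; optional maf, locus_id).
    """
    if dialect == "vcf":
        result = _read_snvs_vcf(path)
    elif dialect == "tsv":
        result = _read_snvs_tsv(path)
    else:
        raise ValueError(f"unknown SNV dialect {dialect!r}")
    _check_coordinate_consistency(result.records)
    if with_stats:
        return result
    return result.records


def _check_coordinate_consistency(records: list[SNVRecord]) -> None:
    seen: dict[str, tuple[str, int]] = {}
    for r in records:
        key = (r.contig, r.position)
        if r.snp_id in seen and seen[r.snp_id] != key:
            raise ConsistencyError(
                f"snp_id {r.snp_id} appears at both {seen[r.snp_id]} and {key}"
            )
        seen[r.snp_id] = key


def _read_snvs_vcf(path: str | Path) -> SNVReadResult:
    records: list[SNVRecord] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise FormatError(
                    f"VCF data line needs >= 5 columns, got {len(cols)}", line=lineno
                )
            chrom, pos_s, snp_id, ref, alts = cols[0], cols[1], cols[2], cols[3], cols[4]
            try:
                pos1 = int(pos_s)
            except ValueError:
                raise FormatError(f"non-integer POS {pos_s!r}", line=lineno)
            maf = None
            locus = None
            if len(cols) >= 8 and cols[7] not in (".", ""):
                for item in cols[7].split(";"):
                    key, _, value = item.partition("=")
                    if key == "MAF" and value:
                        try:
                            maf = float(value)
                        except ValueError:
                            raise FormatError(f"non-numeric MAF {value!r}", line=lineno)
                    elif key == "LOCUS" and value:
                        locus = value
            for alt in alts.split(","):
                if len(ref) != 1 or len(alt) != 1:
                    n_skipped += 1
                    continue
                records.append(
                    SNVRecord(
                        snp_id=snp_id,
                        contig=chrom,
                        position=pos1 - 1,
                        ref_allele=ref.upper(),
                        alt_allele=alt.upper(),
                        maf=maf,
                        locus_id=locus,
                    )
                )
    return SNVReadResult(records, n_skipped)


def _read_snvs_tsv(path: str | Path) -> SNVReadResult:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    required = {"snp_id", "contig", "pos0", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"SNV TSV missing columns {sorted(missing)}")
    records: list[SNVRecord] = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        ref, alt = str(row.ref), str(row.alt)
        if len(ref) != 1 or len(alt) != 1:
            n_skipped += 1
            continue
        maf = getattr(row, "maf", None)
        if maf is not None and pd.isna(maf):
            maf = None
        locus = getattr(row, "locus_id", None)
        if locus is not None and pd.isna(locus):
            locus = None
        records.append(
            SNVRecord(
                snp_id=str(row.snp_id),
                contig=str(row.contig),
                position=int(row.pos0),
                ref_allele=ref.upper(),
                alt_allele=alt.upper(),
                maf=None if maf is None else float(maf),
                locus_id=None if locus is None else str(locus),
            )
        )
    return SNVReadResult(records, n_skipped)


def write_vcf(records: Sequence[SNVRecord], path: str | Path) -> None:
    """Write SNVs as a minimal VCF v4.2 (positions back to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            info = []
            if r.maf is not None:
                info.append(f"MAF={r.maf:.6g}")
            if r.locus_id is not None:
                info.append(f"LOCUS={r.locus_id}")
            fh.write(
                "\t".join(
                    [
                        r.contig,
                        str(r.position + 1),
                        r.snp_id,
                        r.ref_allele,
                        r.alt_allele,
                        ".",
                        ".",
                        ";".join(info) or ".",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Generic deterministic TSV writer
# ---------------------------------------------------------------------------

def _format_value(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, bool):
        return str(v)
    if isinstance(v, float):
        if math.isnan(v):
            return "NA"
        return f"{v:.6g}"
    return str(v)


def write_table(rows: Sequence, path: str | Path, columns: list[str] | None = None) -> None:
    """Write homogeneous records (dataclasses or dicts) as a reproducible TSV.

    Column order follows dataclass field order (or the given list); floats are
    rendered with 6 significant digits so identical inputs give identical bytes.
    """
    rows = list(rows)
    if columns is None:
        if rows and dataclasses.is_dataclass(rows[0]):
            columns = [f.name for f in dataclasses.fields(rows[0])]
        elif rows and isinstance(rows[0], dict):
            columns = list(rows[0].keys())
        else:
            columns = []
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            if dataclasses.is_dataclass(row):
                values = [getattr(row, c) for c in columns]
            else:
                values = [row[c] for c in columns]
            fh.write("\t".join(_format_value(v) for v in values) + "\n")


def write_dataframe(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV dump of a DataFrame (6 significant digits)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Gene model (for genomic-context classification)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModelInterval:
    contig: str
    start: int
    end: int
    feature: str  # gene | exon | utr
    strand: str = "+"
    name: str = ""


def read_gene_model(path: str | Path) -> list[GeneModelInterval]:
    """Read a gene model from a 4/5-column interval TSV or a BED12 file.

    TSV columns: contig, start, end, feature[, strand[, name]] with feature in
    {gene, exon, utr}. BED12 rows are expanded to one gene interval, exon
    intervals from the blocks, and UTRs from thickStart/thickEnd.
    """
    intervals: list[GeneModelInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) == 12:
                intervals.extend(_bed12_to_intervals(cols, lineno))
            elif 4 <= len(cols) <= 6:
                feature = cols[3].lower()
                if feature not in {"gene", "exon", "utr"}:
                    raise FormatError(f"unknown feature {cols[3]!r}", line=lineno)
                intervals.append(
                    GeneModelInterval(
                        contig=cols[0],
                        start=int(cols[1]),
                        end=int(cols[2]),
                        feature=feature,
                        strand=cols[4] if len(cols) > 4 else "+",
                        name=cols[5] if len(cols) > 5 else "",
                    )
                )
            else:
                raise FormatError(
                    f"gene model rows need 4-6 (TSV) or 12 (BED12) columns, got {len(cols)}",
                    line=lineno,
                )
    return intervals


def _bed12_to_intervals(cols: list[str], lineno: int) -> list[GeneModelInterval]:
    try:
        chrom = cols[0]
        start, end = int(cols[1]), int(cols[2])
        name, strand = cols[3], cols[5]
        thick_start, thick_end = int(cols[6]), int(cols[7])
        n_blocks = int(cols[9])
        sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
        offsets = [int(x) for x in cols[11].rstrip(",").split(",")]
    except (ValueError, IndexError):
        raise FormatError("malformed BED12 row", line=lineno)
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise FormatError("BED12 block count mismatch", line=lineno)
    out = [GeneModelInterval(chrom, start, end, "gene", strand, name)]
    # split each block into disjoint coding (exon) and UTR parts so that the
    # downstream category precedence never sees a base labelled both ways
    for size, off in zip(sizes, offsets):
        ex_start, ex_end = start + off, start + off + size
        cds_start, cds_end = max(ex_start, thick_start), min(ex_end, thick_end)
        if cds_start < cds_end:
            out.append(GeneModelInterval(chrom, cds_start, cds_end, "exon", strand, name))
        if ex_start < min(ex_end, thick_start):
            out.append(
                GeneModelInterval(chrom, ex_start, min(ex_end, thick_start), "utr", strand, name)
            )
        if max(ex_start, thick_end) < ex_end:
            out.append(
                GeneModelInterval(chrom, max(ex_start, thick_end), ex_end, "utr", strand, name)
            )
    return out


# ---------------------------------------------------------------------------
# Tabular inputs for downstream modules (thin pandas wrappers with validation)
# ---------------------------------------------------------------------------

def read_annotation_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "locus_id": str})
    required = {"snp_id", "locus_id", "cadd", "eigen", "gwava", "linsight", "regulomedb"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"annotation table missing columns {sorted(missing)}")
    return df


def read_eqtl_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "gene": str})
    required = {"snp_id", "gene", "dataset", "tissue", "p"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"eQTL table missing columns {sorted(missing)}")
    if "fdr" not in df.columns:
        df["fdr"] = float("nan")
    bad = df[(df["p"] <= 0) | (df["p"] > 1)]
    if len(bad):
        raise FormatError(f"eQTL table has {len(bad)} p-values outside (0, 1]")
    return df


def read_ase_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    required = {"snp_id", "tissue", "ref_count", "alt_count"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"ASE table missing columns {sorted(missing)}")
    return df


def read_snp_pool(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    required = {"snp_id", "maf", "eqtl_flag"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"SNP pool missing columns {sorted(missing)}")
    if df["snp_id"].duplicated().any():
        raise ConsistencyError("SNP pool has duplicated snp_ids")
    if "tf" not in df.columns:
        df["tf"] = None
    return df


def read_genotypes(path: str | Path):
    """Read a genotype matrix TSV: snp_id, contig, pos0, then one 0/1/2 column
    per sample (-1 or NA = missing). Returns (ids, contigs, positions, dosages)."""
    import numpy as np

    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "contig": str})
    required = {"snp_id", "contig", "pos0"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"genotype table missing columns {sorted(missing)}")
    sample_cols = [c for c in df.columns if c not in required]
    if not sample_cols:
        raise FormatError("genotype table has no sample columns")
    dosages = df[sample_cols].to_numpy(dtype=float)
    dosages = np.where(np.isnan(dosages), -1, dosages).astype(int)
    if not np.isin(dosages, [-1, 0, 1, 2]).all():
        raise FormatError("genotype dosages must be 0/1/2 or missing")
    return (
        df["snp_id"].tolist(),
        df["contig"].tolist(),
        df["pos0"].to_numpy(dtype=int),
        dosages,
    )


def read_expression_matrix(path: str | Path, stages_path: str | Path):
    """Read a gene x stage RPKM TSV plus its stage-metadata sidecar.

    The sidecar has columns stage, order, prenatal (0/1) and fixes the stage
    ordering and the prenatal/postnatal split explicitly.
    """
    expr = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(stages_path, sep="\t", dtype={"stage": str})
    required = {"stage", "order", "prenatal"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"stage metadata missing columns {sorted(missing)}")
    meta = meta.sort_values("order")
    unknown = set(meta["stage"]) - set(expr.columns)
    if unknown:
        raise FormatError(f"stages {sorted(unknown)} not in expression matrix")
    expr = expr[meta["stage"].tolist()]
    if (expr.to_numpy() < 0).any():
        raise FormatError("expression matrix has negative values")
    prenatal_mask = meta["prenatal"].astype(bool).to_numpy()
    return expr, prenatal_mask


def read_specificity_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "cell_type": str})
    required = {"gene", "cell_type", "specificity"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"specificity table missing columns {sorted(missing)}")
    bad = df[(df["specificity"] < 0) | (df["specificity"] > 1)]
    if len(bad):
        raise FormatError(f"{len(bad)} specificity values outside [0, 1]")
    return df
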