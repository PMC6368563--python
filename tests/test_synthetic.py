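import numpy as np
import pytest

from regvar import io as rio
from regvar import pwm as pwm_mod
from regvar import synthetic
from regvar.disruption import snps_in_summit_windows


class TestMakeGenome:
    def test_gc_concentrates_at_target(self):
        genome = synthetic.make_genome(length_bp=1_000_000, gc=0.5, seed=1)
        seq = next(iter(genome.values())).sequence
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.01

    def test_deterministic_per_seed(self, tmp_path):
        a = synthetic.make_genome(length_bp=20_000, seed=5)
        b = synthetic.make_genome(length_bp=20_000, seed=5)
        pa, pb = tmp_path / "a.fa", tmp_path / "b.fa"
        rio.write_fasta(a.values(), pa)
        rio.write_fasta(b.values(), pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_gc_one_boundary(self):
        genome = synthetic.make_genome(length_bp=10_000, gc=1.0, seed=0)
        assert set(next(iter(genome.values())).sequence) <= {"G", "C"}


@pytest.fixture(scope="module")
def planted():
    genome = synthetic.make_genome(length_bp=400_000, seed=2)
    pwms = synthetic.make_pwms(seed=2)
    return synthetic.plant_motifs_and_peaks(genome, pwms, n_sites_per_tf=10, seed=2), pwms


@pytest.fixture(scope="module")
def bundle():
    genome = synthetic.make_genome(length_bp=500_000, seed=4)
    pwms = synthetic.make_pwms(seed=4)
    genome, peaks, truth = synthetic.plant_motifs_and_peaks(
        genome, pwms, n_sites_per_tf=10, seed=4
    )
    snvs, truth = synthetic.plant_snps(
        truth, genome, pwms, n_disrupting=50, n_benign_in_peak=75,
        n_outside_peak=75, seed=4,
    )
    return genome, pwms, peaks, snvs, truth


class TestPlantMotifsAndPeaks:
    def test_counts(self, planted):
        (genome, peaks, truth), pwms = planted
        assert len(peaks) == 30
        assert len(truth.planted_motif_sites) == 30

    def test_consensus_written_at_sites(self, planted):
        (genome, peaks, truth), pwms = planted
        by_name = {p.name: p for p in pwms}
        for tf, contig, start, strand in truth.planted_motif_sites:
            expected = by_name[tf].consensus()
            if strand == "-":
                expected = pwm_mod.reverse_complement(expected)
            assert genome[contig].sequence[start : start + len(expected)] == expected

    def test_scanning_recovers_planted_sites(self, planted):
        (genome, peaks, truth), pwms = planted
        recovered = 0
        for p in pwms:
            lom = pwm_mod.build_log_odds(p)
            dist = pwm_mod.exact_pvalue_table(lom)
            starts = {
                (c, s)
                for tf, c, s, _ in truth.planted_motif_sites
                if tf == p.name
            }
            for contig, start in starts:
                window = genome[contig].sequence[start : start + p.width]
                matches = pwm_mod.scan_sequence(lom, dist, window, alpha=1e-3)
                recovered += bool(matches)
        assert recovered >= 0.95 * len(truth.planted_motif_sites)

    def test_zero_jitter_summit_on_centre(self):
        genome = synthetic.make_genome(length_bp=200_000, seed=3)
        pwms = synthetic.make_pwms(tf_names=("TFX",), seed=3)
        _, peaks, truth = synthetic.plant_motifs_and_peaks(
            genome, pwms, n_sites_per_tf=5, summit_jitter_bp=0, seed=3
        )
        w = pwms[0].width
        centres = {start + w // 2 for _, _, start, _ in truth.planted_motif_sites}
        assert {p.summit for p in peaks} == centres


class TestPlantSnps:
    def test_class_sizes(self, bundle):
        _, _, _, snvs, truth = bundle
        assert len(truth.disrupting_snp_ids) == 50
        assert len(truth.benign_in_peak_snp_ids) == 75
        assert len(truth.outside_peak_snp_ids) == 75
        assert len(snvs) == 200

    def test_ref_alleles_match_genome(self, bundle):
        genome, _, _, snvs, _ = bundle
        for s in snvs:
            assert genome[s.contig].sequence[s.position] == s.ref_allele

    def test_outside_snps_never_pair(self, bundle):
        _, _, peaks, snvs, truth = bundle
        outside = [s for s in snvs if s.snp_id in truth.outside_peak_snp_ids]
        assert snps_in_summit_windows(outside, peaks, flank=50) == []

    def test_disrupting_snps_sit_inside_planted_motifs(self, bundle):
        _, pwms, _, snvs, truth = bundle
        widths = {p.name: p.width for p in pwms}
        spans = [
            (c, start, start + widths[tf])
            for tf, c, start, _ in truth.planted_motif_sites
        ]
        for s in snvs:
            if s.snp_id not in truth.disrupting_snp_ids:
                continue
            assert any(c == s.contig and a <= s.position < b for c, a, b in spans)

    def test_mafs_in_range(self, bundle):
        _, _, _, snvs, _ = bundle
        assert all(0.05 <= s.maf <= 0.5 for s in snvs)


class TestTabularGenerators:
    def test_annotation_ratings_respect_grammar(self):
        from regvar.prioritize import parse_rating

        table, _ = synthetic.make_annotation_scores(n_loci=20, seed=6)
        for rating in table["regulomedb"]:
            parse_rating(rating)  # must not raise

    def test_zero_fraction_plants_nothing(self):
        _, planted = synthetic.make_annotation_scores(
            n_loci=20, planted_consensus_fraction=0.0, seed=7
        )
        assert planted == {}

    def test_ase_imbalance_power(self):
        from regvar.eqtl_ase import binomial_ase
        from regvar.io import SNVRecord

        truth = synthetic.SyntheticTruth(
            seed=0, disrupting_snp_ids={f"d{i}" for i in range(100)}
        )
        snvs = [
            SNVRecord(f"d{i}", "chr1", 1000 + 10 * i, "A", "G", maf=0.3)
            for i in range(100)
        ]
        _, ase, _, _, truth = synthetic.make_eqtl_ase_expression(
            truth, snvs, ase_imbalance_ratio=0.9, ase_imbalanced_fraction=0.3, seed=8
        )
        flagged = {
            r.snp_id
            for r in ase.itertuples()
            if binomial_ase(r.ref_count, r.alt_count) < 0.001
        }
        imbalanced = truth.imbalanced_ase_snp_ids
        assert len(flagged & imbalanced) / len(imbalanced) >= 0.8

    def test_eqtl_rates_differ_by_class(self):
        from regvar.io import SNVRecord

        truth = synthetic.SyntheticTruth(
            seed=0, disrupting_snp_ids={f"d{i}" for i in range(200)}
        )
        snvs = [
            SNVRecord(f"d{i}", "chr1", 1000 + 10 * i, "A", "G", maf=0.3)
            for i in range(200)
        ] + [
            SNVRecord(f"b{i}", "chr1", 50_000 + 10 * i, "A", "G", maf=0.3)
            for i in range(200)
        ]
        eqtl, _, _, _, truth = synthetic.make_eqtl_ase_expression(
            truth, snvs, enriched_eqtl_rate=0.6, background_eqtl_rate=0.3, seed=9
        )
        cmc = eqtl[eqtl["dataset"] == "CMC"]
        rate_d = (cmc[cmc["snp_id"].str.startswith("d")]["fdr"] < 0.05).mean()
        rate_b = (cmc[cmc["snp_id"].str.startswith("b")]["fdr"] < 0.05).mean()
        assert rate_d > rate_b + 0.15

    def test_pool_determinism(self):
        a = synthetic.make_snp_pool(n_pool=500, seed=10)
        b = synthetic.make_snp_pool(n_pool=500, seed=10)
        assert a.equals(b)


class TestFixtureRoundTrip:
    def test_all_files_readable_through_io(self, fixture_dir):
        genome = rio.read_fasta(fixture_dir / "genome.fa")
        motifs = rio.read_meme_motifs(fixture_dir / "motifs.meme")
        peaks = rio.read_narrowpeak(fixture_dir / "peaks.narrowPeak")
        snvs = rio.read_snvs(fixture_dir / "snps.vcf")
        assert genome and motifs and peaks and snvs
        rio.read_annotation_scores(fixture_dir / "annotation_scores.tsv")
        rio.read_eqtl_table(fixture_dir / "eqtl.tsv")
        rio.read_ase_table(fixture_dir / "ase.tsv")
        rio.read_snp_pool(fixture_dir / "snp_pool.tsv")
        rio.read_genotypes(fixture_dir / "genotypes.tsv")
        rio.read_expression_matrix(
            fixture_dir / "expression.tsv", fixture_dir / "stages.tsv"
        )
        rio.read_specificity_table(fixture_dir / "specificity.tsv")
        rio.read_gene_model(fixture_dir / "gene_model.tsv")

    def test_vcf_and_tsv_dialects_agree(self, fixture_dir):
        vcf = rio.read_snvs(fixture_dir / "snps.vcf")
        tsv = rio.read_snvs(fixture_dir / "snps.tsv", dialect="tsv")
        assert {(s.snp_id, s.contig, s.position, s.ref_allele, s.alt_allele) for s in vcf} == {
            (s.snp_id, s.contig, s.position, s.ref_allele, s.alt_allele) for s in tsv
        }

    def test_fixture_bit_reproducible(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        synthetic.generate_fixture(a, seed=99, length_bp=120_000, n_sites_per_tf=3,
                                   n_disrupting=6, n_benign_in_peak=6, n_outside_peak=6,
                                   n_loci=10)
        synthetic.generate_fixture(b, seed=99, length_bp=120_000, n_sites_per_tf=3,
                                   n_disrupting=6, n_benign_in_peak=6, n_outside_peak=6,
                                   n_loci=10)
        for f in sorted(p.name for p in a.iterdir()):
            assert (a / f).read_bytes() == (b / f).read_bytes(), f
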