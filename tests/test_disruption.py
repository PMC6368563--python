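import numpy as np
import pytest

from regvar import disruption as ddm
from regvar import pwm
from regvar.errors import ReferenceMismatchError
from regvar.io import GeneModelInterval, GenomeSequence, PeakRecord, SNVRecord


def make_peak(contig="chr1", summit=1000, tf="TF1", half=150):
    return PeakRecord(
        contig=contig,
        start=summit - half,
        end=summit + half,
        summit_offset=half,
        neg_log10_q=3.0,
        tf_name=tf,
        peak_id=f"{tf}:{summit}",
    )


def snv(snp_id, pos, contig="chr1", ref="A", alt="G"):
    return SNVRecord(snp_id, contig, pos, ref, alt)


class TestSummitPairing:
    def test_flank_boundary_inclusive_exclusive(self):
        peak = make_peak(summit=1000)
        inside = snv("in", 1050)
        outside = snv("out", 1051)
        pairs = ddm.snps_in_summit_windows([inside, outside], [peak], flank=50)
        assert [(s.snp_id, p.summit) for s, p in pairs] == [("in", 1000)]

    def test_contig_mismatch_never_pairs(self):
        pairs = ddm.snps_in_summit_windows(
            [snv("s", 1000, contig="chr2")], [make_peak(summit=1000)], flank=50
        )
        assert pairs == []

    def test_snp_can_pair_with_multiple_tf_peaks(self):
        peaks = [make_peak(summit=1000, tf="TF1"), make_peak(summit=1020, tf="TF2")]
        pairs = ddm.snps_in_summit_windows([snv("s", 1010)], peaks, flank=50)
        assert {p.tf_name for _, p in pairs} == {"TF1", "TF2"}


class TestAlleleContext:
    @pytest.fixture
    def genome(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        seq = seq[:100] + "A" + seq[101:]
        return {"chr1": GenomeSequence("chr1", seq)}

    def test_context_lengths_and_centre(self, genome):
        ref_seq, alt_seq = ddm.allele_context(genome, snv("s", 100), flank=20)
        assert len(ref_seq) == len(alt_seq) == 41
        assert ref_seq[20] == "A" and alt_seq[20] == "G"
        assert ref_seq[:20] == alt_seq[:20] and ref_seq[21:] == alt_seq[21:]

    def test_reference_mismatch_raises(self, genome):
        with pytest.raises(ReferenceMismatchError):
            ddm.allele_context(genome, snv("s", 100, ref="C", alt="G"), flank=20)

    def test_zero_flank_degenerates_to_alleles(self, genome):
        ref_seq, alt_seq = ddm.allele_context(genome, snv("s", 100), flank=0)
        assert (ref_seq, alt_seq) == ("A", "G")


class TestCallDisruption:
    def setup_method(self):
        rng = np.random.default_rng(1)
        probs = np.full((8, 4), 0.03)
        probs[np.arange(8), rng.integers(0, 4, 8)] = 0.91
        self.pwm = pwm.PWM.from_rows("T", probs)
        self.lom = pwm.build_log_odds(self.pwm)
        self.dist = pwm.exact_pvalue_table(self.lom)
        self.flanks = "".join(rng.choice(list("ACGT"), size=40))

    def test_planted_consensus_with_worst_alt(self):
        consensus = self.pwm.consensus()
        snp_col = 4
        ref_base = consensus[snp_col]
        worst = pwm.ALPHABET[int(self.pwm.probs[snp_col].argmin())]
        left = self.flanks[: 20 - snp_col] + consensus[:snp_col]
        right = consensus[snp_col + 1 :] + self.flanks[20:]
        ref_seq = left + ref_base + right
        alt_seq = left + worst + right
        ref_res, alt_res, disrupts, delta = ddm.call_disruption(
            self.lom, self.dist, ref_seq, alt_seq, snp_index=20, alpha=1e-3
        )
        assert ref_res.best_pvalue < 1e-3
        assert disrupts
        assert delta > 0

    def test_uniform_pwm_never_disrupts(self):
        lom = pwm.build_log_odds(pwm.PWM.from_rows("u", np.full((6, 4), 0.25)))
        dist = pwm.exact_pvalue_table(lom)
        seq = "ACGTACGTACGTACGTACGTA"
        ref_res, alt_res, disrupts, delta = ddm.call_disruption(
            lom, dist, seq, seq[:10] + "G" + seq[11:], snp_index=10
        )
        assert ref_res.best_pvalue == 1.0 and alt_res.best_pvalue == 1.0
        assert not disrupts

    def test_verdict_symmetric_under_allele_swap(self):
        consensus = self.pwm.consensus()
        ref_seq = self.flanks[:16] + consensus + self.flanks[24:]
        alt_seq = ref_seq[:20] + "T" + ref_seq[21:]
        if alt_seq == ref_seq:
            alt_seq = ref_seq[:20] + "C" + ref_seq[21:]
        a = ddm.call_disruption(self.lom, self.dist, ref_seq, alt_seq, 20)
        b = ddm.call_disruption(self.lom, self.dist, alt_seq, ref_seq, 20)
        assert a[2] == b[2]  # disrupts
        assert a[3] == pytest.approx(-b[3])  # delta flips sign

    def test_equal_alleles_scoring_gives_zero_delta(self):
        # identical contexts: delta must be exactly zero
        seq = self.flanks[:16] + self.pwm.consensus() + self.flanks[24:]
        _, _, _, delta = ddm.call_disruption(self.lom, self.dist, seq, seq, 20)
        assert delta == 0.0

    def test_window_count_bounded_by_two_w(self):
        seq = "ACGT" * 11
        ref_res, _, _, _ = ddm.call_disruption(
            self.lom, self.dist, seq, seq, snp_index=20
        )
        assert ref_res.n_windows_scored <= 2 * self.lom.width


class TestScreenOnFixture:
    def test_planted_recovery_and_peak_gate(self, fixture_run, fixture_truth):
        called = {c.snp_id for c in fixture_run.calls if c.disrupts}
        truth = fixture_truth
        sensitivity = len(called & truth.disrupting_snp_ids) / len(
            truth.disrupting_snp_ids
        )
        assert sensitivity >= 0.90
        assert not called & truth.outside_peak_snp_ids

    def test_every_disrupting_snp_is_inside_a_summit_window(
        self, fixture_run, fixture_truth
    ):
        # filter soundness: only SNPs paired to a summit window can be called
        gated = (
            fixture_truth.disrupting_snp_ids | fixture_truth.benign_in_peak_snp_ids
        )
        called = {c.snp_id for c in fixture_run.calls if c.disrupts}
        assert called <= gated

    def test_empty_snp_list_gives_empty_output(self, fixture_dir):
        from regvar import io as rio

        genome = rio.read_fasta(fixture_dir / "genome.fa")
        peaks = rio.read_narrowpeak(fixture_dir / "peaks.narrowPeak")
        motifs = rio.read_meme_motifs(fixture_dir / "motifs.meme")
        assert ddm.run_disruption_screen(genome, [], peaks, motifs) == []


class TestSummaries:
    def _call(self, snp, tf, disrupts=True):
        res = ddm.AlleleScanResult(
            allele="A", best_score=1.0, best_pvalue=1e-4 if disrupts else 0.5,
            best_window_start=0, best_strand="+", n_windows_scored=1,
        )
        return ddm.DisruptionCall(
            snp_id=snp, tf_name=tf, motif=tf, ref_result=res, alt_result=res,
            disrupts=disrupts, delta_llr=0.0, peak_id="p",
        )

    def test_counts_and_pairwise_overlap(self):
        calls = [
            self._call("s1", "TF1"),
            self._call("s2", "TF1"),
            self._call("s3", "TF1"),
            self._call("s3", "TF2"),
            self._call("s4", "TF2", disrupts=False),
        ]
        per_tf, pairs = ddm.summarize_by_tf(calls)
        assert dict(zip(per_tf["tf_name"], per_tf["n_disrupting_snps"])) == {
            "TF1": 3,
            "TF2": 1,
        }
        assert pairs.iloc[0].tolist() == ["TF1", "TF2", 1]

    def test_duplicates_counted_once(self):
        calls = [self._call("s1", "TF1"), self._call("s1", "TF1")]
        per_tf, _ = ddm.summarize_by_tf(calls)
        assert per_tf["n_disrupting_snps"].tolist() == [1]

    def test_no_disrupting_calls_empty_table(self):
        per_tf, pairs = ddm.summarize_by_tf([self._call("s", "TF1", disrupts=False)])
        assert per_tf.empty and pairs.empty


class TestGenomicContext:
    @pytest.fixture
    def model(self):
        return [
            GeneModelInterval("chr1", 1000, 5000, "gene", "+", "g1"),
            GeneModelInterval("chr1", 1200, 1400, "exon", "+", "g1"),
            GeneModelInterval("chr1", 1100, 1200, "utr", "+", "g1"),
        ]

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (1300, "exonic"),
            (1150, "UTR"),
            (2000, "intronic"),
            (500, "upstream"),
            (5500, "downstream"),
            (50_000, "intergenic"),
        ],
    )
    def test_precedence(self, model, pos, expected):
        out = ddm.genomic_context([snv("s", pos)], model)
        assert out["category"].tolist() == [expected]

    def test_minus_strand_orientation(self):
        model = [GeneModelInterval("chr1", 1000, 5000, "gene", "-", "g1")]
        out = ddm.genomic_context([snv("u", 5200), snv("d", 800)], model)
        assert out["category"].tolist() == ["upstream", "downstream"]

    def test_fractions_sum_to_one(self, model):
        snps = [snv(f"s{i}", p) for i, p in enumerate([1300, 2000, 9000])]
        frac = ddm.context_fractions(ddm.genomic_context(snps, model))
        assert frac["fraction"].sum() == pytest.approx(1.0)
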