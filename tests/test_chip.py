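"""Peak annotation, binding enrichment and PWM relatedness scanning."""

import numpy as np
import pytest

from sigscreen import (
    PWM,
    Peak,
    PeakSet,
    annotate_peaks_to_genes,
    binding_enrichment,
    pwm_relatedness,
    read_bed,
    read_pwm,
    scan_ares,
)
from sigscreen.chip import TssRecord, TssTable, read_tss_table


def brute_force_annotation(peaks, tss, window):
    out = {}
    for rec in tss:
        for p in peaks:
            # 1-based inclusive window vs the bases a half-open peak covers
            peak_first, peak_last = p.start + 1, p.end
            if p.chrom == rec.chrom and peak_first <= rec.tss_position + window \
                    and peak_last >= rec.tss_position - window:
                out.setdefault(rec.gene_id, []).append(p)
    return out


class TestAnnotatePeaks:
    def tss(self, pos=50_000, gene="GENE1"):
        return TssTable([TssRecord(gene, "chr1", pos)])

    def test_peak_five_kb_upstream_associated(self):
        peaks = PeakSet([Peak("chr1", 44_900, 45_100)])
        assert "GENE1" in annotate_peaks_to_genes(peaks, self.tss())

    def test_peak_fifteen_kb_away_not_associated(self):
        peaks = PeakSet([Peak("chr1", 64_900, 65_100)])
        assert annotate_peaks_to_genes(peaks, self.tss()) == {}

    def test_boundary_exactly_at_window_edge_is_inclusive(self):
        # peak's first covered base (1-based start+1) == tss + 10,000
        peaks = PeakSet([Peak("chr1", 59_999, 60_200)])
        assert "GENE1" in annotate_peaks_to_genes(peaks, self.tss())
        # one base further: excluded
        peaks = PeakSet([Peak("chr1", 60_000, 60_200)])
        assert annotate_peaks_to_genes(peaks, self.tss()) == {}

    def test_agrees_with_quadratic_brute_force(self):
        rng = np.random.default_rng(23)
        peaks = PeakSet(
            [Peak(f"chr{rng.integers(1, 3)}", int(s), int(s) + int(rng.integers(50, 500)))
             for s in rng.integers(0, 200_000, 60)]
        )
        tss = TssTable(
            [TssRecord(f"G{i}", f"chr{rng.integers(1, 3)}", int(rng.integers(1, 200_000)))
             for i in range(40)]
        )
        fast = annotate_peaks_to_genes(peaks, tss)
        slow = brute_force_annotation(peaks, tss, 10_000)
        assert {g: sorted((p.start, p.end) for p in v) for g, v in fast.items()} == {
            g: sorted((p.start, p.end) for p in v) for g, v in slow.items()
        }

    def test_chromosome_mismatch_warns(self, caplog):
        peaks = PeakSet([Peak("1", 100, 200)])
        with caplog.at_level("WARNING"):
            annotate_peaks_to_genes(peaks, self.tss())
        assert any("mismatch" in rec.message for rec in caplog.records)


class TestBindingEnrichment:
    def test_reported_fractions_and_significance(self):
        bm = {f"b{i}" for i in range(143)}
        bound = {f"b{i}" for i in range(38)} | {f"x{i}" for i in range(3553 - 38)}
        res = binding_enrichment(bm, bound, 26_000)
        assert round(100 * res["fraction_biomarker"], 1) == 26.6
        assert round(100 * res["fraction_background"], 1) == 13.7
        assert res["p_value"] < 0.05

    def test_background_rate_signature_not_enriched(self):
        bm = {f"b{i}" for i in range(100)}
        bound = {f"b{i}" for i in range(10)} | {f"x{i}" for i in range(90)}
        res = binding_enrichment(bm, bound, 1000)
        assert res["p_value"] > 0.3

    def test_universe_too_small_rejected(self):
        with pytest.raises(ValueError):
            binding_enrichment({"a"}, {"b", "c"}, 2)


@pytest.fixture()
def toy_pwm():
    # favors A, then C, third column indifferent
    return PWM([[2, 0, 1], [0, 2, 1], [0, 0, 1], [0, 0, 1]])


class TestPwmRelatedness:
    def test_consensus_scores_one(self, toy_pwm):
        r, off, strand = pwm_relatedness(toy_pwm.consensus(), toy_pwm)
        assert r == 1.0 and off == 0

    def test_anticonsensus_scores_zero(self):
        pwm = PWM([[2, 0], [0, 2], [1, 1], [1, 1]])
        # column minima: C (or G/T) then A
        assert pwm.relatedness("CA") == 0.0

    def test_brute_force_scan_over_short_sequence(self, toy_pwm):
        seq = "ACAGT"
        rc = "ACTGT"  # reverse complement of seq
        best = -1.0
        for s in (seq, rc):
            for off in range(len(s) - 2):
                best = max(best, toy_pwm.relatedness(s[off:off + 3]))
        r, _, _ = pwm_relatedness(seq, toy_pwm)
        assert r == pytest.approx(best)

    def test_strand_symmetry(self, toy_pwm):
        rng = np.random.default_rng(4)
        for _ in range(10):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
            rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            assert pwm_relatedness(seq, toy_pwm)[0] == pytest.approx(
                pwm_relatedness(rc, toy_pwm)[0]
            )

    def test_n_scores_as_column_minimum(self, toy_pwm):
        assert toy_pwm.score("NCA") == pytest.approx(0 + 2 + 1)

    def test_sequence_shorter_than_motif_rejected(self, toy_pwm):
        with pytest.raises(ValueError):
            pwm_relatedness("AC", toy_pwm)


class TestScanAres:
    def pwm(self):
        counts = np.ones((4, 8))
        for j, b in enumerate("TGACTCAG"):
            counts["ACGT".index(b), j] = 97
        return PWM.from_counts(counts)

    def passing_kmer_count(self, pwm, threshold=0.8):
        """Exhaustive enumeration of k-mers reaching the threshold (L = 8)."""
        L = len(pwm)
        bases = np.asarray(list("ACGT"))
        idx = np.indices((4,) * L).reshape(L, -1)
        scores = sum(pwm.matrix[idx[j], j] for j in range(L))
        rel = (scores - pwm.min_score) / (pwm.max_score - pwm.min_score)
        passing = ["".join(bases[idx[:, i]]) for i in np.flatnonzero(rel >= threshold)]
        return set(passing)

    def test_planted_consensus_found_at_offset(self):
        pwm = self.pwm()
        rng = np.random.default_rng(9)
        passing = self.passing_kmer_count(pwm)
        seq = self.motif_free_sequence(rng, 200, passing)
        seq = seq[:73] + "TGACTCAG" + seq[81:]
        genome = {"chr1": seq}
        hits = scan_ares(PeakSet([Peak("chr1", 0, 200)]), genome, pwm)
        (peak_hits,) = hits.values()
        assert [(h.offset, h.strand) for h in peak_hits if h.relatedness == 1.0] == [(73, "+")]

    def test_reverse_complement_plant_reported_on_minus_strand(self):
        pwm = self.pwm()
        rng = np.random.default_rng(10)
        passing = self.passing_kmer_count(pwm)
        seq = self.motif_free_sequence(rng, 120, passing)
        rc_motif = "TGACTCAG".translate(str.maketrans("ACGT", "TGCA"))[::-1]
        seq = seq[:40] + rc_motif + seq[48:]
        hits = scan_ares(PeakSet([Peak("chr1", 0, 120)]), {"chr1": seq}, pwm)
        (peak_hits,) = hits.values()
        top = [h for h in peak_hits if h.relatedness == 1.0]
        assert [(h.offset, h.strand) for h in top] == [(40, "-")]

    def motif_free_sequence(self, rng, length, passing):
        rc = str.maketrans("ACGT", "TGCA")
        while True:
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
            rcseq = seq.translate(rc)[::-1]
            if not any(seq[i:i + 8] in passing or rcseq[i:i + 8] in passing
                       for i in range(length - 7)):
                return seq

    def test_motif_free_sequence_yields_no_hits(self):
        pwm = self.pwm()
        rng = np.random.default_rng(11)
        passing = self.passing_kmer_count(pwm)
        seq = self.motif_free_sequence(rng, 300, passing)
        assert scan_ares(PeakSet([Peak("chr1", 0, 300)]), {"chr1": seq}, pwm) == {}

    def test_peak_outside_genome_skipped(self, caplog):
        pwm = self.pwm()
        with caplog.at_level("WARNING"):
            hits = scan_ares(
                PeakSet([Peak("chr1", 500, 700)]), {"chr1": "ACGT" * 20}, pwm
            )
        assert hits == {}


def test_bed_and_tss_readers(tmp_path):
    (tmp_path / "p.bed").write_text("chr1\t100\t200\npeak\t50\nchr1\t400\t450\n")
    # malformed mixed row counts are not the point here; write a clean file
    (tmp_path / "p.bed").write_text("chr1\t100\t200\nchr2\t400\t450\n")
    ps = read_bed(tmp_path / "p.bed")
    assert [(p.chrom, p.start, p.end) for p in ps] == [("chr1", 100, 200), ("chr2", 400, 450)]

    (tmp_path / "t.tsv").write_text(
        "gene_id\tchrom\ttss_position\tstrand\nnqo1\tchr1\t150\t+\n"
    )
    tt = read_tss_table(tmp_path / "t.tsv")
    assert tt.records[0].gene_id == "NQO1"


def test_pwm_reader_counts_and_weights(tmp_path):
    (tmp_path / "m.txt").write_text("A 10 0\nC 0 10\nG 0 0\nT 0 0\n")
    pwm = read_pwm(tmp_path / "m.txt", as_counts=True)
    assert pwm.consensus() == "AC"
    (tmp_path / "w.txt").write_text("1 0\n0 1\n0 0\n0 0\n")
    pwm2 = read_pwm(tmp_path / "w.txt")
    assert pwm2.max_score == 2.0 and pwm2.min_score == 0.0
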