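"""Read QC, pair merging, fit alignment and editing-rate pileup."""

import numpy as np
import pytest

from hairpinsense.editquant import (
    Alignment,
    ReadRecord,
    align_to_amplicon,
    editing_rates,
    merge_pairs,
    quality_filter,
    read_fastq,
    run_pipeline,
    revcomp_read,
    write_fastq,
)
from hairpinsense.errors import InputError
from hairpinsense.seqcore import NucSeq


def _read(bases, quals=None, rid="r", mate="single"):
    if quals is None:
        quals = (40,) * len(bases)
    elif isinstance(quals, int):
        quals = (quals,) * len(bases)
    return ReadRecord(rid, bases, tuple(quals), mate)


class TestQualityFilter:
    def test_low_quality_ends_trimmed(self):
        rec = _read("ACGTACGT", (15, 15, 30, 30, 30, 30, 15, 15))
        kept, stats = quality_filter([rec])
        assert kept[0].bases == "GTAC"
        assert stats.bases_trimmed == 4

    def test_n_rich_read_discarded(self):
        rec = _read("ACGTN" * 4, 40)  # 4/20 N = 20% > 10%
        kept, stats = quality_filter([rec])
        assert not kept and stats.discarded == 1

    def test_clean_read_untouched(self):
        rec = _read("ACGT" * 5, 40)
        kept, stats = quality_filter([rec])
        assert kept == [rec] and stats.bases_trimmed == 0

    def test_fully_low_quality_read_dropped(self):
        kept, stats = quality_filter([_read("ACGT", 5)])
        assert not kept and stats.discarded == 1


class TestMergePairs:
    def test_constructed_eight_base_overlap(self):
        r1 = _read("ACGTACGTAC", 40, "p", "1")
        # R2 reads the reverse strand; its revcomp is r1[2:] plus 2 new bases
        rc2 = "GTACGTACGT"
        r2 = revcomp_read(_read(rc2, 40, "p", "2"))
        result = merge_pairs(r1, r2, min_overlap=6)
        assert result.ok and result.overlap == 8
        assert len(result.merged) == 12
        assert result.merged.bases == "ACGTACGTACGT"

    def test_disjoint_reads_unmerged(self):
        r1 = _read("AAAACCCC", 40, "p", "1")
        r2 = revcomp_read(_read("GGGGTTTT", 40, "p", "2"))
        assert not merge_pairs(r1, r2, min_overlap=4).ok

    def test_disagreement_resolved_by_quality(self):
        r1 = _read("AAAACCCCGGGGCCCC", (40,) * 15 + (10,), "p", "1")
        rc2 = "CCCCGGGGCCCG" + "TTTT"  # 12-base overlap, one disagreement
        r2 = revcomp_read(_read(rc2, 40, "p", "2"))
        result = merge_pairs(r1, r2, min_overlap=6)
        assert result.ok and result.overlap == 12
        assert result.identity == pytest.approx(11 / 12)
        # the Q40 R2 call beats the Q10 R1 call at the disagreement
        assert result.merged.bases == "AAAACCCCGGGGCCCG" + "TTTT"


class TestAlignment:
    REF = NucSeq.dna(
        "GATTACAGATTACAGGGTTTCCCAAATTTGGGCCCTTTAAACCCGGGTTTACGTACGTACGT"
        "TGCATGCATGCATGCAGGCCTTGGCCAATTCCGGAATTCCGGTTAACCGGTTAACC"
    )

    def test_exact_substring(self):
        read = _read(self.REF.residues[40:80])
        aln = align_to_amplicon(read, self.REF)
        assert aln.offset == 40 and aln.end == 80 and aln.strand == "+"
        assert aln.score == 80.0

    def test_reverse_strand_symmetry(self):
        read = _read(self.REF.residues[40:80])
        aln = align_to_amplicon(revcomp_read(read), self.REF)
        assert aln.offset == 40 and aln.strand == "-"

    def test_mismatch_scoring(self):
        bases = list(self.REF.residues[40:80])
        bases[10] = "A" if bases[10] != "A" else "C"
        aln = align_to_amplicon(_read("".join(bases)), self.REF)
        assert aln.offset == 40
        assert aln.score == 2 * 39 - 3

    def test_two_candidate_loci_better_score_wins(self):
        # duplicated locus; the second copy carries a mismatch vs the read
        ref = NucSeq.dna("TTTT" + "ACGTACGTGGCCAAGG" + "TTTT" + "ACGTACGTGGCCAAGC" + "TTTT")
        aln = align_to_amplicon(_read("ACGTACGTGGCCAAGG"), ref, min_score=10)
        assert aln.offset == 4 and aln.score == 32.0

    def test_low_score_unaligned(self):
        assert align_to_amplicon(_read("TTTTTTTTTTTT"), NucSeq.dna("ACGCACGC" * 10)) is None


class TestEditingRates:
    def _aln(self, bases, offset, rid="r"):
        n = len(bases)
        return Alignment(rid, offset, offset + n, "+", 2.0 * n,
                         (((offset, offset + n), (0, n)),), bases)

    def test_central_rate_arithmetic(self):
        ref = NucSeq.dna("CCAGG")
        alns = [self._aln("CCAGG", 0, f"a{i}") for i in range(40)]
        alns += [self._aln("CCGGG", 0, f"g{i}") for i in range(60)]
        report = editing_rates(alns, ref, central_site=2)
        assert report.central_pct == pytest.approx(60.0)
        assert report.status == "ok"

    def test_no_g_no_bystanders(self):
        ref = NucSeq.dna("AACCAAGG")
        alns = [self._aln("AACCAAGG", 0, f"r{i}") for i in range(80)]
        report = editing_rates(alns, ref, central_site=0)
        assert report.central_pct == 0.0
        assert report.bystanders == []
        assert (report.edit_pct.dropna() == 0).all()

    def test_counts_sum_to_coverage(self):
        ref = NucSeq.dna("ACGTACGTAC")
        alns = [self._aln("ACGTAC", 0), self._aln("GTACGT", 2), self._aln("ACGTAC", 4)]
        report = editing_rates(alns, ref, central_site=4)
        totals = report.counts.sum(axis=1)
        expected = [1, 1, 2, 2, 3, 3, 2, 2, 1, 1]
        assert list(totals) == expected

    def test_insufficient_depth_status(self):
        ref = NucSeq.dna("CCAGG")
        report = editing_rates([self._aln("CCAGG", 0)], ref, central_site=2)
        assert report.status == "insufficient_depth" and report.central_pct is None

    def test_no_coverage_is_an_error(self):
        ref = NucSeq.dna("CCAGGTTTT")
        with pytest.raises(InputError):
            editing_rates([self._aln("CCA", 0)], ref, central_site=7)


class TestPipelineCalibration:
    def test_single_seed_three_sigma_recovery(self):
        # truth-table oracle: the pipeline estimate must sit on the realised
        # fraction, itself within 3 binomial sigma of the programmed 0.6
        from hairpinsense.simdata import ReadSimConfig, simulate_reads

        bases = list(np.random.default_rng(2).choice(list("ACGT"), size=240))
        site = 118
        bases[site] = "A"
        bases[40] = "A"
        ref = NucSeq.dna("".join(bases))
        cfg = ReadSimConfig(seed=11, depth=600, read_length=150,
                            edit_sites={site: 0.6, 40: 0.01}, error_rate=0.001)
        reads, truth = simulate_reads(ref, cfg)
        report, stats = run_pipeline(reads, ref, site)
        frac = truth["edit_sites"][site]["fraction"]
        sigma = np.sqrt(0.6 * 0.4 / 600)
        assert abs(frac - 0.6) <= 3 * sigma
        assert report.central_pct == pytest.approx(100 * frac, abs=1.0)
        # the low-rate bystander stays under the 2% flag threshold
        assert 40 not in [p for p, _ in report.bystanders]

    def test_pipeline_is_deterministic(self):
        from hairpinsense.simdata import ReadSimConfig, simulate_reads

        ref = NucSeq.dna("ACGT" * 50 + "A" + "TGCA" * 20)
        cfg = ReadSimConfig(seed=5, depth=120, read_length=100, edit_sites={200: 0.5})
        reads, _ = simulate_reads(ref, cfg)
        r1, _ = run_pipeline(reads, ref, 200)
        r2, _ = run_pipeline(reads, ref, 200)
        assert r1.counts.equals(r2.counts)
        assert r1.central_pct == r2.central_pct


class TestFastqRoundtrip:
    def test_roundtrip(self, tmp_path):
        recs = [_read("ACGTN", (2, 40, 60, 0, 33), rid="q1")]
        path = tmp_path / "x.fastq"
        write_fastq(path, recs)
        back = read_fastq(path)
        assert back[0].bases == "ACGTN" and back[0].quals == (2, 40, 60, 0, 33)
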