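"""Read-level panel detection, cutoff summaries and FASTQ subsampling."""

import gzip

import numpy as np
import pytest

import oracles
from conftest import klist_from_strings, random_dna
from taxmer import (
    DetectionConfig,
    DetectionReport,
    KmerError,
    count_in_reads,
    detected_at_cutoffs,
    generate_panel,
    simulate_reads,
    subsample_every_nth,
)
from taxmer.detect import count_fastq_reads, write_report
from taxmer.kmers import count_seqs, decode
from taxmer.simulate import PanelParams


def make_report(counts):
    return DetectionReport(
        k=4,
        panel_codes=np.arange(len(counts), dtype=np.uint64),
        counts=np.array(counts, np.int64),
        n_reads=0,
    )


class TestCountInReads:
    def test_both_strands_counted(self, write_fastq):
        kmer = "ACCGTAGC"  # canonical (revcomp GCTACGGT)
        panel = klist_from_strings({kmer: 1}, 8)
        fq = write_fastq(["TT" + kmer + "AA", oracles.revcomp(kmer) + "CCC"])
        report = count_in_reads(panel, fq)
        assert report.counts.tolist() == [2]
        assert report.n_reads == 2

    def test_repeat_within_one_read_counts_per_window(self, write_fastq):
        kmer = "ACCGTAGC"
        panel = klist_from_strings({kmer: 1}, 8)
        fq = write_fastq([kmer + kmer])
        assert count_in_reads(panel, fq).counts.tolist() == [2]

    def test_disjoint_reads_give_all_zero(self, write_fastq, rng):
        panel = klist_from_strings({"ACCGTAGC": 1, "AAAACCCC": 1}, 8)
        fq = write_fastq(["GTGTGTGTGTGT", "TGTGTGTGTG"])
        report = count_in_reads(panel, fq)
        assert report.counts.tolist() == [0, 0]
        assert all(v == 0 for v in detected_at_cutoffs(report).values())

    def test_short_reads_and_ambiguity_skipped(self, write_fastq):
        panel = klist_from_strings({"ACCGTAGC": 1}, 8)
        fq = write_fastq(["ACCGT", "ACCGNAGC"])
        assert count_in_reads(panel, fq).counts.tolist() == [0]

    def test_matches_naive_scan_oracle(self, rng, write_fastq):
        genome = random_dna(rng, 800)
        k = 8
        reads = [
            genome[s : s + 60]
            for s in rng.integers(0, len(genome) - 60, size=500)
        ]
        reads = [
            r if rng.integers(0, 2) else oracles.revcomp(r) for r in reads
        ]
        panel_strings = sorted(oracles.count_kmers([genome[:100]], k))[:40]
        panel = klist_from_strings({s: 1 for s in panel_strings}, k)
        fq = write_fastq(reads)
        report = count_in_reads(panel, fq)
        expected = oracles.count_kmers(reads, k)
        got = {
            decode(int(c), k): int(n)
            for c, n in zip(report.panel_codes, report.counts)
        }
        assert got == {s: expected.get(s, 0) for s in panel_strings}

    def test_empty_panel_rejected(self, write_fastq):
        from taxmer import KmerList

        with pytest.raises(KmerError, match="empty"):
            count_in_reads(KmerList.empty(8), write_fastq(["ACGT"]))


class TestCutoffs:
    def test_tally_example(self):
        report = make_report([5, 1, 0, 10])
        cfg = DetectionConfig((1, 2, 5, 10))
        assert detected_at_cutoffs(report, cfg) == {1: 3, 2: 2, 5: 2, 10: 1}

    def test_extremes(self):
        report = make_report([3, 7, 2])
        assert report.detected(1) == 3  # all positive: the panel size
        assert report.detected(100) == 0

    def test_monotone_in_cutoff(self, rng):
        counts = rng.integers(0, 50, size=200)
        report = make_report(counts.tolist())
        dets = [report.detected(f) for f in range(1, 60)]
        assert dets == sorted(dets, reverse=True)
        assert all(d <= 200 for d in dets)

    def test_bad_cutoff_ladders_rejected(self):
        for bad in [(), (0, 1), (2, 2), (5, 1)]:
            with pytest.raises(KmerError):
                DetectionConfig(bad)


class TestSimulatedDetection:
    PARAMS = PanelParams(
        seed=31, lsc_len=6000, ssc_len=1500, ir_len=1200,
        n_targets=3, n_nontargets=3, n_private_variants=4,
        target_intra_divergence=0.0, nontarget_divergence=8e-3,
        read_length=100, n_reads=4000,
    )

    def test_saturation_on_error_free_target_reads(self, tmp_path):
        # ~40x coverage of error-free target reads: every panel k-mer seen
        truth = generate_panel(self.PARAMS, m=2)
        panel = truth.oracle_panel
        fq = simulate_reads(
            truth.target_seqs[0],
            PanelParams(**{**self.PARAMS.__dict__, "error_rate": 0.0}),
            tmp_path / "target.fq", seed=41,
        )
        report = count_in_reads(panel, fq)
        assert report.detected(1) == len(panel)

    def test_cutoff_suppresses_nontarget_noise_more_than_signal(self, tmp_path):
        # error-bearing non-target reads produce spurious low-frequency
        # detections; raising the cutoff suppresses them proportionally more
        # than detections in target reads
        truth = generate_panel(self.PARAMS, m=2)
        panel = truth.oracle_panel
        deep = PanelParams(**{**self.PARAMS.__dict__,
                              "error_rate": 5e-3, "n_reads": 30_000})
        fq_t = simulate_reads(truth.target_seqs[0], deep, tmp_path / "t.fq", seed=43)
        fq_n = simulate_reads(truth.nontarget_seqs[0], deep, tmp_path / "n.fq", seed=44)
        rep_t = count_in_reads(panel, fq_t)
        rep_n = count_in_reads(panel, fq_n)
        assert rep_n.detected(1) > 0  # sequencing errors create false hits
        assert rep_n.detected(10) < rep_n.detected(1)
        drop_n = rep_n.detected(10) / rep_n.detected(1)
        drop_t = rep_t.detected(10) / rep_t.detected(1)
        assert drop_n < drop_t  # specificity gain exceeds sensitivity loss

    def test_report_tsv_layout(self, tmp_path, write_fastq):
        panel = klist_from_strings({"ACCGTAGC": 1}, 8)
        fq = write_fastq(["TT" + "ACCGTAGC" + "AA"])
        report = count_in_reads(panel, fq)
        out = tmp_path / "report.tsv"
        write_report(report, out)
        lines = out.read_text().splitlines()
        assert lines[0] == "#panel_size\t1"
        assert "cutoff\t1\t1" in lines
        assert lines[-1] == "ACCGTAGC\t1"


class TestSubsample:
    def test_identity_when_keeping_all(self, write_fastq, tmp_path):
        fq = write_fastq([f"ACGTACGT{'A' * i}" for i in range(6)])
        out = tmp_path / "all.fq"
        subsample_every_nth(fq, out, 6)
        assert out.read_bytes() == fq.read_bytes()

    def test_stride_indices(self, write_fastq, tmp_path):
        fq = write_fastq([random_dna(np.random.default_rng(i), 20) for i in range(10)])
        out = tmp_path / "sub.fq"
        subsample_every_nth(fq, out, 5)
        titles = [l for l in out.read_text().splitlines() if l.startswith("@r")]
        assert titles == ["@r0", "@r2", "@r4", "@r6", "@r8"]

    def test_nonexact_stride_truncates_to_n_out(self, write_fastq, tmp_path):
        fq = write_fastq(["ACGT"] * 10)
        out = tmp_path / "sub.fq"
        subsample_every_nth(fq, out, 3)  # stride 3 -> indices 0,3,6
        assert count_fastq_reads(out) == 3

    def test_records_copied_verbatim_and_deterministic(self, tmp_path):
        fq = tmp_path / "in.fq"
        fq.write_text(
            "@weird read id with spaces\nACGT\n+same on plus line\nIII!\n"
            "@r1\nGGGG\n+\nIIII\n"
        )
        out1, out2 = tmp_path / "o1.fq", tmp_path / "o2.fq"
        subsample_every_nth(fq, out1, 1)
        subsample_every_nth(fq, out2, 1)
        assert out1.read_bytes() == out2.read_bytes()
        assert out1.read_text().startswith("@weird read id with spaces\n")

    def test_gzip_roundtrip(self, write_fastq, tmp_path):
        fq = write_fastq(["ACGTACGT"] * 4)
        out = tmp_path / "sub.fq.gz"
        subsample_every_nth(fq, out, 2)
        with gzip.open(out, "rt") as fh:
            assert sum(1 for _ in fh) == 8

    def test_oversampling_reports_both_numbers(self, write_fastq, tmp_path):
        fq = write_fastq(["ACGT"] * 3)
        with pytest.raises(ValueError, match="5.*3|3.*5"):
            subsample_every_nth(fq, tmp_path / "x.fq", 5)

    def test_prefix_mode(self, write_fastq, tmp_path):
        fq = write_fastq([random_dna(np.random.default_rng(i), 12) for i in range(6)])
        out = tmp_path / "p.fq"
        subsample_every_nth(fq, out, 2, mode="prefix")
        titles = [l for l in out.read_text().splitlines() if l.startswith("@r")]
        assert titles == ["@r0", "@r1"]
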