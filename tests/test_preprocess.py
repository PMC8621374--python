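"""Cleaning, collapsing and library statistics."""

import warnings

import pytest

from mirpipe import preprocess

ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"


def write_fastq(path, records):
    with open(path, "w") as fh:
        for i, (seq, qual) in enumerate(records):
            fh.write(f"@r{i}\n{seq}\n+\n{qual}\n")


def q(n, ch="G"):
    return ch * n


class TestCleanReads:
    def test_good_read_retained_and_trimmed(self, tmp_path):
        insert = "ACGTACGTACGTACGTACGTA"  # 21 nt
        raw = insert + ADAPTER3
        write_fastq(tmp_path / "a.fastq", [(raw, q(len(raw)))])
        res = preprocess.clean_reads(tmp_path / "a.fastq", ADAPTER3)
        assert res.reads == [insert]
        assert len(res.reads[0]) == 21

    def test_polya_discarded(self, tmp_path):
        raw = "A" * 26 + ADAPTER3
        write_fastq(tmp_path / "a.fastq", [(raw, q(len(raw)))])
        res = preprocess.clean_reads(tmp_path / "a.fastq", ADAPTER3)
        assert res.reads == []
        assert res.discards["homopolymer"] == 1

    def test_missing_adapter_discarded(self, tmp_path):
        raw = "ACGTACGTACGTACGTACGTACGTACGTACGTACGT"
        write_fastq(tmp_path / "a.fastq", [(raw, q(len(raw)))])
        res = preprocess.clean_reads(tmp_path / "a.fastq", ADAPTER3)
        assert res.discards["no_adapter"] == 1

    def test_adapter5_contamination_discarded(self, tmp_path):
        raw = "ACGT" + ADAPTER5 + "ACGTACGTACGTACGTACGTA" + ADAPTER3
        write_fastq(tmp_path / "a.fastq", [(raw, q(len(raw)))])
        res = preprocess.clean_reads(tmp_path / "a.fastq", ADAPTER3, ADAPTER5)
        assert res.discards["adapter5_contamination"] == 1

    def test_low_quality_discarded(self, tmp_path):
        insert = "ACGTACGTACGTACGTACGTA"
        raw = insert + ADAPTER3
        qual = "#" * 5 + q(len(raw) - 5)  # 5 of 21 insert bases below Q20
        write_fastq(tmp_path / "a.fastq", [(raw, qual)])
        res = preprocess.clean_reads(tmp_path / "a.fastq", ADAPTER3)
        assert res.discards["low_quality"] == 1

    def test_length_bounds(self, tmp_path):
        short = "ACGTACGTACGT" + ADAPTER3  # 12 nt insert
        long_ = "ACGTACGTACGTACGTACGTACGTACGTACGTACG" + ADAPTER3  # 35 nt
        write_fastq(
            tmp_path / "a.fastq",
            [(short, q(len(short))), (long_, q(len(long_)))],
        )
        res = preprocess.clean_reads(tmp_path / "a.fastq", ADAPTER3)
        assert res.discards["too_short"] == 1
        assert res.discards["too_long"] == 1

    def test_read_conservation(self, tmp_path, rng):
        records = []
        for i in range(300):
            insert = "".join(rng.choice(list("ACGT"), int(rng.integers(15, 34))))
            raw = insert + ADAPTER3
            qual = q(len(raw)) if rng.random() > 0.05 else "#" * len(raw)
            records.append((raw, qual))
        write_fastq(tmp_path / "a.fastq", records)
        res = preprocess.clean_reads(tmp_path / "a.fastq", ADAPTER3)
        assert res.n_clean + sum(res.discards.values()) == res.n_raw == 300

    def test_cleaning_idempotent(self, tmp_path):
        inserts = ["ACGTACGTACGTACGTACGTA", "GGCATCGATCGATCGTTAGCAT"]
        write_fastq(
            tmp_path / "a.fastq", [(s + ADAPTER3, q(len(s) + len(ADAPTER3))) for s in inserts]
        )
        first = preprocess.clean_reads(tmp_path / "a.fastq", ADAPTER3)
        write_fastq(
            tmp_path / "b.fastq",
            [(s + ADAPTER3, q(len(s) + len(ADAPTER3))) for s in first.reads],
        )
        second = preprocess.clean_reads(tmp_path / "b.fastq", ADAPTER3)
        assert second.reads == first.reads

    def test_malformed_record_raises_with_index(self, tmp_path):
        (tmp_path / "bad.fastq").write_text("@r0\nACGT\n+\nGGGG\nACGT\nnot-fastq\n")
        with pytest.raises(ValueError, match="index 1"):
            preprocess.clean_reads(tmp_path / "bad.fastq", ADAPTER3)


class TestCollapse:
    def test_basic_counts(self):
        tags = preprocess.collapse_tags({"L": [["AAC", "AAC", "AAC", "GGT", "GGT"]]})
        assert tags.loc["AAC", "L"] == 3
        assert tags.loc["GGT", "L"] == 2

    def test_replicate_averaging_gives_half_integers(self):
        tags = preprocess.collapse_tags({"L": [["T" * 20] * 5, ["T" * 20] * 4]})
        assert tags.loc["T" * 20, "L"] == 4.5

    def test_empty_library(self):
        tags = preprocess.collapse_tags({"L": [[]]})
        assert len(tags) == 0

    def test_collapse_expand_multiset_identity(self, rng):
        reads = [
            "".join(rng.choice(list("ACGT"), 20)) for _ in range(50)
        ] * 3
        tags = preprocess.collapse_tags({"L": [reads]})
        expanded = []
        for seq, n in tags["L"].items():
            expanded.extend([seq] * int(n))
        assert sorted(expanded) == sorted(reads)


class TestStats:
    def test_percentages_recompute_from_counts(self):
        s = preprocess.library_stats(
            "L", raw_reads=1000, clean_reads=900, mapped_reads=855
        )
        assert s.clean_pct == 90.0
        assert s.mapped_pct == 95.0

    def test_zero_denominator_warns_and_reports_zero(self):
        s = preprocess.library_stats("L", raw_reads=0, clean_reads=0)
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            assert s.clean_pct == 0.0
        assert rec

    def test_mirna_total_is_known_plus_novel(self):
        s = preprocess.library_stats(
            "L", raw_reads=10, clean_reads=10, known_mirna_reads=529_287,
            novel_mirna_reads=3_650_736,
        )
        assert s.mirna_reads_total == 4_180_023


class TestLengthDistribution:
    def test_single_tag_full_mass(self):
        tags = preprocess.collapse_tags({"L": [["A" * 22]]})
        hist = preprocess.length_distribution(tags)["L"]
        assert hist.loc[22, "read_frac"] == 1.0
        assert hist.loc[22, "tag_frac"] == 1.0

    def test_fractions_sum_to_one(self, rng):
        reads = ["".join(rng.choice(list("ACGT"), int(rng.integers(18, 31)))) for _ in range(200)]
        tags = preprocess.collapse_tags({"L": [reads]})
        hist = preprocess.length_distribution(tags)["L"]
        assert abs(hist["read_frac"].sum() - 1.0) < 1e-9
        assert abs(hist["tag_frac"].sum() - 1.0) < 1e-9
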