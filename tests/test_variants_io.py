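"""VCF/BED/SV IO and the somatic filtering cascade."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutspect import (
    FilterPolicy,
    LabeledIntervals,
    MutationRecord,
    SVRecord,
    apply_filters,
    read_bed,
    read_records_tsv,
    read_sv_table,
    read_vcf,
    write_records_tsv,
)

VCF_MINI = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=10000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
chr1\t100\t.\tA\tC\t50\tPASS\t.
chr1\t200\t.\tC\tA,T\t60\tPASS\t.
chr1\t300\t.\tG\t<INS>\t60\tPASS\t.
chr1\t400\t.\tT\tG\t60\tPASS\t.
chr1\t500\t.\tAT\tA\t60\tPASS\t.
"""


class TestReadVcf:
    def test_parse_multiallelic_and_symbolic(self, tmp_path):
        p = tmp_path / "mini.vcf"
        p.write_text(VCF_MINI)
        records, skipped = read_vcf(p, sample_id="s1")
        assert skipped == 1  # the <INS> allele
        assert len(records) == 5  # 4 sites kept, one split into two ALTs
        at_200 = [r for r in records if r.pos == 200]
        assert {r.alt for r in at_200} == {"A", "T"}
        assert all(r.sample_id == "s1" for r in records)
        # no QSS/DPT INFO: quality falls back to QUAL, depths stay unknown
        assert records[0].qual == 50.0
        assert records[0].depth_tumor is None

    def test_unreadable_file_names_path(self, tmp_path):
        with pytest.raises(IOError, match="nope.vcf"):
            read_vcf(tmp_path / "nope.vcf", sample_id="s")

    def test_toy_vcf_loads_20_records(self, toy_vcf_path):
        records, skipped = read_vcf(toy_vcf_path, sample_id="S1")
        assert len(records) == 20
        assert skipped == 0


class TestMutationRecord:
    def test_invariants(self):
        with pytest.raises(ValueError):
            MutationRecord("c", 0, "A", "C", "s")
        with pytest.raises(ValueError):
            MutationRecord("c", 1, "A", "A", "s")
        with pytest.raises(ValueError):
            MutationRecord("c", 1, "a", "C", "s")

    @pytest.mark.parametrize(
        "ref,alt,cls",
        [("A", "C", "SNV"), ("TG", "CA", "DBS"), ("TG", "TA", "MNV"),
         ("AT", "A", "indel"), ("A", "ATT", "indel")],
    )
    def test_variant_class(self, ref, alt, cls):
        assert MutationRecord("c", 5, ref, alt, "s").variant_class() == cls


def _toy_policy(blacklist):
    return FilterPolicy(min_qual=40, min_depth=20, min_alt_support=4,
                        blacklists=[blacklist], drop_shared=True)


class TestFilterCascade:
    @pytest.fixture
    def toy_setup(self, toy_vcf_path, blacklist_bed_path):
        records, _ = read_vcf(toy_vcf_path, sample_id="S1")
        blacklist = read_bed(blacklist_bed_path, "blacklist")
        s2 = [
            MutationRecord("chr1", 500, "C", "T", "S2", qual=60.0, depth_tumor=30,
                           depth_control=30, alt_support=10),
            MutationRecord("chr1", 550, "G", "C", "S2", qual=60.0, depth_tumor=30,
                           depth_control=30, alt_support=10),
        ]
        cohort = {"S1": records, "S2": s2}
        return records, _toy_policy(blacklist), cohort

    def test_hand_counted_removals(self, toy_setup):
        """The frozen 20-record fixture: 3 quality (39.5, 10, 35), 3 depth
        (19x tumor, 15x control, 10x tumor), 2 support (3 and 0 reads),
        2 blacklist (pos 1500 and 2000 inside chr1:1000-2000), 2 shared with
        the second sample; boundary calls (qual 40, depth 20, support 4,
        pos 2001) survive."""
        records, policy, cohort = toy_setup
        kept, report = apply_filters(records, policy, cohort)
        assert report.removed == {
            "quality": 3, "depth": 3, "support": 2, "blacklist": 2, "shared": 2,
        }
        assert len(kept) == 8
        assert {r.pos for r in kept} == {100, 400, 600, 650, 700, 900, 950, 2001}

    def test_report_counts_sum_to_removed(self, toy_setup):
        records, policy, cohort = toy_setup
        kept, report = apply_filters(records, policy, cohort)
        assert sum(report.removed.values()) == report.n_input - report.n_output

    def test_idempotence(self, toy_setup):
        records, policy, cohort = toy_setup
        kept, _ = apply_filters(records, policy, cohort)
        cohort2 = {"S1": kept, "S2": cohort["S2"]}
        kept2, report2 = apply_filters(kept, policy, cohort2)
        assert kept2 == kept
        assert report2.n_input == report2.n_output

    def test_sub_threshold_quality_removed(self):
        rec = MutationRecord("c", 5, "C", "T", "s", qual=39.5, depth_tumor=30,
                             depth_control=30, alt_support=10)
        kept, report = apply_filters([rec], FilterPolicy())
        assert kept == []
        assert report.removed == {"quality": 1}

    def test_missing_field_raises(self):
        rec = MutationRecord("c", 5, "C", "T", "s", qual=50.0)
        with pytest.raises(ValueError, match="depth_tumor"):
            apply_filters([rec], FilterPolicy())

    def test_shared_removal_matches_bruteforce(self, rng):
        """10 records, 2 shared across samples, drop_shared on -> 8 survive,
        matching a brute-force set difference on (chrom,pos,ref,alt)."""
        mk = lambda pos, sid: MutationRecord(
            "c", pos, "C", "T", sid, qual=60.0, depth_tumor=30, depth_control=30,
            alt_support=10)
        s1 = [mk(p, "S1") for p in range(10, 110, 10)]
        s2 = [mk(30, "S2"), mk(70, "S2")]
        cohort = {"S1": s1, "S2": s2}
        policy = FilterPolicy(drop_shared=True)
        kept, report = apply_filters(s1, policy, cohort)
        s2_keys = {r.key() for r in s2}
        brute = [r for r in s1 if r.key() not in s2_keys]
        assert kept == brute
        assert len(kept) == 8
        assert report.removed == {"shared": 2}

    def test_doublet_allele_balance_rule(self):
        def dbs(ab):
            return MutationRecord("c", 5, "TG", "CA", "s", qual=60.0, depth_tumor=30,
                                  depth_control=30, alt_support=10, allele_balance=ab)

        policy = FilterPolicy()
        # removal: 0.01 < AB < 0.25 or AB > 0.75; keep [0.25, 0.75] and <= 0.01
        kept, report = apply_filters([dbs(0.1), dbs(0.9), dbs(0.5), dbs(0.005)], policy)
        assert [r.allele_balance for r in kept] == [0.5, 0.005]
        assert report.removed == {"allele_balance": 2}

    def test_blacklist_matches_bruteforce_membership(self, rng):
        intervals = [("c", int(s), int(s) + int(l))
                     for s, l in zip(rng.integers(0, 9500, 30), rng.integers(1, 300, 30))]
        bl = LabeledIntervals.from_tuples("bl", intervals)
        records = [
            MutationRecord("c", int(p), "C", "T", "s", qual=60.0, depth_tumor=30,
                           depth_control=30, alt_support=10)
            for p in rng.integers(1, 10000, 500)
        ]
        kept, _ = apply_filters(records, FilterPolicy(blacklists=[bl]))
        brute = [
            r for r in records
            if not any(s <= r.pos - 1 < e for _, s, e in intervals)
        ]
        assert kept == brute


class TestReadBed:
    def test_overlapping_intervals_merged(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\nchr1\t50\t150\n")
        iv = read_bed(p, "x")
        assert iv.to_tuples() == [("chr1", 0, 150)]
        assert iv.total_length == 150

    def test_empty_bed(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        iv = read_bed(p, "x")
        assert iv.total_length == 0
        assert not iv.contains("chr1", 5)

    def test_disjoint_lengths_sum(self, tmp_path):
        p = tmp_path / "d.bed"
        p.write_text("chr1\t0\t10\nchr2\t100\t120\nchr1\t500\t530\n")
        assert read_bed(p, "x").total_length == 60

    def test_merge_is_order_invariant(self, rng, tmp_path):
        tuples = [("c", int(s), int(s) + int(l))
                  for s, l in zip(rng.integers(0, 1000, 40), rng.integers(1, 80, 40))]
        a = LabeledIntervals.from_tuples("x", tuples)
        b = LabeledIntervals.from_tuples("x", list(reversed(tuples)))
        assert a.to_tuples() == b.to_tuples()
        assert a.total_length == b.total_length

    @given(
        ivs=st.lists(
            st.tuples(st.integers(0, 1000), st.integers(1, 50)),
            min_size=1, max_size=30,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_merge_produces_disjoint_cover_of_same_positions(self, ivs):
        tuples = [("c", s, s + l) for s, l in ivs]
        li = LabeledIntervals.from_tuples("x", tuples)
        merged = li.to_tuples()
        for (_, _, e1), (_, s2, _) in zip(merged, merged[1:]):
            assert e1 < s2  # strictly separated after merging
        union = {p for _, s, e in tuples for p in range(s, e)}
        assert li.total_length == len(union)
        probe = {0, 500, 1049}
        for p in probe | {min(union), max(union)}:
            assert li.contains("c", p) == (p in union)

    def test_invalid_interval_names_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t100\n")
        with pytest.raises(ValueError, match="bad.bed:1"):
            read_bed(p, "x")


SV_TSV = """sample_id\tclass\tchromA\tposA\tchromB\tposB\tsupport
s1\tDEL\tchr1\t1000\tchr1\t6000\t10
s1\tTRA\tchr1\t1000\tchr5\t2000\t8
s1\tDUP\tchr2\t500\tchr2\t700\t3
"""


class TestSVTable:
    def test_parse_bins_and_flags(self, tmp_path):
        p = tmp_path / "sv.tsv"
        p.write_text(SV_TSV)
        recs = read_sv_table(p)
        assert recs[0].size == 5000
        assert recs[0].size_bin == "[1e3,1e4)"
        assert recs[1].size is None
        assert recs[1].size_bin == "interchromosomal"
        assert not recs[0].below_min_support
        assert recs[2].below_min_support  # support 3 < 4

    def test_unknown_class_rejected(self, tmp_path):
        p = tmp_path / "sv.tsv"
        p.write_text("sample_id\tclass\tchromA\tposA\tchromB\tposB\tsupport\n"
                     "s1\tBND\tchr1\t1\tchr1\t2\t9\n")
        with pytest.raises(ValueError, match="BND"):
            read_sv_table(p)


def test_records_tsv_round_trip(tmp_path):
    recs = [
        MutationRecord("chr1", 10, "C", "T", "s", qual=50.0, depth_tumor=30,
                       depth_control=25, alt_support=9),
        MutationRecord("chr1", 20, "TG", "CA", "s", allele_balance=0.5),
    ]
    p = tmp_path / "r.tsv"
    write_records_tsv(recs, p)
    assert read_records_tsv(p) == recs
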