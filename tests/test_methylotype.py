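"""Alignment filtering, insert reconstruction, locus calling and
classification."""

import numpy as np
import pandas as pd
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cream.methylotype import (
    Insert,
    Locus,
    PipelineConfig,
    build_matrix,
    call_loci,
    classify_locus_sample,
    coverage_filter,
    coverage_stats,
    exclude_low_yield_samples,
    filter_alignments,
    reconstruct_inserts,
)

CFG = PipelineConfig(check_boundary_motifs=False)


def make_sam(tmp_path, records, chrom_len=100_000):
    """Write SAM text records (without header) and parse them with pysam."""
    path = tmp_path / "records.sam"
    header = f"@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:{chrom_len}\n@SQ\tSN:chr2\tLN:{chrom_len}\n"
    path.write_text(header + "".join(records))
    with pysam.AlignmentFile(str(path)) as af:
        return list(af)


def sam_line(qname="q", flag=99, chrom="chr1", pos=101, mapq=30, cigar="50M",
             rnext="=", pnext=301, tlen=250, nm=0):
    length = int(cigar[:-1])  # single-M cigars only
    seq = "A" * length
    return (f"{qname}\t{flag}\t{chrom}\t{pos}\t{mapq}\t{cigar}\t{rnext}\t{pnext}"
            f"\t{tlen}\t{seq}\t{'I' * length}\tNM:i:{nm}\n")


class TestFilterAlignments:
    def test_mapq_boundary(self, tmp_path):
        records = make_sam(tmp_path, [sam_line(qname="a", mapq=19),
                                      sam_line(qname="b", mapq=20)])
        kept, counts = filter_alignments(records, CFG)
        assert [r.query_name for r in kept] == ["b"]
        assert counts["low_mapq"] == 1

    def test_improper_pair_removed(self, tmp_path):
        records = make_sam(tmp_path, [sam_line(flag=97)])  # not proper pair
        kept, counts = filter_alignments(records, CFG)
        assert kept == [] and counts["not_proper_pair"] == 1

    def test_secondary_and_supplementary_removed(self, tmp_path):
        records = make_sam(tmp_path, [sam_line(flag=99 | 256),
                                      sam_line(flag=99 | 2048)])
        kept, counts = filter_alignments(records, CFG)
        assert kept == [] and counts["not_primary_mapped"] == 2

    def test_mate_on_other_chromosome_removed(self, tmp_path):
        records = make_sam(tmp_path, [sam_line(rnext="chr2")])
        kept, counts = filter_alignments(records, CFG)
        assert kept == [] and counts["mate_other_chrom"] == 1

    def test_high_edit_distance_removed(self, tmp_path):
        records = make_sam(tmp_path, [sam_line(nm=6), sam_line(qname="ok", nm=5)])
        kept, counts = filter_alignments(records, CFG)
        assert [r.query_name for r in kept] == ["ok"]
        assert counts["high_nm"] == 1

    def test_counts_sum_to_input(self, tmp_path):
        records = make_sam(
            tmp_path,
            [sam_line(qname="a", mapq=5), sam_line(qname="b"),
             sam_line(qname="c", flag=4), sam_line(qname="d", nm=9)],
        )
        _, counts = filter_alignments(records, CFG)
        drop_reasons = [k for k in counts if k not in ("input", "retained")]
        assert counts["input"] == counts["retained"] + sum(
            counts[k] for k in drop_reasons
        )


class TestExcludeLowYieldSamples:
    @pytest.mark.parametrize(
        "msp, hpa, retained",
        [
            (150_000, 60_000, True),   # mean 105,000
            (90_000, 90_000, False),
            (100_000, 100_000, True),  # boundary inclusive
        ],
    )
    def test_mean_rule(self, msp, hpa, retained):
        counts = {"s": {"MspI": msp, "HpaII": hpa}}
        result = exclude_low_yield_samples(counts, PipelineConfig())
        assert (result == ["s"]) is retained

    def test_missing_library_counts_zero(self):
        counts = {"s": {"MspI": 250_000}}
        assert exclude_low_yield_samples(counts, PipelineConfig()) == ["s"]
        counts = {"s": {"MspI": 150_000}}
        assert exclude_low_yield_samples(counts, PipelineConfig()) == []


class TestReconstructInserts:
    def test_pair_arithmetic_and_collapse(self, tmp_path):
        lines = []
        for q in ("p1", "p2"):  # two identical pairs collapse, support 2
            lines.append(sam_line(qname=q, flag=99, pos=101, cigar="150M",
                                  pnext=281, tlen=330))
            lines.append(sam_line(qname=q, flag=147, pos=281, cigar="150M",
                                  pnext=101, tlen=-330))
        records = make_sam(tmp_path, lines)
        inserts, counts = reconstruct_inserts(records, "s", "MspI", CFG)
        assert len(inserts) == 1
        ins = inserts[0]
        assert (ins.start, ins.end, ins.support) == (100, 430, 2)
        assert ins.length == 330
        assert counts["pairs"] == 2

    def test_unpaired_records_counted(self, tmp_path):
        records = make_sam(tmp_path, [sam_line(qname="lonely")])
        inserts, counts = reconstruct_inserts(records, "s", "MspI", CFG)
        assert inserts == [] and counts["unpaired"] == 1

    def test_boundary_motif_check_drops_unanchored_insert(self, tmp_path):
        # genome with NsiI at 100 (cut 105) and CCGG at 354 (cut 355)
        seq = ["T"] * 1000
        seq[100:106] = "ATGCAT"
        seq[354:358] = "CCGG"
        genome = {"chr1": "".join(seq)}
        good = [
            sam_line(qname="g", flag=99, pos=106, cigar="100M", pnext=256,
                     tlen=250),
            sam_line(qname="g", flag=147, pos=256, cigar="100M", pnext=106,
                     tlen=-250),
        ]
        bad = [
            sam_line(qname="b", flag=99, pos=120, cigar="100M", pnext=256,
                     tlen=236),
            sam_line(qname="b", flag=147, pos=256, cigar="100M", pnext=120,
                     tlen=-236),
        ]
        config = PipelineConfig(check_boundary_motifs=True)
        records = make_sam(tmp_path, good + bad)
        inserts, counts = reconstruct_inserts(
            records, "s", "MspI", config, genome=genome
        )
        assert [(i.start, i.end) for i in inserts] == [(105, 355)]
        assert counts["boundary_motif_fail"] == 1


def brute_force_loci(intervals):
    """Transitive closure of pairwise >=1 bp overlap; the sweep oracle."""
    groups = [{i} for i in range(len(intervals))]

    def find(i):
        for g in groups:
            if i in g:
                return g
        raise AssertionError

    for i, (s1, e1) in enumerate(intervals):
        for j, (s2, e2) in enumerate(intervals):
            if i < j and s1 < e2 and s2 < e1:
                gi, gj = find(i), find(j)
                if gi is not gj:
                    gi |= gj
                    groups.remove(gj)
    spans = sorted(
        (min(intervals[i][0] for i in g), max(intervals[i][1] for i in g))
        for g in groups
    )
    return spans


class TestCallLoci:
    def test_overlapping_libraries_merge(self):
        inserts = [Insert("c", 100, 350, "MspI", "s1"),
                   Insert("c", 100, 350, "HpaII", "s1")]
        loci = call_loci(inserts)
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end, loci[0].type) == (100, 350, "overlapping")

    def test_one_bp_overlap_suffices(self):
        inserts = [Insert("c", 100, 350, "MspI", "s1"),
                   Insert("c", 340, 500, "HpaII", "s1")]
        loci = call_loci(inserts)
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end, loci[0].type) == (100, 500, "overlapping")

    def test_touching_intervals_do_not_merge(self):
        inserts = [Insert("c", 100, 350, "MspI", "s1"),
                   Insert("c", 350, 500, "MspI", "s1")]
        assert len(call_loci(inserts)) == 2

    def test_singleton_library_locus(self):
        loci = call_loci([Insert("c", 600, 800, "MspI", "s1")])
        assert len(loci) == 1
        assert loci[0].type == "msp_only"
        loci = call_loci([Insert("c", 600, 800, "HpaII", "s1")])
        assert loci[0].type == "hpa_only"

    def test_sweep_matches_transitive_closure_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 120))
            starts = rng.integers(0, 5000, size=n)
            lengths = rng.integers(1, 400, size=n)
            intervals = [(int(s), int(s + L)) for s, L in zip(starts, lengths)]
            inserts = [
                Insert("c", s, e, "MspI" if rng.random() < 0.5 else "HpaII",
                       f"s{int(rng.integers(3))}")
                for s, e in intervals
            ]
            spans = sorted((l.start, l.end) for l in call_loci(inserts))
            assert spans == brute_force_loci(intervals)


class TestCoverageFilter:
    def locus(self, supports):
        evidence = {
            f"s{i}": {"MspI": [(100, 350, sup)]} for i, sup in enumerate(supports)
        }
        return Locus("c", 100, 350, "msp_only", evidence)

    def test_half_of_samples_inclusive(self):
        loci = [self.locus([25, 30, 5, 0])]
        assert coverage_filter(loci, ["s0", "s1", "s2", "s3"], CFG) == loci

    def test_below_half_excluded(self):
        loci = [self.locus([25, 5, 5, 0])]
        assert coverage_filter(loci, ["s0", "s1", "s2", "s3"], CFG) == []

    def test_all_covered_retained(self):
        loci = [self.locus([25, 25, 25, 25])]
        assert coverage_filter(loci, ["s0", "s1", "s2", "s3"], CFG) == loci

    def test_no_samples_rejected(self):
        with pytest.raises(ValueError):
            coverage_filter([], [], CFG)

    def test_monotone_in_cov_min(self, rng):
        loci = [self.locus(list(rng.integers(0, 60, size=6))) for _ in range(30)]
        samples = [f"s{i}" for i in range(6)]
        previous = len(loci)
        for cov_min in (0, 10, 20, 40, 80):
            config = PipelineConfig(cov_min=cov_min, check_boundary_motifs=False)
            kept = len(coverage_filter(loci, samples, config))
            assert kept <= previous
            previous = kept


def evidence_locus(msp=None, hpa=None):
    ev = {}
    if msp:
        ev["MspI"] = msp
    if hpa:
        ev["HpaII"] = hpa
    return Locus("c", 100, 500, "overlapping", {"s": ev})


class TestClassify:
    @pytest.mark.parametrize(
        "msp, hpa, expected",
        [
            ([(100, 350, 20)], [(100, 350, 18)], "A"),
            ([(100, 350, 20)], None, "B"),
            (None, [(100, 350, 20)], "D"),
            ([(100, 300, 20)], [(100, 360, 15)], "C"),  # shared anchor end
            ([(100, 300, 20)], [(140, 300, 15)], "C"),  # anchored on the right
            ([(100, 300, 20)], [(120, 360, 15)], "AMB"),  # both ends differ
            (None, None, "NA"),
            ([(100, 350, 2)], None, "NA"),  # below presence_min
            ([(100, 300, 20), (100, 400, 20)], [(100, 300, 20)], "AMB"),
        ],
    )
    def test_truth_table_examples(self, msp, hpa, expected):
        locus = evidence_locus(msp, hpa)
        assert classify_locus_sample(locus, "s", CFG) == expected

    def test_end_slop_tolerates_small_shifts(self):
        config = PipelineConfig(end_slop=3, check_boundary_motifs=False)
        locus = evidence_locus([(100, 350, 20)], [(102, 349, 20)])
        assert classify_locus_sample(locus, "s", config) == "A"

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_every_evidence_configuration_has_exactly_one_status(self, data):
        interval = st.tuples(
            st.integers(0, 50), st.integers(51, 120), st.integers(1, 40)
        )
        msp = data.draw(st.lists(interval, max_size=3))
        hpa = data.draw(st.lists(interval, max_size=3))
        locus = evidence_locus(msp or None, hpa or None)
        status = classify_locus_sample(locus, "s", CFG)
        assert status in ("A", "B", "C", "D", "AMB", "NA")

    def test_unknown_sample_is_missing(self):
        locus = evidence_locus([(100, 350, 20)], None)
        assert classify_locus_sample(locus, "other", CFG) == "NA"


class TestBuildMatrix:
    def test_majority_sets(self):
        loci = [
            Locus("c", 0, 300, "overlapping",
                  {s: {"MspI": [(0, 300, 20)], "HpaII": [(0, 300, 20)]}
                   for s in ("s1", "s2")}),
            Locus("c", 400, 700, "msp_only",
                  {s: {"MspI": [(400, 700, 20)]} for s in ("s1", "s2")}),
            Locus("c", 800, 1100, "overlapping",
                  {"s1": {"MspI": [(800, 1100, 20)], "HpaII": [(800, 1100, 20)]},
                   "s2": {"MspI": [(800, 1050, 20)]}}),
        ]
        matrix = build_matrix(loci, ["s1", "s2"], CFG)
        summary = matrix.locus_summary().set_index("locus")
        assert summary.loc["c:0-300", "set"] == "unmethylated"
        assert summary.loc["c:400-700", "set"] == "methylated"
        assert summary.loc["c:800-1100", "set"] == "ambiguous"  # 1 A vs 1 B
        binary = matrix.binary
        assert binary.loc["s1", "c:0-300"] == 0.0
        assert binary.loc["s2", "c:400-700"] == 1.0

    def test_b_and_d_calls_are_disjoint_per_cell(self):
        # a cell has exactly one status: B and D cannot coexist by construction
        locus = evidence_locus([(100, 350, 20)], [(360, 500, 20)])
        status = classify_locus_sample(locus, "s", CFG)
        assert status in ("AMB",)  # both present, both ends differ

    def test_no_samples_rejected(self):
        with pytest.raises(ValueError):
            build_matrix([], [], CFG)


class TestCoverageStats:
    def test_single_insert_arithmetic(self):
        stats = coverage_stats(
            [Insert("c", 0, 400, "MspI", "s", support=10)], {"c": 10_000}
        )
        assert stats["MspI"]["pct_covered"] == pytest.approx(4.0)
        assert stats["MspI"]["mean_depth"] == pytest.approx(10.0)

    def test_disjoint_inserts_union(self):
        inserts = [Insert("c", 0, 200, "MspI", "s"),
                   Insert("c", 5000, 5200, "MspI", "s")]
        stats = coverage_stats(inserts, {"c": 10_000})
        assert stats["MspI"]["pct_covered"] == pytest.approx(4.0)

    def test_no_inserts_flagged(self):
        assert coverage_stats([], {"c": 10_000}) == {}
        stats = coverage_stats([Insert("c", 0, 100, "HpaII", "s")], {"c": 1000})
        assert "MspI" not in stats

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            coverage_stats([], {})
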