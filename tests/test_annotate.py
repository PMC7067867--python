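"""Annotation: overlap ratio, counting rules, interval index, database IO."""

import numpy as np
import pytest

from helpers import linear_scan_overlap, mk_read
from srnakit import align, annotate
from srnakit.align import Alignment
from srnakit.annotate import FeatureIndex, FeatureRecord


def aln(start, end, chrom="chr1", strand="+", read_id="r1", span=None, length=None):
    n = end - start
    return Alignment(read_id, chrom, start, end, strand, 0,
                     span or (0, n), length or n)


def feat(start, end, chrom="chr1", strand="+", rna_type="miRNA",
         name="m1", db="db1", feat_id="id1"):
    return FeatureRecord(db, rna_type, name, feat_id, chrom, start, end, strand)


class TestOverlapRatio:
    def test_full_containment_gives_ratio_one(self):
        ratio = annotate.compute_overlap_ratio(aln(105, 127), feat(100, 130))
        assert ratio.l_olp == 22 and ratio.l_read == 22 and ratio.r_olp == 1.0

    def test_disjoint_intervals_give_zero(self):
        assert annotate.compute_overlap_ratio(aln(10, 30), feat(100, 130)).r_olp == 0.0

    def test_partial_overlap(self):
        ratio = annotate.compute_overlap_ratio(aln(100, 120), feat(110, 140))
        assert (ratio.l_olp, ratio.l_read, ratio.r_olp) == (10, 20, 0.5)

    def test_different_chromosome_gives_zero(self):
        assert annotate.compute_overlap_ratio(
            aln(100, 120, chrom="chr2"), feat(100, 130)
        ).r_olp == 0.0

    def test_soft_clipped_read_uses_aligned_span_by_default(self):
        a = aln(100, 118, span=(4, 22), length=22)
        ratio = annotate.compute_overlap_ratio(a, feat(95, 125))
        assert ratio.l_read == 18 and ratio.r_olp == 1.0
        full = annotate.compute_overlap_ratio(a, feat(95, 125), full_read_length=True)
        assert full.l_read == 22 and full.r_olp < 1.0

    def test_containment_iff_ratio_one(self):
        rng = np.random.default_rng(3)
        feature = feat(200, 260)
        for _ in range(200):
            start = int(rng.integers(150, 300))
            end = start + int(rng.integers(10, 40))
            a = aln(start, end)
            contained = 200 <= start and end <= 260
            assert (annotate.compute_overlap_ratio(a, feature).r_olp == 1.0) == contained


class TestAnnotateRead:
    def test_nested_molecules_both_assigned(self):
        """A read inside both a miRNA and an enclosing piRNA hits both."""
        features = [
            feat(100, 122, rna_type="miRNA", name="let-7a-5p"),
            feat(100, 130, rna_type="piRNA", name="piR_008113", db="db2"),
        ]
        index = FeatureIndex(features)
        molecules = {f.molecule for f in annotate.annotate_read([aln(100, 122)], index)}
        assert molecules == {("miRNA", "let-7a-5p"), ("piRNA", "piR_008113")}

    def test_multimap_to_one_molecule_collapses_to_one_count(self):
        features = [feat(i * 100, i * 100 + 30, name="plex", feat_id=f"l{i}")
                    for i in range(11)]
        index = FeatureIndex(features)
        group = [aln(i * 100 + 4, i * 100 + 26, read_id="r9") for i in range(11)]
        tables, _ = annotate.quantify({"r9": group}, index)
        mirna = tables["miRNA"]
        assert list(mirna["Name"]) == ["plex"]
        assert list(mirna["Count"]) == [1]

    def test_no_overlap_gives_empty_set(self):
        index = FeatureIndex([feat(500, 530)])
        assert annotate.annotate_read([aln(100, 122)], index) == set()

    def test_strand_mode(self):
        index = FeatureIndex([feat(100, 130, strand="-")])
        assert annotate.annotate_read([aln(100, 122)], index) == set()
        assert len(annotate.annotate_read([aln(100, 122)], index,
                                          strand_mode="ignore")) == 1

    def test_one_base_outside_rejected_at_default_ratio(self):
        index = FeatureIndex([feat(100, 130)])
        assert len(annotate.annotate_read([aln(108, 130)], index)) == 1
        assert annotate.annotate_read([aln(109, 131)], index) == set()


class TestQuantify:
    def test_five_reads_in_one_mirna(self):
        index = FeatureIndex([feat(100, 130)])
        groups = {f"r{i}": [aln(104, 126, read_id=f"r{i}")] for i in range(5)}
        tables, _ = annotate.quantify(groups, index)
        assert list(tables["miRNA"]["Count"]) == [5]

    def test_column_sums_may_exceed_reads_with_no_priority(self):
        index = FeatureIndex([
            feat(100, 122, rna_type="miRNA", name="m"),
            feat(100, 130, rna_type="piRNA", name="p"),
        ])
        tables, _ = annotate.quantify({"r1": [aln(100, 122)]}, index)
        total = sum(int(t["Count"].sum()) for t in tables.values())
        assert total == 2  # one read, two molecules

    def test_empty_input_gives_header_only_tables(self):
        tables, _ = annotate.quantify({}, FeatureIndex([feat(1, 10)]))
        for table in tables.values():
            assert list(table.columns) == ["DB", "Name", "ID", "Count"]
            assert len(table) == 0

    def test_per_read_contribution_at_most_one(self, aligned, feature_index):
        alns, _ = aligned
        groups = align.group_by_read(alns)
        tables, read_annotations = annotate.quantify(groups, feature_index)
        # brute-force tally: each read contributes exactly once per molecule
        expected = {}
        for molecules in read_annotations.values():
            for mol in molecules:
                expected[mol] = expected.get(mol, 0) + 1
        got = {}
        for rna_type, table in tables.items():
            for _, row in table.iterrows():
                got[(rna_type, row["Name"])] = int(row["Count"])
        assert got == expected

    def test_lowering_min_ratio_never_decreases_counts(self, aligned, feature_index):
        alns, _ = aligned
        groups = align.group_by_read(alns)
        strict, _ = annotate.quantify(groups, feature_index, min_ratio=1.0)
        loose, _ = annotate.quantify(groups, feature_index, min_ratio=0.5)
        for rna_type in annotate.RNA_TYPES:
            s = dict(zip(strict[rna_type]["Name"], strict[rna_type]["Count"]))
            l = dict(zip(loose[rna_type]["Name"], loose[rna_type]["Count"]))
            for name, count in s.items():
                assert l.get(name, 0) >= count

    def test_same_molecule_in_two_databases_merges_with_both_listed(self):
        index = FeatureIndex([
            feat(100, 130, db="dbA", feat_id="idA"),
            feat(100, 130, db="dbB", feat_id="idB"),
        ])
        tables, _ = annotate.quantify({"r1": [aln(104, 126)]}, index)
        row = tables["miRNA"].iloc[0]
        assert row["DB"] == "dbA;dbB" and row["Count"] == 1


class TestFeatureIndex:
    def test_matches_linear_scan_on_random_queries(self):
        rng = np.random.default_rng(23)
        records = []
        for i in range(400):
            chrom = f"chr{int(rng.integers(1, 4))}"
            start = int(rng.integers(0, 50_000))
            records.append(feat(start, start + int(rng.integers(20, 300)),
                                chrom=chrom, name=f"f{i}", feat_id=f"id{i}"))
        index = FeatureIndex(records)
        for _ in range(1000):
            chrom = f"chr{int(rng.integers(1, 5))}"
            start = int(rng.integers(0, 50_000))
            end = start + int(rng.integers(1, 200))
            assert set(index.query(chrom, start, end)) == linear_scan_overlap(
                records, chrom, start, end
            )


class TestFeatureDbIO:
    def test_load_and_round_trip(self, tmp_path):
        path = tmp_path / "db.bed"
        path.write_text(
            "# comment\n"
            "chr1\t100\t130\tmolA\tidA\t+\n"
            "chr1\t500\t530\tmolB\tidB\t-\n"
            "chr2\t10\t40\tmolC\tidC\t+\n"
        )
        records = annotate.load_feature_db(str(path), "toydb", "piRNA")
        assert len(records) == 3
        assert records[0].start == 100 and records[0].end == 130
        assert all(r.db == "toydb" and r.rna_type == "piRNA" for r in records)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.bed"
        path.write_text("")
        assert annotate.load_feature_db(str(path), "d", "miRNA") == []

    @pytest.mark.parametrize(
        "line,match",
        [
            ("chr1\t50\t50\tm\ti\t+", "start must be < end"),
            ("chr1\t50\t60\tm\ti", "expected 6"),
            ("chr1\t50\t60\tm\ti\t?", "strand"),
            ("chr1\tx\t60\tm\ti\t+", "non-integer"),
        ],
    )
    def test_malformed_lines_error_with_line_number(self, tmp_path, line, match):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t1\t30\tok\tid\t+\n" + line + "\n")
        with pytest.raises(ValueError, match="2"):
            annotate.load_feature_db(str(path), "d", "miRNA")

    def test_duplicate_lines_deduplicated(self, tmp_path):
        path = tmp_path / "dup.bed"
        path.write_text("chr1\t1\t30\tm\ti\t+\n" * 3)
        assert len(annotate.load_feature_db(str(path), "d", "miRNA")) == 1


class TestExportByType:
    def test_export_filters_by_annotation(self, tmp_path):
        index = FeatureIndex([
            feat(100, 122, rna_type="miRNA", name="m"),
            feat(100, 130, rna_type="piRNA", name="p"),
            feat(600, 640, rna_type="tRNA", name="t"),
        ])
        reads = {f"r{i}": mk_read("A" * 22, read_id=f"r{i}") for i in range(3)}
        groups = {
            "r0": [aln(100, 122, read_id="r0")],      # miRNA + piRNA
            "r1": [aln(610, 632, read_id="r1")],      # tRNA
            "r2": [aln(5000, 5022, read_id="r2")],    # nothing
        }
        alns = [g[0] for g in groups.values()]
        _, read_annotations = annotate.quantify(groups, index)
        lengths = {"chr1": 10_000}
        out = tmp_path / "mirna.sam"
        n = annotate.export_reads_by_type(alns, read_annotations, "miRNA",
                                          str(out), lengths, reads)
        assert n == 1
        back, _ = align.ingest_sam(str(out))
        assert [a.read_id for a in back] == ["r0"]
        # no-priority: the same read appears in the piRNA export too
        out2 = tmp_path / "pirna.sam"
        assert annotate.export_reads_by_type(alns, read_annotations, "piRNA",
                                             str(out2), lengths, reads) == 1

    def test_unknown_type_lists_valid_types(self, tmp_path):
        with pytest.raises(ValueError, match="miRNA"):
            annotate.export_reads_by_type([], {}, "mystery",
                                          str(tmp_path / "x.sam"), {"chr1": 10})
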