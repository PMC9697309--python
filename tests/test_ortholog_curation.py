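import pytest

from aposcan.ortholog_curation import (
    AnnotationRecord,
    CurationParams,
    DiscardEntry,
    LocusRecord,
    OrthologTable,
    annotation_clean,
    orf_length_filter,
    read_annotation_tsv,
    select_single_copy,
    write_annotation_tsv,
)
from aposcan.sample_design import SampleDesign


@pytest.fixture
def design(three_sample_design):
    return three_sample_design


def _table(rows):
    return OrthologTable(rows=rows)


class TestProteinOrthoParsing:
    def test_dialect_roundtrip(self, tmp_path):
        path = tmp_path / "po.tsv"
        path.write_text(
            "# Species\tGenes\tAlg.-Conn.\ta\tb\th\n"
            "3\t3\t1\tc1\tc2\tc3\n"
            "2\t3\t0.5\tc4,c5\t*\tc6\n"
        )
        table = OrthologTable.read_proteinortho(path)
        assert table.rows == [
            {"a": ["c1"], "b": ["c2"], "h": ["c3"]},
            {"a": ["c4", "c5"], "b": [], "h": ["c6"]},
        ]

    def test_missing_design_column_rejected(self, tmp_path, design):
        path = tmp_path / "po.tsv"
        path.write_text("# Species\tGenes\tAlg.-Conn.\ta\tb\nc\t2\t1\tc1\tc2\n")
        table = OrthologTable.read_proteinortho(path)
        with pytest.raises(ValueError, match="h"):
            select_single_copy(table, design)


class TestSingleCopySelection:
    def test_single_copy_group_retained(self, design):
        loci, discards = select_single_copy(
            _table([{"a": ["c1"], "b": ["c2"], "h": ["c3"]}]), design
        )
        assert len(loci) == 1 and not discards
        assert loci[0].contigs == {"a": "c1", "b": "c2", "h": "c3"}

    def test_multi_copy_group_discarded_with_reason(self, design):
        loci, discards = select_single_copy(
            _table([{"a": ["c1", "c1b"], "b": ["c2"], "h": ["c3"]}]), design
        )
        assert not loci
        assert discards[0].stage == "single_copy" and "a" in discards[0].reason

    def test_toy_table_of_five_groups_keeps_the_two_single_copy(self, design):
        rows = [
            {"a": ["c1"], "b": ["c2"], "h": ["c3"]},     # keep
            {"a": ["c4", "c5"], "b": ["c6"], "h": ["c7"]},
            {"a": [], "b": ["c8"], "h": ["c9"]},
            {"a": ["c10"], "b": ["c11"], "h": ["c12"]},  # keep
            {"a": ["c13"], "b": ["c14", "c15"], "h": []},
        ]
        loci, discards = select_single_copy(_table(rows), design)
        assert [l.locus_id for l in loci] == ["locus_00000", "locus_00003"]
        assert len(loci) + len(discards) == len(rows)

    def test_empty_table_warns_and_returns_empty(self, design, caplog):
        with caplog.at_level("WARNING"):
            loci, discards = select_single_copy(_table([]), design)
        assert loci == [] and discards == []
        assert "empty" in caplog.text


class TestOrfLengthFilter:
    def _loci(self):
        return [LocusRecord("locus_0", {"a": "c1", "b": "c2", "h": "c3"})]

    def test_exact_threshold_is_retained(self):
        seqs = {"c1": "A" * 300, "c2": "A" * 402, "c3": "A" * 300}
        loci, discards = orf_length_filter(self._loci(), seqs)
        assert len(loci) == 1 and not discards

    def test_one_base_below_threshold_removed(self):
        seqs = {"c1": "A" * 299, "c2": "A" * 402, "c3": "A" * 300}
        loci, discards = orf_length_filter(self._loci(), seqs)
        assert not loci and discards[0].stage == "orf_length"

    def test_missing_sequence_is_hard_error_naming_contig(self):
        with pytest.raises(KeyError, match="c2"):
            orf_length_filter(self._loci(), {"c1": "A" * 300, "c3": "A" * 300})

    def test_identity_when_all_loci_long_enough(self):
        seqs = {"c1": "A" * 600, "c2": "A" * 600, "c3": "A" * 600}
        loci, discards = orf_length_filter(self._loci(), seqs)
        assert loci == self._loci() and not discards


class TestAnnotationClean:
    def _locus(self, n=0):
        return LocusRecord(
            f"locus_{n}", {"a": f"ca{n}", "b": f"cb{n}", "h": f"ch{n}"}
        )

    def test_non_spermatophyte_contaminant_removed(self):
        ann = [AnnotationRecord("ca0", "G1", "Fungi", ((0, 10),))]
        loci, discards = annotation_clean([self._locus()], ann)
        assert not loci and discards[0].stage == "contaminant"

    def test_reference_gene_shared_by_two_contigs_removes_both_loci(self):
        ann = [
            AnnotationRecord("ca0", "ASY1", "Spermatophyta", ((0, 10),)),
            AnnotationRecord("ca1", "ASY1", "Spermatophyta", ((5, 20),)),
        ]
        loci, discards = annotation_clean([self._locus(0), self._locus(1)], ann)
        assert not loci
        assert all(d.stage == "paralog" for d in discards)

    def test_multi_gene_contig_kept_without_overlap_removed_with(self):
        no_overlap = [
            AnnotationRecord("ca0", "G1", "Spermatophyta", ((0, 100),)),
            AnnotationRecord("ca0", "G2", "Spermatophyta", ((150, 200),)),
        ]
        loci, _ = annotation_clean([self._locus()], no_overlap)
        assert len(loci) == 1 and loci[0].annotated

        overlap = [
            AnnotationRecord("ca0", "G1", "Spermatophyta", ((0, 100),)),
            AnnotationRecord("ca0", "G2", "Spermatophyta", ((90, 200),)),
        ]
        loci, discards = annotation_clean([self._locus()], overlap)
        assert not loci and discards[0].stage == "fragment_overlap"

    def test_shared_single_base_counts_as_overlap(self):
        touching = [
            AnnotationRecord("ca0", "G1", "Spermatophyta", ((0, 100),)),
            AnnotationRecord("ca0", "G2", "Spermatophyta", ((99, 200),)),
        ]
        loci, discards = annotation_clean([self._locus()], touching)
        assert not loci and discards[0].stage == "fragment_overlap"

    def test_unannotated_locus_flows_through_flagged(self):
        loci, discards = annotation_clean([self._locus()], [])
        assert len(loci) == 1 and not discards
        assert loci[0].annotated is False

    def test_go_terms_collected_onto_locus(self):
        ann = [
            AnnotationRecord(
                "ca0", "G1", "Spermatophyta", ((0, 10),),
                go_terms=("GO:0007143", "GO:0009555"),
            )
        ]
        loci, _ = annotation_clean([self._locus()], ann)
        assert loci[0].go_terms == ("GO:0007143", "GO:0009555")

    def test_filters_idempotent_on_own_output(self):
        ann = [
            AnnotationRecord("ca0", "G1", "Spermatophyta", ((0, 10),)),
            AnnotationRecord("ca1", "G2", "Fungi", ((0, 10),)),
        ]
        loci = [self._locus(0), self._locus(1)]
        once, d1 = annotation_clean(loci, ann)
        twice, d2 = annotation_clean(once, ann)
        assert [l.locus_id for l in once] == [l.locus_id for l in twice]
        assert not d2
        assert len(once) + len(d1) == len(loci)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError, match="interval"):
            AnnotationRecord("c", "G", "Spermatophyta", ((10, 10),))


class TestParams:
    @pytest.mark.parametrize("bad", [0, 2, 301])
    def test_min_orf_must_be_positive_multiple_of_three(self, bad):
        with pytest.raises(ValueError):
            CurationParams(min_orf_nt=bad)


def test_annotation_tsv_roundtrip(tmp_path):
    records = [
        AnnotationRecord(
            "c1", "ASY1", "Spermatophyta", ((0, 90), (120, 300)),
            go_terms=("GO:0007129",),
        ),
        AnnotationRecord("c2"),
    ]
    path = tmp_path / "ann.tsv"
    write_annotation_tsv(records, path)
    assert read_annotation_tsv(path) == records
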