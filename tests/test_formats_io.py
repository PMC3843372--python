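import gzip

import pytest
from hypothesis import given, strategies as st

from helpers import pileup_intervals_from_cigar, SAM_OPS
from tagcplot import formats_io
from tagcplot.errors import FormatError, StructuralError
from tagcplot.formats_io import (
    ContigSeq,
    cigar_reference_intervals,
    normalize_read_id,
    read_alignments,
    read_fasta,
    read_fastq,
    read_fastq_pairs,
    read_hits,
    read_tagc_tsv,
    read_taxdump,
    write_fasta,
    write_fastq,
    write_tagc_tsv,
    write_taxdump,
)

# op codes as pysam numbers: M=0 I=1 D=2 N=3 S=4 H=5 P=6 ==7 X=8
_OP_NUM = {op: i for i, op in enumerate(SAM_OPS)}


# --- FASTA -----------------------------------------------------------------

class TestFasta:
    def test_single_record(self, tmp_path):
        path = tmp_path / "a.fa"
        path.write_text(">c1 desc\nacgt\n")
        records = list(read_fasta(path))
        assert records == [ContigSeq(id="c1", residues="ACGT")]

    def test_two_records_in_order(self, tmp_path):
        path = tmp_path / "a.fa"
        path.write_text(">c1\nAC\nGT\n>c2\nTTTT\n")
        records = list(read_fasta(path))
        assert [r.id for r in records] == ["c1", "c2"]
        assert records[0].residues == "ACGT"

    def test_sequence_before_header_is_error(self, tmp_path):
        path = tmp_path / "a.fa"
        path.write_text("ACGT\n>c1\nACGT\n")
        with pytest.raises(FormatError, match="line 1"):
            list(read_fasta(path))

    def test_gzip_transparency(self, tmp_path):
        path = tmp_path / "a.fa.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(">c1\nACGT\n")
        assert list(read_fasta(path))[0].id == "c1"

    def test_round_trip(self, tmp_path):
        contigs = [ContigSeq("c1", "ACGTN" * 40), ContigSeq("c2", "GG")]
        path = tmp_path / "out.fa"
        write_fasta(contigs, path)
        assert list(read_fasta(path)) == contigs

    @given(
        seqs=st.lists(
            st.text(alphabet="ACGTN", min_size=1, max_size=200),
            min_size=1, max_size=5,
        )
    )
    def test_round_trip_property(self, seqs, tmp_path_factory):
        contigs = [ContigSeq(f"c{i}", s) for i, s in enumerate(seqs)]
        path = tmp_path_factory.mktemp("fa") / "x.fa"
        write_fasta(contigs, path)
        assert list(read_fasta(path)) == contigs


# --- cigar interval decomposition ------------------------------------------

class TestCigarIntervals:
    def test_single_match_block(self):
        assert cigar_reference_intervals(0, [(0, 10)]) == ((0, 10),)

    def test_deletion_splits_intervals(self):
        # 3M2D4M at position 2: deletion consumes reference, adds no depth
        cig = [(_OP_NUM["M"], 3), (_OP_NUM["D"], 2), (_OP_NUM["M"], 4)]
        assert cigar_reference_intervals(2, cig) == ((2, 5), (7, 11))

    def test_insertion_and_softclip_ignored(self):
        cig = [(_OP_NUM["S"], 5), (_OP_NUM["M"], 4), (_OP_NUM["I"], 3),
               (_OP_NUM["M"], 2)]
        # insertion consumes no reference: adjacent matches merge
        assert cigar_reference_intervals(10, cig) == ((10, 16),)

    def test_eq_and_x_count_as_match(self):
        cig = [(_OP_NUM["="], 3), (_OP_NUM["X"], 2)]
        assert cigar_reference_intervals(0, cig) == ((0, 5),)

    @given(
        pos=st.integers(min_value=0, max_value=50),
        ops=st.lists(
            st.tuples(
                st.sampled_from("MIDNS=X"),
                st.integers(min_value=1, max_value=8),
            ),
            min_size=1, max_size=20,
        ),
    )
    def test_matches_per_base_pileup_oracle(self, pos, ops):
        numeric = [(_OP_NUM[op], length) for op, length in ops]
        assert cigar_reference_intervals(pos, numeric) == \
            pileup_intervals_from_cigar(pos, ops)


# --- SAM reading -----------------------------------------------------------

SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:c1\tLN:100\n@SQ\tSN:c2\tLN:50\n"


def _write_sam(tmp_path, body):
    path = tmp_path / "x.sam"
    path.write_text(SAM_HEADER + body)
    return path


class TestReadAlignments:
    def test_mapped_record(self, tmp_path):
        path = _write_sam(
            tmp_path, "r1\t0\tc1\t1\t60\t10M\t*\t0\t0\tACGTACGTAC\t*\n"
        )
        (rec,) = read_alignments(path)
        assert rec.is_mapped and rec.is_primary
        assert rec.contig_id == "c1"
        assert rec.reference_consumed_intervals == ((0, 10),)
        assert rec.mate_role == formats_io.UNPAIRED

    def test_position_converted_to_zero_based(self, tmp_path):
        path = _write_sam(tmp_path, "r1\t0\tc1\t3\t60\t4M\t*\t0\t0\tACGT\t*\n")
        (rec,) = read_alignments(path)
        assert rec.reference_consumed_intervals == ((2, 6),)

    def test_unmapped_record(self, tmp_path):
        path = _write_sam(tmp_path, "r1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*\n")
        (rec,) = read_alignments(path)
        assert not rec.is_mapped
        assert rec.contig_id is None
        assert rec.reference_consumed_intervals == ()

    def test_secondary_and_supplementary_not_primary(self, tmp_path):
        body = (
            "r1\t256\tc1\t1\t0\t4M\t*\t0\t0\tACGT\t*\n"
            "r2\t2048\tc1\t1\t0\t4M\t*\t0\t0\tACGT\t*\n"
        )
        recs = list(read_alignments(_write_sam(tmp_path, body)))
        assert [r.is_primary for r in recs] == [False, False]

    def test_mate_roles(self, tmp_path):
        body = (
            "r1\t99\tc1\t1\t60\t4M\t=\t20\t23\tACGT\t*\n"
            "r1\t147\tc1\t20\t60\t4M\t=\t1\t-23\tACGT\t*\n"
        )
        recs = list(read_alignments(_write_sam(tmp_path, body)))
        assert recs[0].mate_role == formats_io.FIRST_IN_PAIR
        assert recs[1].mate_role == formats_io.SECOND_IN_PAIR

    def test_missing_cigar_skipped(self, tmp_path, caplog):
        body = (
            "r1\t0\tc1\t1\t60\t*\t*\t0\t0\tACGT\t*\n"
            "r2\t0\tc1\t1\t60\t4M\t*\t0\t0\tACGT\t*\n"
        )
        with caplog.at_level("WARNING"):
            recs = list(read_alignments(_write_sam(tmp_path, body)))
        assert [r.read_id for r in recs] == ["r2"]
        assert "no cigar" in caplog.text

    def test_bam_equivalent_to_sam(self, tmp_path):
        import pysam

        body = (
            "r1\t99\tc1\t3\t60\t4M2D3M\t=\t30\t33\tACGTACG\t*\n"
            "r1\t147\tc1\t30\t60\t7M\t=\t3\t-33\tACGTACG\t*\n"
            "r2\t4\t*\t0\t0\t*\t*\t0\t0\tAC\t*\n"
        )
        sam = _write_sam(tmp_path, body)
        bam = tmp_path / "x.bam"
        with pysam.AlignmentFile(sam) as src, \
                pysam.AlignmentFile(bam, "wb", template=src) as dst:
            for aln in src:
                dst.write(aln)
        assert list(read_alignments(bam)) == list(read_alignments(sam))

    def test_unknown_reference_is_format_error(self, tmp_path):
        path = _write_sam(
            tmp_path, "r1\t0\tc99\t1\t60\t4M\t*\t0\t0\tACGT\t*\n"
        )
        with pytest.raises(FormatError):
            list(read_alignments(path))


# --- BLAST hits ------------------------------------------------------------

class TestReadHits:
    def test_two_column(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text("contig1\t6239\n")
        (hit,) = read_hits(path)
        assert hit.query_id == "contig1"
        assert hit.taxids == (6239,)
        assert hit.evalue is None and hit.bitscore is None

    def test_semicolon_multi_taxid(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text("contig1\t6239;6279\n")
        assert next(iter(read_hits(path))).taxids == (6239, 6279)

    def test_file_rank_increases(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text("a\t1\nb\t2\nc\t3\n")
        assert [h.file_rank for h in read_hits(path)] == [0, 1, 2]

    def test_four_column_with_scores(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text("a\t1\t1e-30\t95.5\n")
        (hit,) = read_hits(path)
        assert hit.evalue == 1e-30 and hit.bitscore == 95.5

    def test_non_integer_taxid_names_line(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text("a\t1\nb\tnotanumber\n")
        with pytest.raises(FormatError, match=":2:"):
            list(read_hits(path))


# --- taxdump ---------------------------------------------------------------

def _write_dump(tmp_path, nodes_rows, names_rows):
    nodes = tmp_path / "nodes.dmp"
    names = tmp_path / "names.dmp"
    nodes.write_text("".join(f"{r}\t|\n" for r in nodes_rows))
    names.write_text("".join(f"{r}\t|\n" for r in names_rows))
    return nodes, names


class TestTaxdump:
    def test_three_node_chain(self, tmp_path):
        nodes, names = _write_dump(
            tmp_path,
            ["1\t|\t1\t|\tno rank", "2\t|\t1\t|\torder", "3\t|\t2\t|\tspecies"],
            ["1\t|\troot\t|\t\t|\tscientific name",
             "2\t|\tOrdo\t|\t\t|\tscientific name",
             "3\t|\tSpec\t|\t\t|\tscientific name"],
        )
        tree = read_taxdump(nodes, names)
        assert len(tree) == 3
        assert tree.root_taxid == 1
        assert tree.name_of(2) == "Ordo"

    def test_scientific_name_wins_over_synonym(self, tmp_path):
        nodes, names = _write_dump(
            tmp_path,
            ["1\t|\t1\t|\tno rank"],
            ["1\t|\talias\t|\t\t|\tsynonym",
             "1\t|\tproper\t|\t\t|\tscientific name"],
        )
        assert read_taxdump(nodes, names).name_of(1) == "proper"

    def test_first_name_used_without_scientific(self, tmp_path):
        nodes, names = _write_dump(
            tmp_path,
            ["1\t|\t1\t|\tno rank"],
            ["1\t|\tfirst\t|\t\t|\tsynonym",
             "1\t|\tsecond\t|\t\t|\tequivalent name"],
        )
        assert read_taxdump(nodes, names).name_of(1) == "first"

    def test_orphan_parent_is_structural_error(self, tmp_path):
        nodes, names = _write_dump(
            tmp_path,
            ["1\t|\t1\t|\tno rank", "5\t|\t99\t|\torder"],
            ["1\t|\troot\t|\t\t|\tscientific name"],
        )
        with pytest.raises(StructuralError, match=r"\[5\]"):
            read_taxdump(nodes, names)

    def test_round_trip(self, tmp_path, mini_tree):
        nodes = tmp_path / "nodes.dmp"
        names = tmp_path / "names.dmp"
        write_taxdump(mini_tree, nodes, names)
        tree2 = read_taxdump(nodes, names)
        assert tree2.nodes == mini_tree.nodes
        assert tree2.root_taxid == mini_tree.root_taxid


# --- TAGC TSV --------------------------------------------------------------

class TestTagcTsv:
    def test_header_grammar(self, tmp_path, toy_table):
        path = tmp_path / "t.tsv"
        write_tagc_tsv(toy_table, path)
        header = path.read_text().splitlines()[0]
        assert header == "seqid\tlength\tgc\tcov_lib1\tcov_total\ttaxlevel_order"

    def test_single_contig_two_libs_one_rank_header(self, tmp_path):
        from conftest import make_table

        table = make_table(
            [("c1", 10, 0.5, (1.0, 2.0), ("Ordo",))],
            libraries=("lib1", "lib2"), ranks=("order",),
        )
        path = tmp_path / "t.tsv"
        write_tagc_tsv(table, path)
        assert path.read_text().splitlines()[0] == \
            "seqid\tlength\tgc\tcov_lib1\tcov_lib2\ttaxlevel_order"

    def test_round_trip(self, tmp_path, toy_table):
        path = tmp_path / "t.tsv"
        write_tagc_tsv(toy_table, path)
        table2 = read_tagc_tsv(path)
        assert table2.library_labels == toy_table.library_labels
        assert table2.rank_labels == toy_table.rank_labels
        assert [r.seqid for r in table2.rows] == [r.seqid for r in toy_table.rows]

    def test_double_cycle_idempotent(self, tmp_path, toy_table):
        p1, p2 = tmp_path / "t1.tsv", tmp_path / "t2.tsv"
        write_tagc_tsv(toy_table, p1)
        write_tagc_tsv(read_tagc_tsv(p1), p2)
        assert p1.read_text() == p2.read_text()

    def test_precision(self, tmp_path, toy_table):
        path = tmp_path / "t.tsv"
        write_tagc_tsv(toy_table, path)
        first_row = path.read_text().splitlines()[1].split("\t")
        assert first_row[2] == "0.4000"  # gc: 4 decimals
        assert first_row[3] == "100.000"  # coverage: 3 decimals

    def test_unknown_column_is_error(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("seqid\tlength\tgc\tbogus\nc1\t10\t0.5\tx\n")
        with pytest.raises(FormatError, match="bogus"):
            read_tagc_tsv(path)

    def test_cov_after_taxlevel_is_error(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("seqid\tlength\tgc\ttaxlevel_order\tcov_lib1\n")
        with pytest.raises(FormatError, match="cov_lib1"):
            read_tagc_tsv(path)


# --- FASTQ -----------------------------------------------------------------

class TestFastq:
    def test_pair_iteration(self, tmp_path):
        p1, p2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
        p1.write_text("@r1/1\nACGT\n+\nIIII\n")
        p2.write_text("@r1/2\nTTTT\n+\nIIII\n")
        pairs = list(read_fastq_pairs(p1, p2))
        assert len(pairs) == 1
        assert pairs[0][0][1] == "ACGT"

    def test_normalization(self):
        assert normalize_read_id("r1/1") == "r1"
        assert normalize_read_id("r1/2") == "r1"
        assert normalize_read_id("r1 comment/2") == "r1"
        assert normalize_read_id("r1") == "r1"

    def test_suffix_and_bare_id_compare_equal(self, tmp_path):
        p1, p2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
        p1.write_text("@read7/1\nAC\n+\nII\n")
        p2.write_text("@read7\nGT\n+\nII\n")
        assert len(list(read_fastq_pairs(p1, p2))) == 1

    def test_desynchronized_pairs_error(self, tmp_path):
        p1, p2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
        p1.write_text("@a/1\nAC\n+\nII\n@b/1\nAC\n+\nII\n")
        p2.write_text("@a/2\nGT\n+\nII\n@c/2\nGT\n+\nII\n")
        with pytest.raises(FormatError, match="record 1"):
            list(read_fastq_pairs(p1, p2))

    def test_truncated_record_error(self, tmp_path):
        path = tmp_path / "r.fq"
        path.write_text("@a\nACGT\n+\n")
        with pytest.raises(FormatError):
            list(read_fastq(path))

    def test_write_preserves_order(self, tmp_path):
        records = [("a/1", "AC", "II"), ("b/1", "GT", "JJ")]
        path = tmp_path / "o.fq"
        write_fastq(records, path)
        assert list(read_fastq(path)) == records
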