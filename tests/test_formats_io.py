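"""Format boundary: FASTA, BLAST tabular, taxonomy dump, metadata TSVs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from forefield import formats_io as fio
from forefield.taxonomy import TaxonomyTree

from .conftest import random_tree


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">c1\nACGT\n")
        recs = list(fio.read_fasta(p))
        assert len(recs) == 1
        assert recs[0].contig_id == "c1"
        assert recs[0].length == 4

    def test_min_length_filter_keeps_only_long_contigs(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">long\n" + "A" * 300 + "\n>short\n" + "C" * 299 + "\n")
        recs = list(fio.read_fasta(p, min_length=300))
        assert [r.contig_id for r in recs] == ["long"]

    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        recs = [
            fio.ContigRecord(f"c{i}", 50, "".join(rng.choice(list("ACGTN"), 50)))
            for i in range(5)
        ]
        p = tmp_path / "rt.fasta"
        fio.write_fasta(p, recs)
        back = list(fio.read_fasta(p))
        assert [(r.contig_id, r.sequence) for r in back] == [
            (r.contig_id, r.sequence) for r in recs
        ]

    def test_illegal_character_raises(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">c1\nACXT\n")
        with pytest.raises(fio.FormatError):
            list(fio.read_fasta(p))

    def test_empty_file_empty_stream(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        assert list(fio.read_fasta(p)) == []


# ---------------------------------------------------------------------------
# Coordinate convention
# ---------------------------------------------------------------------------

class TestCoordinates:
    @pytest.mark.parametrize(
        "qs,qe,expected",
        [
            (101, 400, (100, 400, "+")),
            (400, 101, (100, 400, "-")),
            (1, 1_000, (0, 1000, "+")),
        ],
    )
    def test_one_based_inclusive_to_half_open(self, qs, qe, expected):
        assert fio.to_half_open(qs, qe) == expected

    @given(
        st.integers(min_value=1, max_value=10**6),
        st.integers(min_value=1, max_value=10**6),
    )
    @settings(max_examples=200, deadline=None)
    def test_conversion_round_trips(self, a, b):
        if a == b:
            with pytest.raises(ValueError):
                fio.to_half_open(a, b)
            return
        start, end, strand = fio.to_half_open(a, b)
        assert 0 <= start < end
        assert fio.to_one_based(start, end, strand) == (a, b)


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

def _row(qseqid="c1", sseqid="accA", pident=75.0, qstart=101, qend=400,
         evalue=1e-30, bitscore=150.0, title=None):
    fields = [qseqid, sseqid, pident, 300, 10, 1, qstart, qend, 1, 100, evalue, bitscore]
    if title is not None:
        fields.append(title)
    return "\t".join(str(x) for x in fields)


class TestReadAlignments:
    ACC = {"accA": 6, "accB": 7}

    def test_plus_strand_normalization(self, tmp_path):
        p = tmp_path / "aln.tsv"
        p.write_text(_row(qstart=101, qend=400) + "\n")
        res = fio.read_alignments(p, self.ACC)
        (h,) = res.hits
        assert (h.q_start, h.q_end, h.strand) == (100, 400, "+")
        assert h.subject_taxid == 6

    def test_minus_strand_normalization(self, tmp_path):
        p = tmp_path / "aln.tsv"
        p.write_text(_row(qstart=400, qend=101) + "\n")
        (h,) = fio.read_alignments(p, self.ACC).hits
        assert (h.q_start, h.q_end, h.strand) == (100, 400, "-")

    def test_identity_filter_strict_at_50(self, tmp_path):
        p = tmp_path / "aln.tsv"
        p.write_text(_row(pident=49.9) + "\n" + _row(pident=50.0) + "\n")
        res = fio.read_alignments(p, self.ACC, min_identity=50.0)
        assert len(res.hits) == 1
        assert res.n_identity_filtered == 1

    def test_unresolved_accession_kept_without_taxid(self, tmp_path):
        p = tmp_path / "aln.tsv"
        p.write_text(_row(sseqid="unknownAcc") + "\n")
        res = fio.read_alignments(p, self.ACC)
        assert res.n_unresolved_acc == 1
        assert res.hits[0].subject_taxid is None  # retained for gene calling

    def test_subject_title_column_supplies_gene_label(self, tmp_path):
        p = tmp_path / "aln.tsv"
        p.write_text(_row(title="nitrogenase nifH") + "\n")
        (h,) = fio.read_alignments(p, self.ACC).hits
        assert h.gene_label == "nitrogenase nifH"

    def test_non_numeric_field_raises(self, tmp_path):
        p = tmp_path / "aln.tsv"
        p.write_text(_row().replace("150.0", "xx") + "\n")
        with pytest.raises(fio.FormatError):
            fio.read_alignments(p, self.ACC)

    def test_hit_beyond_contig_length_raises(self, tmp_path):
        p = tmp_path / "aln.tsv"
        p.write_text(_row(qend=400) + "\n")
        with pytest.raises(fio.FormatError):
            fio.read_alignments(p, self.ACC, contig_lengths={"c1": 300})


# ---------------------------------------------------------------------------
# Taxonomy dump
# ---------------------------------------------------------------------------

class TestTaxonomyDump:
    def test_three_node_chain(self, tmp_path):
        nodes = tmp_path / "nodes.dmp"
        names = tmp_path / "names.dmp"
        nodes.write_text(
            "1\t|\t1\t|\tno rank\t|\n2\t|\t1\t|\tphylum\t|\n3\t|\t2\t|\tgenus\t|\n"
        )
        names.write_text(
            "1\t|\troot\t|\t\t|\tscientific name\t|\n"
            "2\t|\tP\t|\t\t|\tscientific name\t|\n"
            "3\t|\tG\t|\t\t|\tscientific name\t|\n"
        )
        tree = fio.read_taxonomy_dump(nodes, names)
        assert len(tree) == 3
        assert tree.parent(3) == 2
        assert tree.name(3) == "G"

    def test_cycle_raises(self, tmp_path):
        nodes = tmp_path / "nodes.dmp"
        names = tmp_path / "names.dmp"
        nodes.write_text(
            "1\t|\t1\t|\tno rank\t|\n2\t|\t3\t|\tphylum\t|\n3\t|\t2\t|\tgenus\t|\n"
        )
        names.write_text("1\t|\troot\t|\t\t|\tscientific name\t|\n")
        with pytest.raises(ValueError, match="cycle"):
            fio.read_taxonomy_dump(nodes, names)

    def test_orphan_raises_listing_offender(self):
        with pytest.raises(ValueError, match=r"orphan.*\[5\]"):
            TaxonomyTree.from_edges([(1, 1, "no rank"), (5, 99, "genus")])

    def test_duplicate_taxid_raises(self):
        with pytest.raises(ValueError, match="duplicate"):
            TaxonomyTree.from_edges([(1, 1, "no rank"), (2, 1, "phylum"), (2, 1, "genus")])

    def test_thousand_node_round_trip_preserves_parent_map(self, tmp_path):
        tree = random_tree(np.random.default_rng(42), 1000)
        nodes = tmp_path / "nodes.dmp"
        names = tmp_path / "names.dmp"
        fio.write_taxonomy_dump(tree, nodes, names)
        back = fio.read_taxonomy_dump(nodes, names)
        assert {t: n.parent for t, n in back.nodes.items()} == {
            t: n.parent for t, n in tree.nodes.items()
        }
        assert {t: n.rank for t, n in back.nodes.items()} == {
            t: n.rank for t, n in tree.nodes.items()
        }


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

HEADER = "sample_id\tforefield\tsubstrate\tdistance_m\ttn_mg_g\ttoc_mg_g\n"


class TestSampleMetadata:
    def test_valid_row(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(HEADER + "s1\tSV\tsoil\t200\t0.5\t3.0\n")
        (s,) = fio.read_sample_metadata(p)
        assert s.forefield == "SV"
        assert s.distance_m == 200

    def test_unknown_forefield_raises(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(HEADER + "s1\tXX\tsoil\t200\t0.5\t3.0\n")
        with pytest.raises(fio.FormatError, match="forefield"):
            fio.read_sample_metadata(p)

    def test_duplicate_sample_raises(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(HEADER + "s1\tG\tsoil\t10\t0.1\t0.2\ns1\tG\tsoil\t20\t0.1\t0.2\n")
        with pytest.raises(fio.FormatError, match="duplicate"):
            fio.read_sample_metadata(p)

    def test_negative_value_raises(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(HEADER + "s1\tG\tsoil\t-5\t0.1\t0.2\n")
        with pytest.raises(fio.FormatError, match="negative"):
            fio.read_sample_metadata(p)

    def test_sixty_five_row_study_parses_fully(self, tmp_path):
        rows = [
            f"s{i}\t{['G', 'SV', 'SW'][i % 3]}\tsoil\t{10 * i}\t0.5\t1.5" for i in range(65)
        ]
        p = tmp_path / "m.tsv"
        p.write_text(HEADER + "\n".join(rows) + "\n")
        assert len(fio.read_sample_metadata(p)) == 65

    def test_round_trip(self, tmp_path):
        samples = [
            fio.SampleMeta("a", "G", "ice", 0.0, 0.05, 0.1),
            fio.SampleMeta("b", "SW", "soil", 120.0, 0.4, 1.2),
        ]
        p = tmp_path / "m.tsv"
        fio.write_sample_metadata(p, samples)
        assert fio.read_sample_metadata(p) == samples


# ---------------------------------------------------------------------------
# Small maps
# ---------------------------------------------------------------------------

class TestMaps:
    def test_accession_map_round_trip(self, tmp_path):
        p = tmp_path / "acc.tsv"
        fio.write_accession_map(p, {"a": 5, "b": 7})
        assert fio.read_accession_map(p) == {"a": 5, "b": 7}

    def test_gene_go_map_validates_go_pattern(self, tmp_path):
        p = tmp_path / "go.tsv"
        p.write_text("geneX\tGO:12345\n")  # 5 digits, malformed
        with pytest.raises(fio.FormatError, match="GO"):
            fio.read_gene_go_map(p)

    def test_gene_go_map_round_trip(self, tmp_path):
        m = fio.GeneToGoMap(gene_to_go={"geneX": {"GO:0000001", "GO:0000002"}, "geneY": set()})
        p = tmp_path / "go.tsv"
        fio.write_gene_go_map(p, m)
        back = fio.read_gene_go_map(p)
        assert back.gene_to_go == m.gene_to_go
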