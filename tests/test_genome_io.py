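"""Table readers/writers: rank assignment, dialects, round-trips."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opxscreen import genome_io
from opxscreen.detect import OpxRecord
from opxscreen.genome_io import (
    DomainHit,
    GeneRecord,
    GeneTable,
    ProteinRecord,
    SecondaryStructure,
    Thresholds,
    read_classification,
    read_domain_hits,
    read_gene_table,
    write_classification,
)


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")


GENE_HEADER = "genome_id\tcontig_id\tgene_id\tstart\tend\tstrand\tprotein_id"


class TestGeneTable:
    def test_unsorted_input_is_sorted_then_ranked(self, tmp_path):
        p = tmp_path / "genes.tsv"
        write_lines(p, [
            GENE_HEADER,
            "G\tc\tg1\t10\t40\t+\tp1",
            "G\tc\tg2\t200\t240\t+\tp2",
            "G\tc\tg3\t90\t140\t-\tp3",
        ])
        table = read_gene_table(p)
        ranks = {g.gene_id: g.rank for g in table.records}
        assert ranks == {"g1": 0, "g3": 1, "g2": 2}

    def test_empty_file_gives_empty_table(self, tmp_path):
        p = tmp_path / "genes.tsv"
        write_lines(p, [GENE_HEADER])
        assert len(read_gene_table(p)) == 0

    def test_ranks_restart_per_contig(self, tmp_path):
        p = tmp_path / "genes.tsv"
        write_lines(p, [
            GENE_HEADER,
            "G\tc1\ta\t10\t40\t+\tp1",
            "G\tc1\tb\t50\t90\t+\tp2",
            "G\tc2\tc\t10\t40\t+\tp3",
            "G\tc2\td\t50\t90\t+\tp4",
        ])
        table = read_gene_table(p)
        assert [g.rank for g in table.contig_genes("G", "c1")] == [0, 1]
        assert [g.rank for g in table.contig_genes("G", "c2")] == [0, 1]

    def test_duplicate_gene_id_is_hard_error(self, tmp_path):
        p = tmp_path / "genes.tsv"
        write_lines(p, [
            GENE_HEADER,
            "G\tc\tg1\t10\t40\t+\tp1",
            "G\tc\tg1\t50\t90\t+\tp2",
        ])
        with pytest.raises(ValueError, match="duplicate gene_id"):
            read_gene_table(p)

    def test_gff3_dialect(self, tmp_path):
        p = tmp_path / "genome.gff3"
        write_lines(p, [
            "##gff-version 3",
            "c1\tsrc\tCDS\t10\t40\t.\t+\t0\tID=g1;protein_id=p1",
            "c1\tsrc\tgene\t10\t40\t.\t+\t.\tID=skipme",
            "c1\tsrc\tCDS\t50\t90\t.\t-\t0\tID=g2;protein_id=p2",
        ])
        table = read_gene_table(p, dialect="gff3")
        assert [g.gene_id for g in table.contig_genes("genome", "c1")] == ["g1", "g2"]
        assert table.gene("g2").strand == "-"

    def test_round_trip(self, tmp_path, contig12):
        path = tmp_path / "genes.tsv"
        genome_io.write_gene_table(contig12, path)
        back = read_gene_table(path)
        assert back.records == contig12.records


class TestDomainHits:
    def test_tsv_row_retained_and_comments_skipped(self, tmp_path):
        p = tmp_path / "hits.tsv"
        write_lines(p, [
            "# a comment",
            "protein_id\tdomain_acc\tscore\tmeets_threshold",
            "P1\tPF02563\t55.2\ttrue",
            "P2\tPF00005\t\tfalse",
        ])
        hits = read_domain_hits(p)
        assert hits[0] == DomainHit("P1", "PF02563", 55.2, True)
        assert hits[1].score is None and not hits[1].meets_threshold

    def test_empty_accession_is_error(self, tmp_path):
        p = tmp_path / "hits.tsv"
        write_lines(p, ["protein_id\tdomain_acc", "P1\t"])
        with pytest.raises(ValueError, match="empty accession"):
            read_domain_hits(p)

    def test_hmmer_tblout_dialect(self, tmp_path):
        p = tmp_path / "hits.tbl"
        fields = ["P9", "-", "Poly_export", "PF02563.19", "1.2e-30", "101.5"] + ["0"] * 12
        write_lines(p, [
            "#                                    --- full sequence ----",
            " ".join(fields),
        ])
        hits = read_domain_hits(p)
        assert hits == [DomainHit("P9", "PF02563", 101.5, True)]

    def test_meets_threshold_defaults_true(self, tmp_path):
        p = tmp_path / "hits.tsv"
        write_lines(p, ["protein_id\tdomain_acc", "P1\tPF02563"])
        assert read_domain_hits(p)[0].meets_threshold

    def test_unknown_dialect_names_offending_line(self, tmp_path):
        p = tmp_path / "hits.txt"
        write_lines(p, ["just some words"])
        with pytest.raises(ValueError, match="just some words"):
            read_domain_hits(p)


class TestValidation:
    def test_start_after_end_rejected(self):
        with pytest.raises(ValueError):
            GeneRecord("g", "G", "c", 100, 10, "+", 0, "p")

    def test_sequence_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ProteinRecord("p", 5, sequence="MKL")

    def test_ss_alphabet_closed(self):
        with pytest.raises(ValueError):
            SecondaryStructure("p", "HHQQ")

    def test_thresholds_positive(self):
        with pytest.raises(ValueError):
            Thresholds(window_genes=0)
        with pytest.raises(ValueError):
            Thresholds(cluster_identity=1.5)

    def test_noncontiguous_ranks_rejected(self):
        genes = [
            GeneRecord("a", "G", "c", 1, 10, "+", 0, "p1"),
            GeneRecord("b", "G", "c", 20, 30, "+", 2, "p2"),
        ]
        with pytest.raises(ValueError, match="contiguous"):
            GeneTable(genes)


opt_bool = st.one_of(st.none(), st.booleans())


@st.composite
def opx_records(draw):
    i = draw(st.integers(0, 10 ** 6))
    coupled = draw(opt_bool)
    return OpxRecord(
        protein_id=f"P{i}",
        gene_id=f"g{i}",
        genome_id="G0",
        length=draw(st.integers(1, 2000)),
        context_ok=draw(st.booleans()),
        pathway=draw(st.sampled_from(["wzx_wzy", "abc", "pcp_unassigned", "none"])),
        pcp2_context=draw(st.booleans()),
        ambiguous_pathway=draw(st.booleans()),
        short=draw(st.booleans()),
        cterm_helix=draw(opt_bool),
        coupled=coupled,
        partner_id=draw(st.one_of(st.none(), st.just("Pp"))) if coupled else None,
        category=draw(st.one_of(st.none(), st.just("short_coupled_nohelix"))),
        cluster_rep=draw(st.one_of(st.none(), st.just(f"P{i}"))),
        is_representative=draw(st.booleans()),
    )


class TestClassificationRoundTrip:
    def test_zero_records_header_only(self, tmp_path):
        path = tmp_path / "cls.tsv"
        write_classification([], path)
        assert len(path.read_text().splitlines()) == 1
        assert read_classification(path) == []

    def test_two_records_three_lines(self, tmp_path):
        recs = [
            OpxRecord("P1", "g1", "G0", 200),
            OpxRecord("P2", "g2", "G0", 300, coupled=True, partner_id="P9"),
        ]
        path = tmp_path / "cls.tsv"
        write_classification(recs, path)
        assert len(path.read_text().splitlines()) == 3
        assert read_classification(path) == recs

    @settings(max_examples=50, deadline=None)
    @given(st.lists(opx_records(), max_size=8))
    def test_round_trip_lossless(self, tmp_path_factory, records):
        path = tmp_path_factory.mktemp("rt") / "cls.tsv"
        write_classification(records, path)
        assert read_classification(path) == records
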