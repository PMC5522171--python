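"""Domain types, symbol normalization and TSV round trips."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herbnet import io as hio
from herbnet.types import (
    ChemicalProteinLink,
    GeneRecord,
    HerbRecord,
    InteractionNetwork,
    MalformedRecordError,
    PathwayAnnotation,
    SLPairRecord,
    TableParseError,
    normalize_symbol,
)


@pytest.mark.parametrize(
    "raw,expected",
    [(" tp53 ", "TP53"), ("BRCA1", "BRCA1"), ("Chek1", "CHEK1")],
)
def test_normalize_symbol(raw, expected):
    assert normalize_symbol(raw) == expected


@pytest.mark.parametrize("raw", ["", "   ", "\t\n"])
def test_normalize_symbol_rejects_blank(raw):
    with pytest.raises(MalformedRecordError):
        normalize_symbol(raw)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.text(min_size=1).filter(lambda s: s.strip()))
def test_normalize_symbol_idempotent(raw):
    once = normalize_symbol(raw)
    assert normalize_symbol(once) == once


class TestNetwork:
    def test_unordered_deduplication(self):
        net = InteractionNetwork([("A", "B"), ("B", "A"), ("A", "C")])
        assert len(net) == 2

    def test_self_loops_dropped(self):
        net = InteractionNetwork([("A", "A"), ("A", "B")])
        assert net.edges == frozenset({("A", "B")})

    def test_join_on_normalized_symbols(self):
        # mixed-case edge file joins identically to a pre-normalized one
        messy = InteractionNetwork([(" tp53", "Brca1"), ("BRCA1", "chek1 ")])
        clean = InteractionNetwork([("TP53", "BRCA1"), ("BRCA1", "CHEK1")])
        assert messy == clean


class TestSLPair:
    def test_canonical_order(self):
        pair = SLPairRecord("TP53", "BRCA1", 0.8)
        assert (pair.gene_a, pair.gene_b) == ("BRCA1", "TP53")

    def test_identical_genes_rejected(self):
        with pytest.raises(MalformedRecordError):
            SLPairRecord("TP53", "tp53", 0.8)

    @pytest.mark.parametrize("conf", [-0.1, 1.5])
    def test_confidence_range(self, conf):
        with pytest.raises(MalformedRecordError):
            SLPairRecord("A", "B", conf)


def test_herb_category_range():
    with pytest.raises(MalformedRecordError):
        HerbRecord("h1", "X", "x", category=9)


def test_deg_table_counts(tmp_path):
    """A table of 306 down + 290 up rows reads back as 596 records."""
    records = [GeneRecord(f"DN{i}", "down") for i in range(306)]
    records += [GeneRecord(f"UP{i}", "up") for i in range(290)]
    path = tmp_path / "degs.tsv"
    hio.write_deg_table(records, path)
    back = hio.read_deg_table(path)
    assert len(back) == 596
    assert sum(r.regulation == "down" for r in back) == 306
    assert sum(r.regulation == "up" for r in back) == 290


def test_ppi_duplicate_edge_file(tmp_path):
    path = tmp_path / "ppi.tsv"
    path.write_text("protein_a\tprotein_b\nA\tB\nB\tA\nA\tC\n")
    net = hio.read_ppi_edges(path)
    assert len(net) == 2


def test_ppi_optional_confidence_column(tmp_path):
    path = tmp_path / "ppi.tsv"
    path.write_text(
        "protein_a\tprotein_b\tconfidence\nA\tB\t0.9\nA\tC\t0.2\n"
    )
    assert len(hio.read_ppi_edges(path)) == 2          # filtering off by default
    assert hio.read_ppi_edges(path, min_conf=0.5).edges == frozenset({("A", "B")})


def test_link_confidence_out_of_range_names_line(tmp_path):
    path = tmp_path / "links.tsv"
    path.write_text(
        "compound_id\tcompound_name\tprotein\tconfidence\n"
        "c1\tcompound one\tTP53\t0.95\n"
        "c2\tcompound two\tBRCA1\t1.2\n"
    )
    with pytest.raises(TableParseError) as exc:
        hio.read_chemical_links(path)
    assert exc.value.line == 3


def test_link_duplicates_keep_max_confidence(tmp_path):
    path = tmp_path / "links.tsv"
    path.write_text(
        "compound_id\tcompound_name\tprotein\tconfidence\n"
        "c1\tx\tTP53\t0.4\n"
        "c1\tx\tTP53\t0.95\n"
        "c1\tx\tTP53\t0.7\n"
    )
    links = hio.read_chemical_links(path)
    assert len(links) == 1 and links[0].confidence == 0.95


def test_link_scale_1000(tmp_path):
    path = tmp_path / "links.tsv"
    path.write_text("compound_id\tcompound_name\tprotein\tconfidence\nc1\tx\tTP53\t900\n")
    links = hio.read_chemical_links(path, scale_1000=True)
    assert links[0].confidence == pytest.approx(0.9)


def test_sl_duplicates_merge(tmp_path):
    path = tmp_path / "sl.tsv"
    path.write_text(
        "gene_a\tgene_b\tconfidence\tdiseases\n"
        "TP53\tBRCA1\t0.6\tAML\n"
        "BRCA1\tTP53\t0.8\tBRCA\n"
    )
    pairs = hio.read_sl_table(path)
    assert len(pairs) == 1
    assert pairs[0].confidence == 0.8
    assert pairs[0].diseases == frozenset({"AML", "BRCA"})


def test_unknown_column_rejected(tmp_path):
    path = tmp_path / "degs.tsv"
    path.write_text("symbol\tregulation\tis_key\tbogus\nTP53\tup\tfalse\tx\n")
    with pytest.raises(TableParseError):
        hio.read_deg_table(path)


def test_gmt_reader(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("pw1\tfirst set\tTP53\tBRCA1\npw2\tsecond\tCHEK1\n")
    sets = hio.read_gmt(path)
    assert {s.pathway_id: s.members for s in sets} == {
        "pw1": frozenset({"TP53", "BRCA1"}),
        "pw2": frozenset({"CHEK1"}),
    }


def test_round_trips(tmp_path):
    """write(read(x)) is the identity for every table dialect."""
    degs = [GeneRecord("TP53", "down", True), GeneRecord("BRCA1", "up")]
    net = InteractionNetwork([("TP53", "BRCA1"), ("BRCA1", "CHEK1")])
    links = [
        ChemicalProteinLink("c1", "caffeine", "TP53", 0.91),
        ChemicalProteinLink("c2", "zinc", "BRCA1", 0.5),
    ]
    herbs = [
        HerbRecord("h1", "Herba una", "Yi Cao", 3, frozenset({"c1", "c2"})),
        HerbRecord("h2", "Herba dua", "Er Cao", 2, frozenset({"c1"}), True, "toxic"),
    ]
    pairs = [SLPairRecord("TP53", "BRCA1", 0.82046875, frozenset({"AML"}))]
    pathways = [PathwayAnnotation("pw1", "some pathway", frozenset({"TP53"}))]

    hio.write_deg_table(degs, tmp_path / "d.tsv")
    assert set(hio.read_deg_table(tmp_path / "d.tsv")) == set(degs)
    hio.write_ppi_edges(net, tmp_path / "p.tsv")
    assert hio.read_ppi_edges(tmp_path / "p.tsv") == net
    hio.write_chemical_links(links, tmp_path / "l.tsv")
    assert set(hio.read_chemical_links(tmp_path / "l.tsv")) == set(links)
    hio.write_herb_table(herbs, tmp_path / "h.tsv", tmp_path / "hi.tsv")
    assert set(hio.read_herb_table(tmp_path / "h.tsv", tmp_path / "hi.tsv")) == set(herbs)
    hio.write_sl_table(pairs, tmp_path / "s.tsv")
    assert set(hio.read_sl_table(tmp_path / "s.tsv")) == set(pairs)
    hio.write_pathway_table(pathways, tmp_path / "pw.tsv")
    assert set(hio.read_pathway_table(tmp_path / "pw.tsv")) == set(pathways)
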