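"""I/O layer: identifier canonicalization, edge-table dialects, GMT, round trips."""

import pytest
from hypothesis import given, strategies as st

from nfkbkit.errors import EmptyInputError, MalformedIdentifierError, ParseError
from nfkbkit.interactome import InteractionNetwork
from nfkbkit.ppi_io import (
    InteractionRecord,
    canonical,
    normalize_id,
    read_edge_table,
    read_edges_and_isolated,
    read_gmt,
    read_protein_set,
    write_network,
    write_node_attributes,
)

from conftest import net_from_edges


class TestCanonicalization:
    def test_trims_and_uppercases(self):
        assert canonical(" tf65 ") == "TF65"

    def test_identity_on_canonical(self):
        assert canonical("TF65") == "TF65"

    @given(st.text(min_size=1).filter(lambda s: s.strip()))
    def test_idempotent(self, raw):
        once = canonical(raw)
        assert canonical(once) == once

    @pytest.mark.parametrize("bad", ["", "   ", "\t\n"])
    def test_blank_rejected(self, bad):
        with pytest.raises(MalformedIdentifierError):
            canonical(bad)

    def test_gene_name_lookup(self):
        pid = normalize_id("nfkb1", gene_names={"NFKB1": "NFKB1"})
        assert pid.accession == "NFKB1" and pid.gene_name == "NFKB1"
        assert normalize_id("NFKB1").gene_name is None


class TestEdgeTable:
    def test_symmetry_collapse_and_self_loop(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tB\nB\tA\nA\tA\n")
        records = read_edge_table(p, dialect="tsv-pairs")
        assert {r.pair for r in records} == {("A", "B"), ("A", "A")}

    def test_sif_multi_target(self, tmp_path):
        p = tmp_path / "net.sif"
        p.write_text("A pp B C\n")
        records = read_edge_table(p, dialect="sif")
        assert {r.pair for r in records} == {("A", "B"), ("A", "C")}

    def test_mitab_prefix_stripped_self_interaction(self, tmp_path):
        p = tmp_path / "ppi.mitab"
        p.write_text("uniprotkb:P19838\tuniprotkb:P19838\tignored\tcols\n")
        records = read_edge_table(p, dialect="mitab-subset")
        assert records == [InteractionRecord("P19838", "P19838", frozenset())]

    def test_sniffing(self, tmp_path):
        sif = tmp_path / "a"
        sif.write_text("A pp B\n")
        tsv = tmp_path / "b"
        tsv.write_text("A\tB\n")
        mitab = tmp_path / "c"
        mitab.write_text("uniprotkb:P1\tuniprotkb:P2\n")
        assert {r.pair for r in read_edge_table(sif)} == {("A", "B")}
        assert {r.pair for r in read_edge_table(tsv)} == {("A", "B")}
        assert {r.pair for r in read_edge_table(mitab)} == {("P1", "P2")}

    def test_sources_merge_on_duplicates(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tB\tbiogrid\nB\tA\tintact\n")
        (rec,) = read_edge_table(p, dialect="tsv-pairs")
        assert rec.sources == {"biogrid", "intact"}

    def test_wrong_column_count_names_line(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tB\nA\tB\tC\tD\n")
        with pytest.raises(ParseError, match="2"):
            read_edge_table(p, dialect="tsv-pairs")

    def test_empty_input_error(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("# only a comment\n")
        with pytest.raises(EmptyInputError):
            read_edge_table(p, dialect="tsv-pairs")

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_duplicated_lines_collapse(self, k, tmp_path):
        lines = ["A\tB", "B\tC", "C\tC"]
        orig, dup = tmp_path / "orig.tsv", tmp_path / "dup.tsv"
        orig.write_text("\n".join(lines) + "\n")
        dup.write_text("\n".join(line for line in lines for _ in range(k)) + "\n")
        assert read_edge_table(orig, "tsv-pairs") == read_edge_table(dup, "tsv-pairs")


class TestProteinSet:
    def test_duplicates_reported(self, tmp_path):
        p = tmp_path / "set.txt"
        p.write_text("A\na\nB\n")
        ps = read_protein_set(p, "S")
        assert ps.members == {"A", "B"}
        assert ps.duplicates_removed == 1

    def test_blank_file_rejected(self, tmp_path):
        p = tmp_path / "set.txt"
        p.write_text("\n\n   \n")
        with pytest.raises(EmptyInputError):
            read_protein_set(p, "S")


class TestGmt:
    def test_basic_parse(self, tmp_path):
        p = tmp_path / "p.gmt"
        p.write_text("P1\tdesc\tA\tB\tC\n")
        (pw,) = read_gmt(p)
        assert pw.pathway_id == "P1" and pw.size == 3

    def test_duplicate_member_counted_once(self, tmp_path):
        p = tmp_path / "p.gmt"
        p.write_text("P1\tdesc\tA\ta\tB\n")
        (pw,) = read_gmt(p)
        assert pw.size == 2

    def test_short_line_names_line_number(self, tmp_path):
        p = tmp_path / "p.gmt"
        p.write_text("P1\tdesc\tA\nP2\tno-members\n")
        with pytest.raises(ParseError, match=":2"):
            read_gmt(p)


class TestRoundTrip:
    @pytest.mark.parametrize("dialect", ["sif", "tsv-pairs"])
    def test_write_read_preserves_nodes_and_edges(self, tmp_path, dialect):
        net = net_from_edges(
            [("A", "B"), ("B", "C"), ("D", "D")], extra_nodes=["LONE"]
        )
        out = tmp_path / f"net.{dialect}"
        write_network(net, out, dialect=dialect)
        records, isolated = read_edges_and_isolated(out, dialect=dialect)
        back = InteractionNetwork.from_records("back", records, extra_nodes=isolated)
        assert back.nodes == net.nodes
        assert back.edge_pairs() == net.edge_pairs()

    @pytest.mark.parametrize("dialect", ["sif", "tsv-pairs"])
    def test_random_networks_round_trip(self, tmp_path, rng, dialect):
        from conftest import random_network

        for i in range(20):
            net = random_network(rng)
            out = tmp_path / f"n{i}.{dialect}"
            write_network(net, out, dialect=dialect)
            records, isolated = read_edges_and_isolated(out, dialect=dialect)
            back = InteractionNetwork.from_records("b", records, extra_nodes=isolated)
            assert back.nodes == net.nodes
            assert back.edge_pairs() == net.edge_pairs()

    def test_isolated_node_emitted_as_bare_sif_line(self, tmp_path):
        net = net_from_edges([("A", "B")], extra_nodes=["Z"])
        out = tmp_path / "net.sif"
        write_network(net, out, dialect="sif")
        assert out.read_text().splitlines() == ["A\tpp\tB", "Z"]

    def test_node_attribute_table_header(self, tmp_path):
        out = tmp_path / "attrs.tsv"
        write_node_attributes({"A": {"betweenness": 0.5}}, out)
        assert out.read_text().splitlines()[0] == "id\tbetweenness"
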