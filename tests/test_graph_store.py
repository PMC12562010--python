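"""Graph store: augmentation rules, PPI typing, masking, edge-list I/O."""

import pytest
from hypothesis import given, settings, strategies as st

from pathokg.errors import GraphError, ParseError, RangeError, VocabularyError
from pathokg.graph_store import (
    DISEASE_VARIANT,
    PROTEIN_GENE,
    VARIANT_GENE,
    EdgeRecord,
    HeteroGraph,
    NodeRef,
    attach_variants,
    bin_tissue_coexpression,
    classify_ppi_temporal,
    collapse_ppi_types,
    mask_edges,
    read_edge_list,
    split_protein_nodes,
    write_edge_list,
)
from pathokg.seq_context import VariantRecord


def _variant(gene="GENE1", label="pathogenic", diseases=(), pos=100):
    return VariantRecord(
        chrom="1", pos=pos, ref="A", alt="T", var_class="snv", gene=gene,
        clinical_label=label, diseases=list(diseases),
    )


class TestSplitProteinNodes:
    def test_rewires_by_edge_type_name(self, small_graph):
        out = split_protein_nodes(small_graph)
        # each protein spawned one gene node joined by a protein-gene edge
        assert len(out.nodes()) == len(small_graph.nodes()) + 2
        assert out.has_edge("P1", "P1:gene", PROTEIN_GENE)
        # PPI stays on the protein pair; gene-named edges moved to the gene node
        assert out.has_edge("P1", "P2", "Protein-Protein (transient PPI)")
        assert out.has_edge("PW1", "P1:gene", "Pathway-Gene (interacts with)")
        assert out.has_edge("D1", "P1:gene", "Disease-Gene (associated with)")
        assert not out.has_edge("PW1", "P1", "Pathway-Gene (interacts with)")

    def test_empty_graph_identity(self):
        out = split_protein_nodes(HeteroGraph())
        assert out.nodes() == [] and out.edges() == []

    def test_edgeless_proteins_counting(self):
        g = HeteroGraph()
        for i in range(5):
            g.add_node(NodeRef(f"P{i}", "protein", f"G{i}"))
        out = split_protein_nodes(g)
        assert len(out.nodes("gene")) == 5
        assert len(out.edges(PROTEIN_GENE)) == 5

    def test_no_gene_edge_touches_protein_after_split(self, small_graph):
        out = split_protein_nodes(small_graph)
        proteins = {n.node_id for n in out.nodes("protein")}
        for e in out.edges():
            if "Gene" in e.edge_type and e.edge_type != PROTEIN_GENE:
                assert e.src not in proteins and e.dst not in proteins


class TestAttachVariants:
    @pytest.fixture()
    def gene_graph(self):
        g = HeteroGraph()
        g.add_node(NodeRef("G1", "gene", "GENE1"))
        g.add_node(NodeRef("D1", "disease", "Fabry disease"))
        g.add_edge("D1", "G1", "Disease-Gene (associated with)")
        return g

    def test_pathogenic_creates_missing_disease(self, gene_graph):
        v = _variant(diseases=["Fabry disease", "Niemann-Pick disease"])
        out = attach_variants(gene_graph, [v])
        assert len(out.nodes("variant")) == 1
        assert len(out.nodes("disease")) == 2  # one created
        assert len(out.edges(VARIANT_GENE)) == 1
        assert len(out.edges(DISEASE_VARIANT)) == 2

    def test_benign_gets_no_disease_edge(self, gene_graph):
        out = attach_variants(gene_graph, [_variant(label="benign")])
        assert len(out.nodes("variant")) == 1
        assert len(out.edges(VARIANT_GENE)) == 1
        assert out.edges(DISEASE_VARIANT) == []

    def test_empty_list_identity(self, gene_graph):
        out = attach_variants(gene_graph, [])
        assert len(out.nodes()) == len(gene_graph.nodes())
        assert len(out.edges()) == len(gene_graph.edges())

    def test_idempotent(self, gene_graph):
        vs = [_variant(diseases=["Fabry disease"]), _variant(label="benign", pos=200)]
        once = attach_variants(gene_graph, vs)
        twice = attach_variants(once, vs)
        assert {e.key() for e in once.edges()} == {e.key() for e in twice.edges()}
        assert len(once.nodes()) == len(twice.nodes())

    def test_unknown_gene_rejected(self, gene_graph):
        with pytest.raises(GraphError, match="NOSUCH"):
            attach_variants(gene_graph, [_variant(gene="NOSUCH")])

    def test_disease_matching_folds_case_and_whitespace(self, gene_graph):
        out = attach_variants(gene_graph, [_variant(diseases=["  FABRY   Disease "])])
        assert len(out.nodes("disease")) == 1  # matched the existing node


class TestPPITemporal:
    @pytest.mark.parametrize(
        "timecourse,expected",
        [
            ([], "unlabeled"),
            ([0.05, 0.02, 0.5], "transient"),
            ([0.05, 0.5], "permanent"),  # exact tie -> permanent
            ([0.2, 0.3, 0.4], "permanent"),
            ([0.09], "transient"),
            ([0.1], "permanent"),  # threshold is strict less-than
        ],
    )
    def test_majority_vote(self, timecourse, expected):
        assert classify_ppi_temporal(timecourse) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(RangeError):
            classify_ppi_temporal([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=-1, max_value=1), max_size=9), st.randoms())
    def test_permutation_invariant(self, values, rnd):
        label = classify_ppi_temporal(values)
        shuffled = list(values)
        rnd.shuffle(shuffled)
        assert classify_ppi_temporal(shuffled) == label


class TestTissueCoexpression:
    @pytest.mark.parametrize(
        "r,expected",
        [
            (0.0, "none"),
            (0.95, "high_positive"),
            (-0.5, "negative"),
            (-0.1, "negative"),
            (0.1, "low_positive"),
            (0.4, "medium_positive"),
            (0.7, "high_positive"),
        ],
    )
    def test_default_bins(self, r, expected):
        assert bin_tissue_coexpression(r) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(RangeError):
            bin_tissue_coexpression(1.01)


class TestMasking:
    @pytest.fixture()
    def graph_with_dv_edges(self):
        g = HeteroGraph()
        g.add_node(NodeRef("G1", "gene", "GENE1"))
        vs = [
            _variant(diseases=[f"disease {i}"], pos=100 + i) for i in range(5)
        ]
        return attach_variants(g, vs)

    def test_mask_drops_exactly_that_type(self, graph_with_dv_edges):
        g = graph_with_dv_edges
        full = g.adjacency()
        masked = mask_edges(g, DISEASE_VARIANT)
        assert len(full) - len(masked) == 5
        assert masked.edge_type_counts().get(DISEASE_VARIANT, 0) == 0

    def test_mask_absent_type_is_identity(self, graph_with_dv_edges):
        g = graph_with_dv_edges
        masked = mask_edges(g, "Drug-Protein (target)")
        assert len(masked) == len(g.adjacency())

    def test_mask_unmask_restores_view(self, graph_with_dv_edges):
        g = graph_with_dv_edges
        before = {e.key() for e in g.adjacency().edges}
        g.mask(DISEASE_VARIANT)
        g.unmask(DISEASE_VARIANT)
        assert {e.key() for e in g.adjacency().edges} == before

    def test_conservation(self, graph_with_dv_edges):
        g = graph_with_dv_edges
        masked = mask_edges(g, DISEASE_VARIANT)
        hidden = [e for e in g.edges() if e.edge_type == DISEASE_VARIANT]
        assert {e.key() for e in masked.edges} | {e.key() for e in hidden} == {
            e.key() for e in g.edges()
        }

    def test_unknown_type_rejected(self, graph_with_dv_edges):
        with pytest.raises(VocabularyError):
            mask_edges(graph_with_dv_edges, "Gene-Gene (made up)")

    def test_underlying_store_unmodified(self, graph_with_dv_edges):
        g = graph_with_dv_edges
        n_before = len(g.edges())
        mask_edges(g, DISEASE_VARIANT)
        assert len(g.edges()) == n_before


class TestCollapsePPI:
    def test_all_ppi_subtypes_merge(self, small_graph):
        small_graph.add_edge("P1", "P2", "Protein-Protein (high positive co-expression PPI)")
        out = collapse_ppi_types(small_graph)
        ppi = [e for e in out.edges() if e.edge_type.startswith("Protein-Protein")]
        assert {e.edge_type for e in ppi} == {"Protein-Protein (PPI)"}
        assert len(ppi) == 1  # duplicate same-type same-pair edges collapse


class TestEdgeListIO:
    def test_round_trip(self, tmp_path, small_graph):
        path = tmp_path / "edges.tsv"
        write_edge_list(small_graph, path)
        back = read_edge_list(path)
        assert {n.node_id for n in back.nodes()} == {n.node_id for n in small_graph.nodes()}
        assert {e.key() for e in back.edges()} == {e.key() for e in small_graph.edges()}
        assert back.edge_type_counts() == small_graph.edge_type_counts()

    def test_unknown_node_type_has_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "src_id\tsrc_type\tdst_id\tdst_type\tedge_type\n"
            "A\twidget\tB\tgene\tDisease-Gene (associated with)\n"
        )
        with pytest.raises(ParseError, match="line 2"):
            read_edge_list(path)

    def test_header_only_gives_empty_graph(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("src_id\tsrc_type\tdst_id\tdst_type\tedge_type\n")
        g = read_edge_list(path)
        assert g.nodes() == [] and g.edges() == []

    def test_completely_empty_file_rejected(self, tmp_path):
        path = tmp_path / "none.tsv"
        path.write_text("")
        with pytest.raises(ParseError):
            read_edge_list(path)

    def test_isolated_nodes_survive_round_trip(self, tmp_path):
        g = HeteroGraph()
        g.add_node(NodeRef("G1", "gene", "GENE1"))
        path = tmp_path / "iso.tsv"
        write_edge_list(g, path)
        back = read_edge_list(path)
        assert [n.node_id for n in back.nodes()] == ["G1"]


def test_duplicate_same_type_edges_collapse():
    g = HeteroGraph()
    g.add_node(NodeRef("P1", "protein", "A"))
    g.add_node(NodeRef("P2", "protein", "B"))
    g.add_edge("P1", "P2", "Protein-Protein (transient PPI)")
    g.add_edge("P2", "P1", "Protein-Protein (transient PPI)")  # same undirected edge
    g.add_edge("P1", "P2", "Protein-Protein (no co-expression PPI)")  # parallel, distinct type
    assert len(g.edges()) == 2


def test_edge_requires_known_endpoints_and_types():
    g = HeteroGraph()
    g.add_node(NodeRef("G1", "gene", "A"))
    g.add_node(NodeRef("D1", "disease", "d"))
    with pytest.raises(VocabularyError):
        g.add_edge("G1", "D1", "Gene-Disease (invented)")
    with pytest.raises(GraphError):
        g.add_edge("G1", "missing", "Disease-Gene (associated with)")
    with pytest.raises(GraphError):  # incompatible endpoint types
        g.add_edge("G1", "G1", "Drug-Drug (synergistic interaction)")
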