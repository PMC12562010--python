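"""Typed heterogeneous knowledge-graph store and graph-augmentation rules.

The graph follows the PrimeKG-style schema: twelve node types (gene, protein,
variant, disease, phenotype, drug, pathway, GO terms, exposure, anatomy) and a
closed vocabulary of typed undirected edges.  On top of the plain store this
module implements the augmentation steps used to prepare the graph for
variant-pathogenicity training:

* splitting each protein node into a (gene, protein) pair and rewiring its
  incident edges by the gene/protein token in the edge-type name;
* attaching variant nodes to their genes, and pathogenic variants to their
  associated diseases (creating disease nodes on demand);
* classifying protein-protein interactions as transient or permanent from
  time-course co-expression, and binning cross-tissue co-expression into
  five ordinal levels;
* masked adjacency views that hide label-bearing edge types (notably
  disease-variant edges) from message passing without mutating the store.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

from pathokg.errors import GraphError, ParseError, RangeError, VocabularyError

if TYPE_CHECKING:  # pragma: no cover
    from pathokg.seq_context import VariantRecord

NODE_TYPES = frozenset(
    {
        "gene",
        "protein",
        "variant",
        "disease",
        "phenotype",
        "drug",
        "pathway",
        "molecular_function",
        "biological_process",
        "cellular_component",
        "exposure",
        "anatomy",
    }
)

BASIC_NODE_TYPES = frozenset({"gene", "protein", "variant", "pathway", "disease"})

# Controlled edge-type vocabulary mapping each type to its unordered pair of
# compatible endpoint node types.
EDGE_VOCAB: dict[str, frozenset[str]] = {
    "Drug-Drug (synergistic interaction)": frozenset({"drug"}),
    "Anatomy-Gene (expression present)": frozenset({"anatomy", "gene"}),
    "Anatomy-Gene (expression absent)": frozenset({"anatomy", "gene"}),
    "Protein-Protein (transient PPI)": frozenset({"protein"}),
    "Protein-Protein (permanent PPI)": frozenset({"protein"}),
    "Protein-Protein (unlabeled PPI)": frozenset({"protein"}),
    "Protein-Protein (PPI)": frozenset({"protein"}),
    "Protein-Protein (negative co-expression PPI)": frozenset({"protein"}),
    "Protein-Protein (no co-expression PPI)": frozenset({"protein"}),
    "Protein-Protein (low positive co-expression PPI)": frozenset({"protein"}),
    "Protein-Protein (medium positive co-expression PPI)": frozenset({"protein"}),
    "Protein-Protein (high positive co-expression PPI)": frozenset({"protein"}),
    "Variant-Gene (associated with)": frozenset({"variant", "gene"}),
    "Disease-Variant (associated with)": frozenset({"disease", "variant"}),
    "Disease-Phenotype (phenotype present)": frozenset({"disease", "phenotype"}),
    "Disease-Phenotype (phenotype absent)": frozenset({"disease", "phenotype"}),
    "Bioprocess-Gene (interacts with)": frozenset({"biological_process", "gene"}),
    "Bioprocess-Bioprocess (parent-child)": frozenset({"biological_process"}),
    "Disease-Gene (associated with)": frozenset({"disease", "gene"}),
    "Cellular component-Gene (interacts with)": frozenset({"cellular_component", "gene"}),
    "Cellular component-Cellular component (parent-child)": frozenset({"cellular_component"}),
    "Disease-Disease (parent-child)": frozenset({"disease"}),
    "Molecular function-Gene (interacts with)": frozenset({"molecular_function", "gene"}),
    "Molecular function-Molecular function (parent-child)": frozenset({"molecular_function"}),
    "Drug-Effect/Phenotype (side effect)": frozenset({"drug", "phenotype"}),
    "Pathway-Gene (interacts with)": frozenset({"pathway", "gene"}),
    "Pathway-Pathway (parent-child)": frozenset({"pathway"}),
    "Phenotype-Phenotype (parent-child)": frozenset({"phenotype"}),
    "Phenotype-Gene (associated with)": frozenset({"phenotype", "gene"}),
    "Contraindication (contraindication)": frozenset({"drug", "disease"}),
    "Indication (indication)": frozenset({"drug", "disease"}),
    "Off-label use (off-label use)": frozenset({"drug", "disease"}),
    "Anatomy-Anatomy (parent-child)": frozenset({"anatomy"}),
    "Protein-Gene (associated with)": frozenset({"protein", "gene"}),
    "Drug-Protein (target)": frozenset({"drug", "protein"}),
    "Drug-Protein (enzyme)": frozenset({"drug", "protein"}),
    "Drug-Protein (transporter)": frozenset({"drug", "protein"}),
    "Drug-Protein (carrier)": frozenset({"drug", "protein"}),
    "Exposure-Exposure (parent-child)": frozenset({"exposure"}),
    "Exposure-Disease (linked to)": frozenset({"exposure", "disease"}),
    "Exposure-Bioprocess (interacts with)": frozenset({"exposure", "biological_process"}),
    "Exposure-Gene (interacts with)": frozenset({"exposure", "gene"}),
    "Exposure-Molecular function (interacts with)": frozenset({"exposure", "molecular_function"}),
    "Exposure-Cellular component (interacts with)": frozenset({"exposure", "cellular_component"}),
}

VARIANT_GENE = "Variant-Gene (associated with)"
DISEASE_VARIANT = "Disease-Variant (associated with)"
PROTEIN_GENE = "Protein-Gene (associated with)"
DISEASE_GENE = "Disease-Gene (associated with)"
PATHWAY_GENE = "Pathway-Gene (interacts with)"

PPI_TEMPORAL_EDGE = {
    "transient": "Protein-Protein (transient PPI)",
    "permanent": "Protein-Protein (permanent PPI)",
    "unlabeled": "Protein-Protein (unlabeled PPI)",
}
COEXPRESSION_EDGE = {
    "negative": "Protein-Protein (negative co-expression PPI)",
    "none": "Protein-Protein (no co-expression PPI)",
    "low_positive": "Protein-Protein (low positive co-expression PPI)",
    "medium_positive": "Protein-Protein (medium positive co-expression PPI)",
    "high_positive": "Protein-Protein (high positive co-expression PPI)",
}

#: all PPI subtypes, used by the option that collapses them into a single type
PPI_EDGE_TYPES = frozenset(t for t in EDGE_VOCAB if t.startswith("Protein-Protein"))

# transient-PPI threshold on per-experiment co-expression
TRANSIENT_THRESHOLD = 0.1

#: default bin edges for cross-tissue co-expression (implementation-chosen,
#: exposed so a study can override them)
DEFAULT_COEXPR_BINS = {"negative": -0.1, "none": 0.1, "low_positive": 0.4, "medium_positive": 0.7}


def _check_edge_type(edge_type: str) -> None:
    if edge_type not in EDGE_VOCAB:
        raise VocabularyError(f"unknown edge type: {edge_type!r}")


def normalize_disease_name(name: str) -> str:
    """Canonical key for matching disease names: trimmed and case-folded."""
    return " ".join(name.split()).casefold()


@dataclass(frozen=True)
class NodeRef:
    """A typed node; ``name`` is the display label used as text-embedding source."""

    node_id: str
    node_type: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.node_type not in NODE_TYPES:
            raise VocabularyError(f"unknown node type: {self.node_type!r}")
        if not self.name:
            object.__setattr__(self, "name", self.node_id)


@dataclass(frozen=True)
class EdgeRecord:
    """One undirected typed edge; (src, dst) order is not semantic."""

    src: str
    dst: str
    edge_type: str

    def key(self) -> tuple[str, str, str]:
        a, b = sorted((self.src, self.dst))
        return (a, b, self.edge_type)


@dataclass
class CoexpressionProfile:
    """Per-pair co-expression evidence: time-course values and a tissue-level r."""

    gene_a: str
    gene_b: str
    timecourse: list[float] = field(default_factory=list)
    tissue_r: float | None = None


class AdjacencyView:
    """Read-only view of a graph's edges with some edge types hidden.

    The view holds its own (node order, edge list) snapshot; mutating it does
    not touch the parent graph, and masked types are simply absent.
    """

    def __init__(self, graph: "HeteroGraph", masked_types: frozenset[str]):
        self.masked_types = masked_types
        self.node_ids: list[str] = sorted(graph._nodes)
        self.node_types: dict[str, str] = {i: graph._nodes[i].node_type for i in self.node_ids}
        self._index = {nid: k for k, nid in enumerate(self.node_ids)}
        self.edges: list[EdgeRecord] = [
            e for e in graph.edges() if e.edge_type not in masked_types
        ]

    def __len__(self) -> int:
        return len(self.edges)

    def edge_type_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.edges:
            counts[e.edge_type] = counts.get(e.edge_type, 0) + 1
        return counts

    def index_of(self, node_id: str) -> int:
        return self._index[node_id]

    def edge_index_pairs(self) -> list[tuple[int, int]]:
        """Undirected edges as index pairs under the canonical node order."""
        return [(self._index[e.src], self._index[e.dst]) for e in self.edges]


class HeteroGraph:
    """Undirected typed multigraph with maskable edge types.

    Parallel edges of *different* types between the same node pair are allowed
    (e.g. a temporal-PPI edge plus a co-expression-PPI edge); duplicate edges
    of the same type between the same pair collapse to one.
    """

    def __init__(self) -> None:
        self._nodes: dict[str, NodeRef] = {}
        self._edges: dict[tuple[str, str, str], EdgeRecord] = {}
        self.masked_types: set[str] = set()
        self._disease_name_index: dict[str, str] = {}

    # -- nodes ------------------------------------------------------------
    def add_node(self, node: NodeRef) -> None:
        existing = self._nodes.get(node.node_id)
        if existing is not None:
            if existing.node_type != node.node_type:
                raise GraphError(
                    f"node {node.node_id!r} already present with type "
                    f"{existing.node_type!r}, cannot re-add as {node.node_type!r}"
                )
            return
        self._nodes[node.node_id] = node
        if node.node_type == "disease":
            self._disease_name_index.setdefault(normalize_disease_name(node.name), node.node_id)

    def has_node(self, node_id: str) -> bool:
        return node_id in self._nodes

    def node(self, node_id: str) -> NodeRef:
        return self._nodes[node_id]

    def nodes(self, node_type: str | None = None) -> list[NodeRef]:
        out = list(self._nodes.values())
        if node_type is not None:
            out = [n for n in out if n.node_type == node_type]
        return out

    def node_ids(self) -> list[str]:
        return sorted(self._nodes)

    def find_disease(self, name: str) -> str | None:
        """Disease node id whose name matches after trimming and case-folding."""
        return self._disease_name_index.get(normalize_disease_name(name))

    # -- edges ------------------------------------------------------------
    def add_edge(self, src: str, dst: str, edge_type: str) -> None:
        _check_edge_type(edge_type)
        for nid in (src, dst):
            if nid not in self._nodes:
                raise GraphError(f"edge endpoint {nid!r} not in graph")
        allowed = EDGE_VOCAB[edge_type]
        for nid in (src, dst):
            t = self._nodes[nid].node_type
            # a pre-split protein node stands for its gene, so gene-endpoint
            # edge types may be incident to proteins until split_protein_nodes runs
            if t not in allowed and not (t == "protein" and "gene" in allowed):
                raise GraphError(
                    f"edge type {edge_type!r} incompatible with endpoint type "
                    f"{t!r} of node {nid!r}"
                )
        rec = EdgeRecord(src, dst, edge_type)
        self._edges.setdefault(rec.key(), rec)

    def remove_edges_of_type(self, edge_type: str) -> int:
        keys = [k for k in self._edges if k[2] == edge_type]
        for k in keys:
            del self._edges[k]
        return len(keys)

    def edges(self, edge_type: str | None = None) -> list[EdgeRecord]:
        out = list(self._edges.values())
        if edge_type is not None:
            out = [e for e in out if e.edge_type == edge_type]
        return out

    def has_edge(self, src: str, dst: str, edge_type: str) -> bool:
        return EdgeRecord(src, dst, edge_type).key() in self._edges

    def edge_type_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self._edges.values():
            counts[e.edge_type] = counts.get(e.edge_type, 0) + 1
        return counts

    def neighbors(self, node_id: str, edge_type: str | None = None) -> list[str]:
        out = []
        for e in self._edges.values():
            if edge_type is not None and e.edge_type != edge_type:
                continue
            if e.src == node_id:
                out.append(e.dst)
            elif e.dst == node_id:
                out.append(e.src)
        return sorted(set(out))

    # -- masking ----------------------------------------------------------
    def mask(self, edge_type: str) -> None:
        _check_edge_type(edge_type)
        self.masked_types.add(edge_type)

    def unmask(self, edge_type: str) -> None:
        self.masked_types.discard(edge_type)

    def adjacency(self, extra_masked: Iterable[str] = ()) -> AdjacencyView:
        masked = set(self.masked_types)
        for t in extra_masked:
            _check_edge_type(t)
            masked.add(t)
        return AdjacencyView(self, frozenset(masked))

    # -- misc -------------------------------------------------------------
    def copy(self) -> "HeteroGraph":
        g = HeteroGraph()
        g._nodes = dict(self._nodes)
        g._edges = dict(self._edges)
        g.masked_types = set(self.masked_types)
        g._disease_name_index = dict(self._disease_name_index)
        return g

    def __repr__(self) -> str:  # pragma: no cover
        return f"HeteroGraph(nodes={len(self._nodes)}, edges={len(self._edges)})"


def mask_edges(graph: HeteroGraph, edge_type: str) -> AdjacencyView:
    """Adjacency view with every edge of ``edge_type`` hidden.

    The underlying store is not modified; masking is involutive at the view
    level (a view built without the mask restores the full adjacency).
    """
    _check_edge_type(edge_type)
    return graph.adjacency(extra_masked=[edge_type])


# ---------------------------------------------------------------------------
# graph augmentation
# ---------------------------------------------------------------------------

def _route_endpoint(edge_type: str) -> str:
    """Which half of a split protein node an edge re-attaches to.

    Routing keys on the gene/protein token in the vocabulary name: types
    naming a Gene endpoint move to the new gene node, types naming a Protein
    endpoint stay on the protein node.
    """
    _check_edge_type(edge_type)
    if edge_type == PROTEIN_GENE:
        return "protein"
    if "Gene" in edge_type:
        return "gene"
    if "Protein" in edge_type:
        return "protein"
    raise VocabularyError(
        f"edge type {edge_type!r} cannot be incident to a protein node"
    )


def split_protein_nodes(graph: HeteroGraph, gene_suffix: str = ":gene") -> HeteroGraph:
    """Split every protein node into a (gene, protein) pair.

    The new gene node keeps the protein's display name (the gene symbol) and
    gets id ``<protein_id><gene_suffix>``.  The pair is joined by a
    protein-gene edge, and each incident edge is rewired according to
    :func:`_route_endpoint`.  Node count grows by exactly the number of
    protein nodes; the input graph is not modified.
    """
    out = HeteroGraph()
    out.masked_types = set(graph.masked_types)
    gene_of: dict[str, str] = {}
    for node in graph.nodes():
        out.add_node(node)
        if node.node_type == "protein":
            gid = node.node_id + gene_suffix
            if graph.has_node(gid):
                raise GraphError(f"gene id {gid!r} already exists; pick another suffix")
            out.add_node(NodeRef(gid, "gene", node.name))
            gene_of[node.node_id] = gid
    for pid, gid in gene_of.items():
        out.add_edge(pid, gid, PROTEIN_GENE)
    for e in graph.edges():
        src, dst = e.src, e.dst
        src_is_p = src in gene_of
        dst_is_p = dst in gene_of
        if src_is_p or dst_is_p:
            side = _route_endpoint(e.edge_type)
            if side == "gene":
                if src_is_p:
                    src = gene_of[src]
                if dst_is_p:
                    dst = gene_of[dst]
        out.add_edge(src, dst, e.edge_type)
    return out


def variant_node_id(v: "VariantRecord") -> str:
    return f"var:{v.chrom}:{v.pos}:{v.ref or '-'}>{v.alt or '-'}"


def attach_variants(
    graph: HeteroGraph,
    variants: Sequence["VariantRecord"],
    gene_index: dict[str, str] | None = None,
) -> HeteroGraph:
    """Attach variant nodes to the graph.

    Each variant gets one node and one variant-gene edge.  Pathogenic variants
    additionally get one disease-variant edge per associated disease, creating
    the disease node when the name (trimmed, case-folded) is not found.
    Benign variants get no disease edge.  Re-running with the same list is a
    no-op (idempotent).  ``gene_index`` maps gene symbol to gene node id; by
    default gene nodes are looked up by display name.
    """
    out = graph.copy()
    if gene_index is None:
        gene_index = {}
        for n in graph.nodes("gene"):
            gene_index.setdefault(n.name, n.node_id)
            gene_index.setdefault(n.node_id, n.node_id)
    for v in variants:
        gid = gene_index.get(v.gene)
        if gid is None or not out.has_node(gid):
            raise GraphError(f"variant {variant_node_id(v)} references unknown gene {v.gene!r}")
        vid = variant_node_id(v)
        out.add_node(NodeRef(vid, "variant", vid))
        out.add_edge(vid, gid, VARIANT_GENE)
        if v.clinical_label == "pathogenic":
            for disease_name in v.diseases:
                did = out.find_disease(disease_name)
                if did is None:
                    did = "disease:" + normalize_disease_name(disease_name)
                    out.add_node(NodeRef(did, "disease", disease_name.strip()))
                out.add_edge(did, vid, DISEASE_VARIANT)
    return out


# ---------------------------------------------------------------------------
# PPI typing from co-expression
# ---------------------------------------------------------------------------

def _check_correlation(r: float) -> None:
    if not -1.0 <= r <= 1.0:
        raise RangeError(f"correlation {r} outside [-1, 1]")


def classify_ppi_temporal(timecourse: Sequence[float]) -> str:
    """Label a PPI ``transient``/``permanent``/``unlabeled`` from time-course co-expression.

    Each experiment votes transient iff its correlation is below
    :data:`TRANSIENT_THRESHOLD`; the edge label is the strict majority over
    experiments.  No experiments means ``unlabeled``; an exact tie resolves to
    ``permanent`` (the less volatile class).
    """
    for r in timecourse:
        _check_correlation(r)
    if not timecourse:
        return "unlabeled"
    transient_votes = sum(1 for r in timecourse if r < TRANSIENT_THRESHOLD)
    return "transient" if 2 * transient_votes > len(timecourse) else "permanent"


def bin_tissue_coexpression(r: float, bins: dict[str, float] | None = None) -> str:
    """Ordinal co-expression level of a gene pair across tissues.

    Thresholds are half-open on the right: negative (r <= b_neg), none
    (b_neg < r < b_none), then low/medium/high positive.  ``bins`` overrides
    the implementation defaults.
    """
    _check_correlation(r)
    b = DEFAULT_COEXPR_BINS if bins is None else bins
    if r <= b["negative"]:
        return "negative"
    if r < b["none"]:
        return "none"
    if r < b["low_positive"]:
        return "low_positive"
    if r < b["medium_positive"]:
        return "medium_positive"
    return "high_positive"


def apply_ppi_typing(
    graph: HeteroGraph,
    profiles: Iterable[CoexpressionProfile],
    protein_index: dict[str, str] | None = None,
) -> HeteroGraph:
    """Replace generic PPI edges with temporal labels and add co-expression edges.

    For each profile whose endpoints are connected by a generic
    ``Protein-Protein (PPI)`` edge, that edge is replaced by its
    transient/permanent/unlabeled counterpart, and — when a tissue-level r is
    present — a second, co-expression-binned PPI edge is added between the
    same pair.
    """
    out = graph.copy()
    idx = protein_index or {}
    for prof in profiles:
        a = idx.get(prof.gene_a, prof.gene_a)
        b = idx.get(prof.gene_b, prof.gene_b)
        if not (out.has_node(a) and out.has_node(b)):
            continue
        generic = EdgeRecord(a, b, "Protein-Protein (PPI)")
        if generic.key() in out._edges:
            del out._edges[generic.key()]
        label = classify_ppi_temporal(prof.timecourse)
        out.add_edge(a, b, PPI_TEMPORAL_EDGE[label])
        if prof.tissue_r is not None:
            out.add_edge(a, b, COEXPRESSION_EDGE[bin_tissue_coexpression(prof.tissue_r)])
    return out


def collapse_ppi_types(graph: HeteroGraph) -> HeteroGraph:
    """Collapse all PPI subtypes to the single generic PPI type."""
    out = HeteroGraph()
    out.masked_types = set(graph.masked_types) - PPI_EDGE_TYPES
    for n in graph.nodes():
        out.add_node(n)
    for e in graph.edges():
        t = "Protein-Protein (PPI)" if e.edge_type in PPI_EDGE_TYPES else e.edge_type
        out.add_edge(e.src, e.dst, t)
    return out


# ---------------------------------------------------------------------------
# edge-list I/O (5-column TSV)
# ---------------------------------------------------------------------------

_EDGE_COLUMNS = ["src_id", "src_type", "dst_id", "dst_type", "edge_type"]


def write_edge_list(graph: HeteroGraph, path) -> None:
    """Write the graph as a UTF-8 TSV with header src_id/src_type/dst_id/dst_type/edge_type.

    Isolated nodes are preserved via self-describing rows with an empty dst.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_EDGE_COLUMNS)
        touched: set[str] = set()
        for e in sorted(graph.edges(), key=lambda e: e.key()):
            s, d = graph.node(e.src), graph.node(e.dst)
            w.writerow([s.node_id, s.node_type, d.node_id, d.node_type, e.edge_type])
            touched.update((e.src, e.dst))
        for nid in graph.node_ids():
            if nid not in touched:
                n = graph.node(nid)
                w.writerow([n.node_id, n.node_type, "", "", ""])


def read_edge_list(path) -> HeteroGraph:
    """Read a 5-column edge-list TSV written by :func:`write_edge_list`."""
    graph = HeteroGraph()
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty file (header row required)", line=1)
        if header != _EDGE_COLUMNS:
            raise ParseError(f"expected header {_EDGE_COLUMNS}, got {header}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c for c in row):
                continue
            if len(row) != 5:
                raise ParseError(f"expected 5 columns, got {len(row)}", line=lineno)
            src_id, src_type, dst_id, dst_type, edge_type = row
            try:
                graph.add_node(NodeRef(src_id, src_type, src_id))
                if dst_id == "" and edge_type == "":
                    continue  # isolated-node row
                graph.add_node(NodeRef(dst_id, dst_type, dst_id))
                graph.add_edge(src_id, dst_id, edge_type)
            except (VocabularyError, GraphError) as exc:
                raise ParseError(str(exc), line=lineno) from exc
    return graph


def read_node_table(path) -> list[NodeRef]:
    """Read a node TSV (node_id, node_type, name) into NodeRefs."""
    nodes = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["node_id", "node_type", "name"]:
            raise ParseError("expected header node_id/node_type/name", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise ParseError(f"expected 3 columns, got {len(row)}", line=lineno)
            try:
                nodes.append(NodeRef(row[0], row[1], row[2]))
            except VocabularyError as exc:
                raise ParseError(str(exc), line=lineno) from exc
    return nodes
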