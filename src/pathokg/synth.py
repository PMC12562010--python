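"""Seeded synthetic data: toy genome, knowledge graph, variants and embeddings.

The generator emulates the inputs the pipeline consumes in a real study —
a ClinVar-style variant table, a PrimeKG-style typed graph, co-expression
evidence, and per-node embedding vectors — at desk scale, with a *planted*
variant-disease signal of tunable strength so that model behavior is
checkable against ground truth:

* every disease carries a latent unit direction ``u_d``;
* **direct mode** puts ``sqrt(alpha) * u_d`` into the embeddings of
  pathogenic variants (benign variants are pure noise), so even a graph-free
  model can read the signal;
* **relational mode** (default) additionally writes the disease directions
  into *gene* embeddings, gives every disease node the *same* shared raw
  embedding, and gives benign variants a decoy direction drawn from another
  gene's diseases.  The shared disease embedding means the raw input carries
  no disease identity whatsoever — a graph-free model cannot even memorize
  which disease it is looking at — so the disease-specific signal is
  reachable only through graph edges (disease -> gene), which is what gives
  the graph model its advantage over the raw-embedding baseline: the
  relational context, not the raw embedding, carries the signal.

All randomness flows from one integer seed; identical seeds give bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pathokg.errors import ConfigError
from pathokg.graph_store import (
    DISEASE_GENE,
    PATHWAY_GENE,
    PROTEIN_GENE,
    CoexpressionProfile,
    HeteroGraph,
    NodeRef,
    attach_variants,
    apply_ppi_typing,
)
from pathokg.node_features import EmbeddingMatrix
from pathokg.seq_context import ALLOWED_REVIEW_STATUSES, ChromSeq, VariantRecord

_BASES = np.array(list("ACGT"))


@dataclass
class SynthConfig:
    """Generator settings; defaults define the standard study conditions."""

    n_genes: int = 50
    diseases_per_gene: tuple[int, int] = (2, 2)
    variants_per_gene: tuple[int, int] = (40, 40)
    pathogenic_fraction: float = 0.5
    n_pathways: int = 10
    ppi_density: float = 0.05
    n_experiments: int = 5
    transient_fraction: float = 0.5
    embed_dim: int = 32
    signal_strength: float = 0.9
    signal_mode: str = "relational"  # or "direct"
    full_graph: bool = False
    n_chromosomes: int = 2
    gene_spacing: int = 200
    invalid_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ConfigError("signal_strength must lie in [0, 1]")
        if self.signal_mode not in ("relational", "direct"):
            raise ConfigError(f"unknown signal mode {self.signal_mode!r}")
        if not 0.0 <= self.pathogenic_fraction <= 1.0:
            raise ConfigError("pathogenic_fraction must lie in [0, 1]")
        if self.n_genes < 1 or self.n_pathways < 1 or self.n_chromosomes < 1:
            raise ConfigError("counts must be >= 1")


@dataclass
class GeneLocus:
    symbol: str
    chrom: str
    start: int
    end: int


@dataclass
class SynthDataset:
    """One complete synthetic study: genome, graph, variants, embeddings."""

    config: SynthConfig
    genome: dict[str, ChromSeq]
    gene_loci: dict[str, GeneLocus]
    graph: HeteroGraph  # variants attached
    base_graph: HeteroGraph  # before variant attachment
    variants: list[VariantRecord]
    embeddings: EmbeddingMatrix
    coexpression: list[CoexpressionProfile] = field(default_factory=list)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SynthConfig) -> tuple[dict[str, ChromSeq], dict[str, GeneLocus]]:
    """Uniform-random chromosomes with evenly spaced gene loci."""
    rng = np.random.default_rng(config.seed)
    genes_per_chrom = -(-config.n_genes // config.n_chromosomes)
    length = (genes_per_chrom + 2) * config.gene_spacing
    genome: dict[str, ChromSeq] = {}
    loci: dict[str, GeneLocus] = {}
    for c in range(config.n_chromosomes):
        name = str(c + 1)
        seq = "".join(rng.choice(_BASES, size=length))
        genome[name] = ChromSeq(name, seq)
    for i in range(config.n_genes):
        chrom = str(i % config.n_chromosomes + 1)
        slot = i // config.n_chromosomes
        start = (slot + 1) * config.gene_spacing
        loci[f"G{i + 1:03d}"] = GeneLocus(
            f"G{i + 1:03d}", chrom, start, start + config.gene_spacing - 1
        )
    return genome, loci


# ---------------------------------------------------------------------------
# knowledge graph
# ---------------------------------------------------------------------------

def simulate_coexpression(
    ppi_pairs: list[tuple[str, str]], config: SynthConfig, seed_offset: int = 1
) -> list[CoexpressionProfile]:
    """Time-course and tissue co-expression with a controlled transient fraction.

    Exactly ``round(transient_fraction * n)`` pairs get a strict majority of
    experiments below the transient threshold; the rest get at most half
    below (so the majority classifier recovers the planted labels exactly).
    Tissue-level correlations are spread over all five co-expression bins.
    """
    rng = np.random.default_rng(config.seed + seed_offset)
    n = len(ppi_pairs)
    if n == 0:
        return []
    m = config.n_experiments
    n_transient = int(round(config.transient_fraction * n))
    transient = np.zeros(n, dtype=bool)
    transient[rng.permutation(n)[:n_transient]] = True
    tissue_ranges = [(-0.9, -0.11), (-0.09, 0.09), (0.11, 0.39), (0.41, 0.69), (0.71, 0.99)]
    out = []
    for k, (a, b) in enumerate(ppi_pairs):
        if transient[k]:
            below = int(rng.integers(m // 2 + 1, m + 1))
        else:
            below = int(rng.integers(0, m // 2 + 1))
        values = np.concatenate(
            [rng.uniform(-0.95, 0.09, size=below), rng.uniform(0.11, 0.95, size=m - below)]
        )
        rng.shuffle(values)
        lo, hi = tissue_ranges[int(rng.integers(len(tissue_ranges)))]
        out.append(
            CoexpressionProfile(a, b, timecourse=values.tolist(), tissue_r=float(rng.uniform(lo, hi)))
        )
    return out


_STUB_TYPES = (
    "phenotype",
    "drug",
    "molecular_function",
    "biological_process",
    "cellular_component",
    "exposure",
    "anatomy",
)
_STUB_EDGES = {
    "phenotype": ("Disease-Phenotype (phenotype present)", "disease"),
    "drug": ("Drug-Protein (target)", "protein"),
    "molecular_function": ("Molecular function-Gene (interacts with)", "gene"),
    "biological_process": ("Bioprocess-Gene (interacts with)", "gene"),
    "cellular_component": ("Cellular component-Gene (interacts with)", "gene"),
    "exposure": ("Exposure-Disease (linked to)", "disease"),
    "anatomy": ("Anatomy-Gene (expression present)", "gene"),
}


def simulate_kg(
    config: SynthConfig,
) -> tuple[HeteroGraph, dict[str, list[str]], list[CoexpressionProfile]]:
    """Typed knowledge graph over genes, proteins, pathways and diseases.

    Each gene gets a 1:1 protein, membership in one pathway, and 1..k unique
    diseases; proteins are wired into a random PPI layer whose edges are typed
    from simulated co-expression.  Full-graph mode adds stub nodes of the
    seven remaining types.  Returns (graph, diseases-by-gene, co-expression).
    """
    rng = np.random.default_rng(config.seed + 2)
    g = HeteroGraph()
    genes = [f"G{i + 1:03d}" for i in range(config.n_genes)]
    for i, sym in enumerate(genes):
        g.add_node(NodeRef(sym, "gene", sym))
        g.add_node(NodeRef(f"P:{sym}", "protein", sym))
        g.add_edge(f"P:{sym}", sym, PROTEIN_GENE)
    for p in range(config.n_pathways):
        g.add_node(NodeRef(f"PW{p + 1:02d}", "pathway", f"pathway {p + 1}"))
    for i, sym in enumerate(genes):
        g.add_edge(f"PW{i % config.n_pathways + 1:02d}", sym, PATHWAY_GENE)

    lo, hi = config.diseases_per_gene
    diseases_by_gene: dict[str, list[str]] = {}
    for sym in genes:
        k = int(rng.integers(lo, hi + 1))
        names = []
        for j in range(k):
            did = f"D:{sym}:{j + 1}"
            g.add_node(NodeRef(did, "disease", f"{sym} disease {j + 1}"))
            g.add_edge(did, sym, DISEASE_GENE)
            names.append(f"{sym} disease {j + 1}")
        diseases_by_gene[sym] = names

    proteins = [f"P:{sym}" for sym in genes]
    pairs: list[tuple[str, str]] = []
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            if rng.random() < config.ppi_density:
                pairs.append((proteins[i], proteins[j]))
    profiles = simulate_coexpression(pairs, config)
    g = apply_ppi_typing(g, profiles)

    if config.full_graph:
        for t in _STUB_TYPES:
            edge_type, anchor_type = _STUB_EDGES[t]
            anchors = [n.node_id for n in g.nodes(anchor_type)]
            for s in range(3):
                nid = f"{t}:{s + 1}"
                g.add_node(NodeRef(nid, t, f"{t} {s + 1}"))
                g.add_edge(nid, anchors[int(rng.integers(len(anchors)))], edge_type)
    return g, diseases_by_gene, profiles


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

_CLASS_WEIGHTS = {"snv": 0.7, "insertion": 0.1, "deletion": 0.1, "indel": 0.1}


def _random_variant(
    rng: np.random.Generator,
    chrom: ChromSeq,
    locus: GeneLocus,
    pos: int,
    var_class: str,
) -> tuple[str, str]:
    """(ref, alt) alleles of the requested class at the given position."""
    if var_class == "snv":
        ref = chrom.base(pos)
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        return ref, alt
    if var_class == "insertion":
        ref = chrom.base(pos)
        payload = "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
        return ref, ref + payload
    if var_class == "deletion":
        d = int(rng.integers(1, 4))
        return chrom.slice(pos, pos + d - 1), ""
    d = int(rng.integers(1, 4))
    ref = chrom.slice(pos, pos + d - 1)
    alt = "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
    return ref, alt


def _spoil_record(rng: np.random.Generator, v: VariantRecord) -> VariantRecord:
    """Make a record violate exactly one ClinVar-style inclusion rule."""
    rule = int(rng.integers(4))
    if rule == 0:
        v.clinical_label = "likely pathogenic"
    elif rule == 1:
        v.review_status = "no assertion criteria provided"
    elif rule == 2:
        v.origin = "somatic"
    else:
        v.assembly = "GRCh37"
    return v


def simulate_variants(
    genome: dict[str, ChromSeq],
    gene_loci: dict[str, GeneLocus],
    diseases_by_gene: dict[str, list[str]],
    config: SynthConfig,
) -> list[VariantRecord]:
    """ClinVar-style records per gene with reference alleles read off the genome.

    Pathogenic variants get one associated disease of their gene; benign
    variants get none.  Review statuses, origins and submission dates
    (2018-2024) are populated so the inclusion filters and the date-based
    split are exercisable; ``invalid_fraction`` of records violate one
    inclusion rule each.
    """
    rng = np.random.default_rng(config.seed + 3)
    lo, hi = config.variants_per_gene
    classes = list(_CLASS_WEIGHTS)
    weights = np.array(list(_CLASS_WEIGHTS.values()))
    out: list[VariantRecord] = []
    for sym in sorted(gene_loci):
        locus = gene_loci[sym]
        chrom = genome[locus.chrom]
        n = int(rng.integers(lo, hi + 1))
        # distinct positions, margin 4 for multi-base ref segments
        positions = rng.choice(
            np.arange(locus.start, locus.end - 4), size=min(n, locus.end - 4 - locus.start),
            replace=False,
        )
        n_path = int(round(config.pathogenic_fraction * len(positions)))
        for j, pos in enumerate(sorted(int(p) for p in positions)):
            var_class = str(rng.choice(classes, p=weights))
            ref, alt = _random_variant(rng, chrom, locus, pos, var_class)
            pathogenic = j < n_path
            year = int(rng.integers(2018, 2025))
            v = VariantRecord(
                chrom=locus.chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                var_class=var_class,
                gene=sym,
                clinical_label="pathogenic" if pathogenic else "benign",
                review_status=str(rng.choice(ALLOWED_REVIEW_STATUSES)),
                submission_date=f"{year}-{int(rng.integers(1, 13)):02d}-{int(rng.integers(1, 29)):02d}",
                diseases=[str(rng.choice(diseases_by_gene[sym]))] if pathogenic else [],
            )
            if rng.random() < config.invalid_fraction:
                v = _spoil_record(rng, v)
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# planted-signal embeddings
# ---------------------------------------------------------------------------

def _unit(rng: np.random.Generator, dim: int) -> np.ndarray:
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)


def _mix(direction: np.ndarray, noise: np.ndarray, alpha: float) -> np.ndarray:
    v = np.sqrt(alpha) * direction + np.sqrt(1.0 - alpha) * noise
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def plant_signal(
    graph: HeteroGraph,
    variants: list[VariantRecord],
    config: SynthConfig,
) -> EmbeddingMatrix:
    """Node embeddings with a planted variant-disease signal of strength alpha.

    See the module docstring for the two modes.  Rows follow the canonical
    (sorted id) order of ``graph``, which must already contain the variants.
    """
    rng = np.random.default_rng(config.seed + 4)
    alpha = config.signal_strength
    dim = config.embed_dim
    node_ids = graph.node_ids()

    disease_nodes = [n.node_id for n in graph.nodes("disease")]
    u = {did: _unit(rng, dim) for did in sorted(disease_nodes)}
    shared_disease_vec = _unit(rng, dim)
    diseases_of_gene: dict[str, list[str]] = {}
    for did in sorted(disease_nodes):
        for gid in graph.neighbors(did, DISEASE_GENE):
            diseases_of_gene.setdefault(gid, []).append(did)

    by_variant = {v.variant_id: v for v in variants}
    vectors: dict[str, np.ndarray] = {}
    for nid in node_ids:
        node = graph.node(nid)
        noise = _unit(rng, dim)
        if node.node_type == "variant" and nid in by_variant:
            rec = by_variant[nid]
            if rec.clinical_label == "pathogenic" and rec.diseases:
                dids = [graph.find_disease(d) for d in rec.diseases]
                direction = np.mean([u[d] for d in dids if d in u], axis=0)
                direction /= np.linalg.norm(direction)
                vectors[nid] = _mix(direction, noise, alpha)
            elif rec.clinical_label == "benign" and config.signal_mode == "relational":
                own = set(diseases_of_gene.get(rec.gene, []))
                decoys = [d for d in sorted(u) if d not in own]
                direction = u[decoys[int(rng.integers(len(decoys)))]] if decoys else noise
                vectors[nid] = _mix(direction, noise, alpha)
            else:
                vectors[nid] = noise
        elif node.node_type == "gene" and config.signal_mode == "relational":
            dids = diseases_of_gene.get(nid, [])
            if dids:
                direction = np.mean([u[d] for d in dids], axis=0)
                direction /= np.linalg.norm(direction)
                vectors[nid] = _mix(direction, noise, alpha)
            else:
                vectors[nid] = noise
        elif node.node_type == "disease":
            vectors[nid] = u.get(nid, noise) if config.signal_mode == "direct" else shared_disease_vec
        else:
            vectors[nid] = noise
    return EmbeddingMatrix(node_ids, np.stack([vectors[nid] for nid in node_ids]))


# ---------------------------------------------------------------------------
# one-call study generator
# ---------------------------------------------------------------------------

def simulate(config: SynthConfig | None = None) -> SynthDataset:
    """Generate a complete, internally consistent synthetic study."""
    config = config or SynthConfig()
    genome, loci = simulate_genome(config)
    base_graph, diseases_by_gene, profiles = simulate_kg(config)
    variants = simulate_variants(genome, loci, diseases_by_gene, config)
    attachable = [v for v in variants if v.clinical_label in ("benign", "pathogenic")]
    graph = attach_variants(base_graph, attachable)
    embeddings = plant_signal(graph, attachable, config)
    return SynthDataset(
        config=config,
        genome=genome,
        gene_loci=loci,
        graph=graph,
        base_graph=base_graph,
        variants=variants,
        embeddings=embeddings,
        coexpression=profiles,
    )
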