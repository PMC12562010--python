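"""Initial per-node feature vectors.

Every node enters the graph encoder with a fixed-width numeric vector.  In
the original pipeline these come from pretrained language models (BioBERT for
text, HyenaDNA / Nucleotide Transformer for variant genomic context); here the
sources sit behind a minimal provider contract — any deterministic callable
mapping a string to a fixed-width vector — so the pipeline runs with the
built-in feature-hashing embedder, with externally precomputed matrices, or
with synthetic planted-signal embeddings.

Text sources per node type:

* variant — ``"<variant type> located on chromosome <chromosome number> at
  position <variant position> with reference allele <reference allele> and
  alternative allele <alternative allele>"`` (or a DNA context window when a
  sequence provider is configured);
* protein — ``"Protein encoded by gene <gene symbol>"``;
* drug/disease — a list of description features, embedded separately and
  averaged; diseases without descriptions fall back to their name;
* everything else — the node display name.

All embeddings are L2-normalized per row, then right-padded with zeros to a
common width across node types so the encoder consumes a single matrix.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np

from pathokg.errors import ConfigError, ParseError, RangeError, ShapeError, TemplateError
from pathokg.graph_store import HeteroGraph, NodeRef
from pathokg.seq_context import DNA_ALPHABET, VariantRecord

VARIANT_TEXT_TEMPLATE = (
    "{var_class} located on chromosome {chrom} at position {pos} "
    "with reference allele {ref} and alternative allele {alt}"
)


def build_variant_text(v: VariantRecord) -> str:
    """Textual description of a variant used as language-model input."""
    for fname in ("chrom", "ref", "alt", "var_class"):
        if not getattr(v, fname):
            raise TemplateError(f"variant text template: missing field {fname!r}")
    if not v.pos:
        raise TemplateError("variant text template: missing field 'pos'")
    return VARIANT_TEXT_TEMPLATE.format(
        var_class=v.var_class, chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt
    )


def build_protein_text(gene_symbol: str) -> str:
    """Textual description of a protein node from its gene symbol."""
    symbol = gene_symbol.strip()
    if not symbol:
        raise TemplateError("protein text template: empty gene symbol")
    return f"Protein encoded by gene {symbol}"


def node_text(
    node: NodeRef,
    descriptions: Mapping[str, Sequence[str]] | None = None,
    variants: Mapping[str, VariantRecord] | None = None,
) -> str | list[str]:
    """Embedding input(s) for one node.

    Drug/disease nodes with multi-feature descriptions return the feature
    list (one embedding per feature, averaged downstream); protein and variant
    nodes delegate to their templates; everything else returns the name.
    """
    if descriptions and node.node_type in ("drug", "disease"):
        feats = descriptions.get(node.node_id)
        if feats:
            return list(feats)
    if node.node_type == "protein":
        return build_protein_text(node.name)
    if node.node_type == "variant" and variants is not None:
        rec = variants.get(node.node_id)
        if rec is not None:
            return build_variant_text(rec)
    return node.name


def average_feature_embeddings(vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise mean of equal-width vectors (multi-feature node fusion)."""
    if len(vectors) == 0:
        raise ShapeError("cannot average an empty list of embeddings")
    widths = {len(np.asarray(v).ravel()) for v in vectors}
    if len(widths) > 1:
        raise ShapeError(f"embedding width mismatch: {sorted(widths)}")
    return np.mean(np.asarray(vectors, dtype=np.float64), axis=0)


@dataclass
class EmbeddingMatrix:
    """Id-indexed fixed-width embedding rows (one node per row)."""

    ids: list[str]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.ids):
            raise ShapeError(
                f"vectors shape {self.vectors.shape} does not match {len(self.ids)} ids"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise RangeError("embedding matrix contains non-finite values")
        self._index = {nid: i for i, nid in enumerate(self.ids)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def row(self, node_id: str) -> np.ndarray:
        return self.vectors[self._index[node_id]]

    def index_of(self, node_id: str) -> int:
        return self._index[node_id]

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["node_id"] + [f"e{i}" for i in range(self.dim)])
            for nid, vec in zip(self.ids, self.vectors):
                w.writerow([nid] + [repr(float(x)) for x in vec])

    @classmethod
    def from_tsv(cls, path) -> "EmbeddingMatrix":
        ids, rows = [], []
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader, None)
            if not header or header[0] != "node_id":
                raise ParseError("expected header starting with node_id", line=1)
            width = len(header) - 1
            for lineno, row in enumerate(reader, start=2):
                if not row:
                    continue
                if len(row) != width + 1:
                    raise ParseError(f"expected {width + 1} columns", line=lineno)
                ids.append(row[0])
                rows.append([float(x) for x in row[1:]])
        return cls(ids, np.asarray(rows, dtype=np.float64))


def l2_normalize(matrix: EmbeddingMatrix | np.ndarray) -> EmbeddingMatrix | np.ndarray:
    """Scale each nonzero row to unit Euclidean norm; zero rows pass through."""
    if isinstance(matrix, EmbeddingMatrix):
        return EmbeddingMatrix(list(matrix.ids), l2_normalize(matrix.vectors))
    x = np.asarray(matrix, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise RangeError("cannot normalize non-finite values")
    norms = np.linalg.norm(x, axis=-1, keepdims=True)
    safe = np.where(norms == 0.0, 1.0, norms)
    return x / safe


class EmbeddingProvider(Protocol):
    """Deterministic map from a text or DNA string to a fixed-width vector."""

    dim: int

    def __call__(self, text: str) -> np.ndarray: ...  # pragma: no cover


def _looks_like_dna(text: str) -> bool:
    return len(text) >= 6 and set(text.upper()) <= DNA_ALPHABET


class HashEmbedder:
    """Feature-hashing embedder: a deterministic stand-in provider.

    Words (for text) or overlapping 6-mers (for DNA) are hashed with the seed
    into ``dim`` signed buckets and accumulated, then scaled by
    ``1/sqrt(token count)``; identical input always yields an identical
    vector.  Carries no semantics — it exists so the full pipeline runs and
    is exactly reproducible without pretrained models.
    """

    KMER = 6

    def __init__(self, dim: int, seed: int = 0):
        if dim < 1:
            raise ConfigError(f"embedder dim must be >= 1, got {dim}")
        self.dim = dim
        self.seed = seed

    def _tokens(self, text: str) -> list[str]:
        if _looks_like_dna(text):
            s = text.upper()
            return [s[i : i + self.KMER] for i in range(len(s) - self.KMER + 1)]
        return text.split()

    def __call__(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim, dtype=np.float64)
        tokens = self._tokens(text)
        if not tokens:
            import warnings

            warnings.warn(f"empty embedder input {text!r}; returning zero vector")
            return vec
        for tok in tokens:
            h = hashlib.blake2b(
                tok.encode("utf-8"), digest_size=8, key=str(self.seed).encode()
            ).digest()
            value = int.from_bytes(h, "big")
            bucket = value % self.dim
            sign = 1.0 if (value >> 32) & 1 else -1.0
            vec[bucket] += sign
        return vec / np.sqrt(len(tokens))


def assemble_initial_features(
    graph: HeteroGraph,
    providers: Mapping[str, EmbeddingProvider] | EmbeddingProvider,
    descriptions: Mapping[str, Sequence[str]] | None = None,
    variants: Mapping[str, VariantRecord] | None = None,
    variant_sequences: Mapping[str, str] | None = None,
) -> EmbeddingMatrix:
    """Per-node initial features for the whole graph.

    ``providers`` maps node type to provider (a single provider serves all
    types).  Variant nodes are embedded from ``variant_sequences`` (context
    windows) when given, else from their text template.  Per-type embeddings
    are L2-normalized, then zero-padded on the right to the maximum width so
    the encoder consumes one matrix; rows follow the canonical (sorted id)
    node order.
    """
    node_ids = graph.node_ids()
    per_node: dict[str, np.ndarray] = {}
    for nid in node_ids:
        node = graph.node(nid)
        if isinstance(providers, Mapping):
            provider = providers.get(node.node_type)
            if provider is None:
                raise ConfigError(f"no embedding provider for node type {node.node_type!r}")
        else:
            provider = providers
        if node.node_type == "variant" and variant_sequences is not None:
            source: str | list[str] = variant_sequences.get(nid) or node_text(
                node, descriptions, variants
            )
        else:
            source = node_text(node, descriptions, variants)
        if isinstance(source, list):
            vec = average_feature_embeddings([provider(s) for s in source])
        else:
            vec = provider(source)
        per_node[nid] = np.asarray(vec, dtype=np.float64).ravel()

    width = max(v.shape[0] for v in per_node.values())
    out = np.zeros((len(node_ids), width), dtype=np.float64)
    for i, nid in enumerate(node_ids):
        vec = per_node[nid]
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec = vec / norm
        out[i, : vec.shape[0]] = vec
    return EmbeddingMatrix(node_ids, out)
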