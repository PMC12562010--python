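"""Pair construction, ClinVar-style filtering, data splits and training.

A *pair example* is a (variant, disease) pair with a binary label: pathogenic
variants paired with each of their associated diseases form the positive
class; benign variants paired with every disease linked to their gene form
the negative class.  Three split strategies are provided:

* ``random_split`` — seeded 70/15/15 shuffle over pairs;
* ``per_gene_balanced_split`` — per gene, one variant is reserved for
  validation and one for testing (different classes when possible), and the
  remaining pairs are class-balanced exactly within each gene before entering
  training;
* ``date_split`` — variants submitted up to a cutoff year feed an 80/20
  train/validation split, later submissions form the test set (forward-in-time
  deployment scenario).

Training is end-to-end mini-batch SGD (momentum, weight decay) on binary
cross-entropy.  Disease-variant edges are masked out of every adjacency used
in a forward pass — these edges *are* the labels, so leaving them in would
leak the answer through message passing; the mask is re-asserted every epoch.
The model state returned is the epoch argmin of validation loss.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np

from pathokg.errors import PathoKGError, SplitError
from pathokg.graph_store import (
    DISEASE_GENE,
    DISEASE_VARIANT,
    HeteroGraph,
)
from pathokg.metrics import ConfusionMatrix, EvalReport
from pathokg.model import (
    BaselineState,
    ModelState,
    SGDOptimizer,
    bce_loss,
    decode_pairs,
    gcn_backward,
    gcn_encode,
    mlp_backward,
    normalized_adjacency,
)
from pathokg.node_features import EmbeddingMatrix
from pathokg.seq_context import ALLOWED_REVIEW_STATUSES, VariantRecord

NUCLEAR_CHROMOSOMES = frozenset([str(i) for i in range(1, 23)] + ["X", "Y"])


@dataclass(frozen=True)
class PairExample:
    """One labeled variant-disease pair; label 1 = pathogenic association."""

    variant_id: str
    disease_id: str
    label: int
    gene: str


@dataclass
class DataSplit:
    train: list[PairExample]
    validation: list[PairExample]
    test: list[PairExample]
    report: dict = field(default_factory=dict)

    def assert_disjoint(self) -> None:
        t = set(self.train)
        v = set(self.validation)
        s = set(self.test)
        if t & v or t & s or v & s:
            raise SplitError("pair appears in more than one partition")


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults follow the reference protocol."""

    learning_rate: float = 0.001
    weight_decay: float = 0.1
    momentum: float = 0.9
    epochs: int = 200
    batch_size: int | None = 64
    patience: int = 30
    seed: int = 0
    split_mode: str = "random"
    window: int = 64
    provider: str = "hash"
    threshold: float = 0.5
    # per-batch BCE reduction: "sum" makes the update magnitude per example
    # independent of batch size and, at the configured learning rate, is what
    # lets the model train in a reasonable epoch budget; "mean" available
    loss_reduction: str = "sum"
    # training arithmetic precision; float32 halves runtime at desk scale
    dtype: str = "float32"

    @property
    def np_dtype(self):
        return np.float32 if self.dtype == "float32" else np.float64
    # diagnostics only: run with disease-variant edges visible to the encoder
    # to demonstrate the label leakage the mask prevents
    leak_disease_variant_edges: bool = False


# ---------------------------------------------------------------------------
# ClinVar-style filtering
# ---------------------------------------------------------------------------

_FILTER_RULES = ("label", "review_status", "origin", "assembly", "gene", "chromosome")


def filter_clinvar_records(
    records: list[VariantRecord],
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Keep benign/pathogenic, well-reviewed, germline, GRCh38, gene-linked nuclear variants.

    Records are dropped by the first rule they violate; the returned counter
    reports drops per rule.
    """
    kept: list[VariantRecord] = []
    drops = {rule: 0 for rule in _FILTER_RULES}
    for v in records:
        if v.clinical_label not in ("benign", "pathogenic"):
            drops["label"] += 1
        elif v.review_status not in ALLOWED_REVIEW_STATUSES:
            drops["review_status"] += 1
        elif v.origin != "germline":
            drops["origin"] += 1
        elif v.assembly != "GRCh38":
            drops["assembly"] += 1
        elif not v.gene.strip():
            drops["gene"] += 1
        elif v.chrom.removeprefix("chr") not in NUCLEAR_CHROMOSOMES:
            drops["chromosome"] += 1
        else:
            kept.append(v)
    return kept, drops


# ---------------------------------------------------------------------------
# pair construction
# ---------------------------------------------------------------------------

def _gene_node_index(graph: HeteroGraph) -> dict[str, str]:
    index: dict[str, str] = {}
    for n in graph.nodes("gene"):
        index.setdefault(n.name, n.node_id)
        index.setdefault(n.node_id, n.node_id)
    return index


def pairs_for_variant(
    graph: HeteroGraph, v: VariantRecord, gene_index: dict[str, str] | None = None
) -> list[PairExample]:
    """Pair examples contributed by one attached variant.

    Pathogenic: one positive per associated disease.  Benign: one negative
    per disease linked to the variant's gene by a disease-gene edge.
    """
    if gene_index is None:
        gene_index = _gene_node_index(graph)
    out: list[PairExample] = []
    if v.clinical_label == "pathogenic":
        for name in v.diseases:
            did = graph.find_disease(name)
            if did is not None:
                out.append(PairExample(v.variant_id, did, 1, v.gene))
    elif v.clinical_label == "benign":
        gid = gene_index.get(v.gene)
        if gid is not None:
            for did in graph.neighbors(gid, DISEASE_GENE):
                out.append(PairExample(v.variant_id, did, 0, v.gene))
    return out


def build_pairs(
    graph: HeteroGraph, variants: list[VariantRecord]
) -> tuple[list[PairExample], list[PairExample], dict]:
    """All positive and negative pair examples, plus a construction report."""
    gene_index = _gene_node_index(graph)
    positives: list[PairExample] = []
    negatives: list[PairExample] = []
    benign_without_disease = 0
    for v in variants:
        pairs = pairs_for_variant(graph, v, gene_index)
        if v.clinical_label == "benign" and not pairs:
            benign_without_disease += 1
        positives.extend(p for p in pairs if p.label == 1)
        negatives.extend(p for p in pairs if p.label == 0)
    report = {"benign_variants_without_disease_edges": benign_without_disease}
    if benign_without_disease:
        print(
            f"warning: {benign_without_disease} benign variant(s) in genes with "
            "no disease edge contribute no negative pairs",
            file=sys.stderr,
        )
    return positives, negatives, report


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def random_split(
    pairs: list[PairExample],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> DataSplit:
    """Seeded shuffle then contiguous 70/15/15 partition (remainder to train)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise SplitError(f"fractions {fractions} must sum to 1")
    if len(pairs) < 3:
        raise SplitError(f"cannot split {len(pairs)} pairs three ways")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    shuffled = [pairs[i] for i in order]
    n = len(pairs)
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train = n - n_val - n_test
    return DataSplit(
        train=shuffled[:n_train],
        validation=shuffled[n_train : n_train + n_val],
        test=shuffled[n_train + n_val :],
    )


def per_gene_balanced_split(
    variants: list[VariantRecord],
    graph: HeteroGraph,
    seed: int = 0,
) -> DataSplit:
    """Per-gene class-balanced training pairs with reserved evaluation variants.

    For each gene with more than one variant, one variant is reserved for
    validation and one for testing — drawn from different classes when both
    remain.  The remaining variants' pairs are balanced exactly per gene:
    ``min(positive, negative)`` pairs from each class enter training; surplus
    majority-class pairs are held out and counted in the report.
    """
    rng = np.random.default_rng(seed)
    gene_index = _gene_node_index(graph)
    by_gene: dict[str, list[VariantRecord]] = {}
    for v in variants:
        by_gene.setdefault(v.gene, []).append(v)

    train: list[PairExample] = []
    val: list[PairExample] = []
    test: list[PairExample] = []
    single_variant_genes = 0
    surplus_pairs = 0

    for gene in sorted(by_gene):
        vs = sorted(by_gene[gene], key=lambda v: v.variant_id)
        if len(vs) == 1:
            single_variant_genes += 1
            train.extend(pairs_for_variant(graph, vs[0], gene_index))
            continue
        val_idx = int(rng.integers(len(vs)))
        val_variant = vs.pop(val_idx)
        other_class = [i for i, v in enumerate(vs) if v.clinical_label != val_variant.clinical_label]
        pool = other_class if other_class else list(range(len(vs)))
        test_variant = vs.pop(pool[int(rng.integers(len(pool)))])
        val.extend(pairs_for_variant(graph, val_variant, gene_index))
        test.extend(pairs_for_variant(graph, test_variant, gene_index))

        pos: list[PairExample] = []
        neg: list[PairExample] = []
        for v in vs:
            for p in pairs_for_variant(graph, v, gene_index):
                (pos if p.label == 1 else neg).append(p)
        k = min(len(pos), len(neg))
        surplus_pairs += len(pos) + len(neg) - 2 * k
        train.extend(pos[i] for i in rng.permutation(len(pos))[:k])
        train.extend(neg[i] for i in rng.permutation(len(neg))[:k])

    if single_variant_genes:
        print(
            f"warning: {single_variant_genes} gene(s) with a single variant "
            "assigned wholly to training",
            file=sys.stderr,
        )
    split = DataSplit(
        train=train,
        validation=val,
        test=test,
        report={
            "single_variant_genes": single_variant_genes,
            "surplus_majority_pairs_excluded": surplus_pairs,
        },
    )
    split.assert_disjoint()
    return split


def date_split(
    variants: list[VariantRecord],
    graph: HeteroGraph,
    cutoff_year: int = 2022,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> DataSplit:
    """Train/validate on submissions up to ``cutoff_year``, test on later ones."""
    gene_index = _gene_node_index(graph)
    early: list[PairExample] = []
    late: list[PairExample] = []
    undated = 0
    for v in variants:
        if not v.submission_date:
            undated += 1
            continue
        year = int(v.submission_date[:4])
        target = early if year <= cutoff_year else late
        target.extend(pairs_for_variant(graph, v, gene_index))
    if not late:
        raise SplitError(f"no variants submitted after {cutoff_year}: empty test set")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(early))
    n_val = int(np.floor(val_fraction * len(early)))
    val = [early[i] for i in order[:n_val]]
    train = [early[i] for i in order[n_val:]]
    return DataSplit(
        train=train,
        validation=val,
        test=late,
        report={"undated_variants_excluded": undated},
    )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _pair_indices(pairs: list[PairExample], features: EmbeddingMatrix):
    vi = np.array([features.index_of(p.variant_id) for p in pairs], dtype=np.intp)
    di = np.array([features.index_of(p.disease_id) for p in pairs], dtype=np.intp)
    y = np.array([p.label for p in pairs], dtype=np.float64)
    return vi, di, y


def _training_view(graph: HeteroGraph, config: TrainConfig):
    extra = [] if config.leak_disease_variant_edges else [DISEASE_VARIANT]
    view = graph.adjacency(extra_masked=extra)
    if not config.leak_disease_variant_edges:
        assert view.edge_type_counts().get(DISEASE_VARIANT, 0) == 0, (
            "leakage guard: disease-variant edges present in training adjacency"
        )
    return view


def train(
    graph: HeteroGraph,
    features: EmbeddingMatrix,
    split: DataSplit,
    config: TrainConfig,
    verbose: bool = False,
) -> tuple[ModelState, dict]:
    """End-to-end training of the GCN encoder + pair decoder.

    Returns the model state at the epoch with minimum validation binary
    cross-entropy, plus a history dict with per-epoch train/validation losses.
    Losses are recorded in evaluation mode (dropout off) so the history is a
    deterministic function of the parameter trajectory.
    """
    split.assert_disjoint()
    view = _training_view(graph, config)
    if features.ids != view.node_ids:
        raise PathoKGError("feature matrix rows must follow the canonical node order")
    dtype = config.np_dtype
    A_hat = normalized_adjacency(view).astype(dtype)
    X = features.vectors.astype(dtype)
    vi_tr, di_tr, y_tr = _pair_indices(split.train, features)
    vi_va, di_va, y_va = _pair_indices(split.validation, features)
    y_tr = y_tr.astype(dtype)
    y_va = y_va.astype(dtype)

    state = ModelState.init(X.shape[1], config.seed, dtype=dtype)
    optimizer = SGDOptimizer(config.learning_rate, config.weight_decay, config.momentum)
    rng = np.random.default_rng(config.seed)

    def eval_losses() -> tuple[float, float]:
        Z, _ = gcn_encode(X, A_hat, state.encoder, training=False)
        p_tr, _, _ = decode_pairs(Z[vi_tr], Z[di_tr], state.decoder, training=False)
        p_va, _, _ = decode_pairs(Z[vi_va], Z[di_va], state.decoder, training=False)
        return bce_loss(p_tr, y_tr), bce_loss(p_va, y_va)

    history: dict = {"train_loss": [], "val_loss": [], "best_epoch": None}
    best_state = state.copy()
    best_val = np.inf
    n_train = len(split.train)
    batch = config.batch_size or n_train
    epochs_since_best = 0

    for epoch in range(config.epochs):
        # leakage guard re-asserted every epoch
        if not config.leak_disease_variant_edges:
            assert view.edge_type_counts().get(DISEASE_VARIANT, 0) == 0
        order = rng.permutation(n_train)
        for lo in range(0, n_train, batch):
            idx = order[lo : lo + batch]
            Zd, enc_cache = gcn_encode(X, A_hat, state.encoder, training=True, rng=rng)
            probs, logits, dec_cache = decode_pairs(
                Zd[vi_tr[idx]], Zd[di_tr[idx]], state.decoder, training=True, rng=rng
            )
            scale = 1.0 if config.loss_reduction == "sum" else 1.0 / len(idx)
            dlogits = (probs - y_tr[idx]) * scale
            dec_grads, dP = mlp_backward(dec_cache, dlogits, state.decoder)
            d = Zd.shape[1]
            dZd = np.zeros_like(Zd)
            np.add.at(dZd, vi_tr[idx], dP[:, :d])
            np.add.at(dZd, di_tr[idx], dP[:, d:])
            enc_grads = gcn_backward(enc_cache, dZd, state.encoder)
            optimizer.step(state.arrays(), enc_grads + dec_grads)

        train_loss, val_loss = eval_losses()
        if not np.isfinite(train_loss) or not np.isfinite(val_loss):
            raise PathoKGError(
                f"non-finite loss at epoch {epoch} (lr={config.learning_rate}); "
                "training aborted"
            )
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = state.copy()
            history["best_epoch"] = epoch
            epochs_since_best = 0
        else:
            epochs_since_best += 1
        if verbose:
            print(
                f"epoch {epoch}: train_bce={train_loss:.4f} val_bce={val_loss:.4f}",
                file=sys.stderr,
            )
        if config.patience and epochs_since_best >= config.patience:
            break

    return best_state, history


def train_baseline(
    features: EmbeddingMatrix,
    split: DataSplit,
    config: TrainConfig,
    pair_input: bool = True,
) -> tuple[BaselineState, dict]:
    """Train a graph-free baseline network on raw embeddings.

    ``pair_input=True``: disease-specific baseline on concatenated raw
    (variant, disease) embeddings.  ``pair_input=False``: variant-only,
    non-disease-specific baseline; duplicate (variant, label) combinations
    collapse since the disease is ignored.
    """
    split.assert_disjoint()
    vi_tr, di_tr, y_tr = _pair_indices(split.train, features)
    vi_va, di_va, y_va = _pair_indices(split.validation, features)
    X = features.vectors.astype(config.np_dtype)
    y_tr = y_tr.astype(config.np_dtype)
    y_va = y_va.astype(config.np_dtype)

    state = BaselineState.init(
        X.shape[1], config.seed, pair_input=pair_input, dtype=config.np_dtype
    )
    optimizer = SGDOptimizer(config.learning_rate, config.weight_decay, config.momentum)
    rng = np.random.default_rng(config.seed)

    def batch_input(vidx, didx):
        return (X[vidx], X[didx]) if pair_input else (X[vidx], None)

    def eval_loss(vidx, didx, y):
        probs, _, _ = state.forward(*batch_input(vidx, didx), training=False)
        return bce_loss(probs, y)

    history: dict = {"train_loss": [], "val_loss": [], "best_epoch": None}
    best_state = state.copy()
    best_val = np.inf
    n_train = len(split.train)
    batch = config.batch_size or n_train
    epochs_since_best = 0

    for epoch in range(config.epochs):
        order = rng.permutation(n_train)
        for lo in range(0, n_train, batch):
            idx = order[lo : lo + batch]
            probs, logits, cache = state.forward(
                *batch_input(vi_tr[idx], di_tr[idx]), training=True, rng=rng
            )
            scale = 1.0 if config.loss_reduction == "sum" else 1.0 / len(idx)
            dlogits = (probs - y_tr[idx]) * scale
            grads, _ = mlp_backward(cache, dlogits, state.net)
            optimizer.step(state.arrays(), grads)
        train_loss = eval_loss(vi_tr, di_tr, y_tr)
        val_loss = eval_loss(vi_va, di_va, y_va)
        if not np.isfinite(train_loss) or not np.isfinite(val_loss):
            raise PathoKGError(f"non-finite loss at epoch {epoch}")
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = state.copy()
            history["best_epoch"] = epoch
            epochs_since_best = 0
        else:
            epochs_since_best += 1
        if config.patience and epochs_since_best >= config.patience:
            break
    return best_state, history


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def predict_pairs(
    state: ModelState,
    graph: HeteroGraph,
    features: EmbeddingMatrix,
    pairs: list[PairExample],
    config: TrainConfig,
) -> np.ndarray:
    """Evaluation-mode pair probabilities over the masked adjacency."""
    view = _training_view(graph, config)
    A_hat = normalized_adjacency(view)
    vi, di, _ = _pair_indices(pairs, features)
    return state.predict(features.vectors, A_hat, vi, di)


def evaluate(
    state: ModelState | BaselineState,
    graph: HeteroGraph | None,
    features: EmbeddingMatrix,
    pairs: list[PairExample],
    config: TrainConfig,
) -> EvalReport:
    """Score pairs, threshold at ``config.threshold``, and build an EvalReport.

    Probabilities exactly at the threshold classify as pathogenic
    (``p >= threshold``).
    """
    if not pairs:
        raise PathoKGError("cannot evaluate an empty pair list")
    _, _, y = _pair_indices(pairs, features)
    if isinstance(state, BaselineState):
        vi, di, _ = _pair_indices(pairs, features)
        X = features.vectors
        probs, _, _ = state.forward(
            X[vi], X[di] if state.pair_input else None, training=False
        )
    else:
        if graph is None:
            raise PathoKGError("graph required to evaluate the GCN model")
        probs = predict_pairs(state, graph, features, pairs, config)
    predicted = probs >= config.threshold
    cm = ConfusionMatrix.from_predictions(predicted, y.astype(bool))
    report = EvalReport.from_confusion(cm)
    report.extras["threshold"] = config.threshold
    report.extras["n_pairs"] = len(pairs)
    return report
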