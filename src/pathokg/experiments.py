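"""Canned end-to-end experiments on synthetic planted-signal data.

These are the package's reference workflows: generate a synthetic study,
build the pair dataset, split, train the graph model and/or the graph-free
baselines, and evaluate on the held-out test pairs.  They are what the
command-line ``run-all`` mode and the reproduction script execute.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from pathokg.metrics import EvalReport
from pathokg.pipeline import (
    DataSplit,
    TrainConfig,
    build_pairs,
    date_split,
    evaluate,
    per_gene_balanced_split,
    random_split,
    train,
    train_baseline,
)
from pathokg.synth import SynthConfig, SynthDataset, simulate


@dataclass
class ExperimentResult:
    dataset: SynthDataset
    split: DataSplit
    report: EvalReport
    history: dict
    model: object


def make_split(dataset: SynthDataset, config: TrainConfig) -> DataSplit:
    attachable = [v for v in dataset.variants if v.clinical_label in ("benign", "pathogenic")]
    if config.split_mode == "random":
        pos, neg, _ = build_pairs(dataset.graph, attachable)
        return random_split(pos + neg, seed=config.seed)
    if config.split_mode == "per_gene_balanced":
        return per_gene_balanced_split(attachable, dataset.graph, seed=config.seed)
    if config.split_mode == "date":
        return date_split(attachable, dataset.graph, seed=config.seed)
    raise ValueError(f"unknown split mode {config.split_mode!r}")


def run_gcn(
    synth_config: SynthConfig,
    train_config: TrainConfig | None = None,
    dataset: SynthDataset | None = None,
    split: DataSplit | None = None,
) -> ExperimentResult:
    """Train and evaluate the two-stage GCN+NN model on a synthetic study."""
    cfg = train_config or TrainConfig(seed=synth_config.seed)
    ds = dataset or simulate(synth_config)
    sp = split or make_split(ds, cfg)
    state, history = train(ds.graph, ds.embeddings, sp, cfg)
    report = evaluate(state, ds.graph, ds.embeddings, sp.test, cfg)
    return ExperimentResult(ds, sp, report, history, state)


def run_baseline(
    synth_config: SynthConfig,
    train_config: TrainConfig | None = None,
    pair_input: bool = True,
    dataset: SynthDataset | None = None,
    split: DataSplit | None = None,
) -> ExperimentResult:
    """Train and evaluate a graph-free baseline on the same synthetic study.

    ``pair_input=True`` is the disease-specific raw-embedding baseline;
    ``False`` is the variant-only, non-disease-specific baseline.
    """
    cfg = train_config or TrainConfig(seed=synth_config.seed)
    ds = dataset or simulate(synth_config)
    sp = split or make_split(ds, cfg)
    state, history = train_baseline(ds.embeddings, sp, cfg, pair_input=pair_input)
    report = evaluate(state, None, ds.embeddings, sp.test, cfg)
    return ExperimentResult(ds, sp, report, history, state)


def seed_sweep(
    base_synth: SynthConfig,
    seeds: list[int],
    train_config: TrainConfig | None = None,
    model: str = "gcn",
) -> list[ExperimentResult]:
    """Repeat an experiment over seeds (fresh data, split and init per seed)."""
    results = []
    for s in seeds:
        sc = replace(base_synth, seed=s)
        tc = replace(train_config or TrainConfig(), seed=s)
        if model == "gcn":
            results.append(run_gcn(sc, tc))
        elif model == "baseline_pair":
            results.append(run_baseline(sc, tc, pair_input=True))
        elif model == "baseline_variant":
            results.append(run_baseline(sc, tc, pair_input=False))
        else:
            raise ValueError(f"unknown model {model!r}")
    return results
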