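# Methods

This note documents the model, the procedures, the synthetic-data design and
the numerical choices behind `pathokg`, in the order the pipeline runs them.

## Graph construction

The knowledge graph is an undirected typed multigraph over twelve node types
(gene, protein, variant, disease, phenotype, drug, pathway, molecular
function, biological process, cellular component, exposure, anatomy) and a
closed edge-type vocabulary. Parallel edges of *different* types between the
same pair are allowed (a protein pair can carry both a temporal-PPI edge and
a co-expression edge); same-type duplicates collapse.

**Protein splitting.** Source graphs in the PrimeKG style use one protein
node per gene/protein unit. `split_protein_nodes` turns each into a (gene,
protein) pair joined by a protein–gene edge and rewires incident edges by the
token in the edge-type name: types naming a *Gene* endpoint (disease–gene,
pathway–gene, anatomy–gene, …) move to the new gene node; types naming a
*Protein* endpoint (all PPI subtypes, drug–protein) stay. The routing rule is
an implementation choice — nothing else in the vocabulary disambiguates it —
and is enforced by a property test (after splitting, no gene-endpoint edge
touches a protein).

**Variant attachment.** Each variant gets a node and a variant–gene edge;
each *pathogenic* variant also gets one disease–variant edge per associated
disease. Diseases are matched by name after whitespace trimming and case
folding; unmatched names create new disease nodes. No ontology normalization
is attempted. Attachment is idempotent.

**PPI temporal typing.** A protein pair's interaction is called *transient*
in one experiment when the time-course co-expression of the coding genes is
below 0.1 in that experiment, else *permanent*; the edge label is the strict
majority over experiments, *unlabeled* with no data, and an exact tie
resolves to permanent (the less volatile class — ties are not otherwise
defined). A second, tissue-level co-expression edge is binned into five
ordinal levels; the bin edges (−0.1, 0.1, 0.4, 0.7) are configuration values
chosen here, not a published constant.

**Masking.** Adjacency views hide a set of edge types without touching the
store. Disease–variant edges are the prediction target, so every adjacency
used in training or evaluation excludes them; the training loop re-asserts
this each epoch, and a diagnostics-only flag (`leak_disease_variant_edges`)
exists to *demonstrate* the leakage: with the mask off, training-pair
accuracy on a zero-signal dataset jumps from 0.50 to ≈0.95 — the model reads
the labels straight off the graph.

## Context-window extraction

Coordinates are 1-based inclusive. A window of length W nominally places the
variant at 0-based offset `W // 2`; a window overhanging a chromosome end by
`n` bases shifts by exactly `n` inward. Per class: snv substitutes the
alternative base; insertion splices the payload at the *window midpoint* and
trims `len(payload) // 2` bases from the left, the remainder from the right
(odd payloads lose the extra base on the 3′ side); deletion extracts an
extended window of length `W + len(segment)` centered on the segment middle
and excises the segment; indel composes deletion with insertion, aligning the
replacement payload to the same midpoint offset a pure insertion would
occupy — chosen so a 1-for-1 indel is exactly the snv extraction, for every
window parity. All four are pure functions, tested exhaustively against an
independent splice-the-whole-chromosome oracle (every position of a 200-base
chromosome, every W up to 50).

Real studies use W matched to the embedding model (12,282 for a
Nucleotide-Transformer-class model, 400 in fine-tuned settings, up to 10⁶
for long-context models); the library treats W as a required argument with no
silent default, and the toy pipelines here use W of a few dozen bases.

## Node features

Per-type text sources: variants use the fixed template
"`<class> located on chromosome <chrom> at position <pos> with reference
allele <ref> and alternative allele <alt>`" (or their genomic context window
when a sequence provider is configured); proteins use
"`Protein encoded by gene <symbol>`"; drug/disease nodes with multi-feature
descriptions are embedded per feature and averaged; everything else uses the
node name. Any deterministic string→vector callable satisfies the provider
contract; the built-in `HashEmbedder` (signed feature hashing of words or
overlapping 6-mers, scaled by `1/sqrt(tokens)`) is semantics-free but exact
and reproducible, which is what the pipeline tests need. Adapters for
pretrained text or DNA models plug in behind the same contract; nothing in
the package requires them.

Embeddings are L2-normalized per row (zero rows pass through — a guard, not
a convention with scientific content) and zero-padded on the right to the
widest type so one matrix feeds the encoder. Padding, rather than learned
per-type projections, is the simplest reading of a single shared first GCN
layer consuming mixed-width inputs (256/768/1024 variant widths vs 768 text
width in the real setting); a projection layer is a possible extension.

## Model

Encoder: 2-layer GCN over the symmetric normalized adjacency with self-loops,
`Â = D̃^{-1/2}(A+I)D̃^{-1/2}`, all unmasked edge types pooled homogeneously
and binarized. Hidden widths 256 then 64, ReLU after both layers, dropout 0.3
after each activation during training. Decoder: `[z_variant ; z_disease]`
(variant first) → 64 → 32 → 1 with ReLU + dropout 0.3 on hidden layers and a
sigmoid output. Baselines reuse the 3-layer family with hidden 256/64 on raw
embeddings (pair-input and variant-only versions). Biases are included
everywhere and initialized to zero; weights are Glorot-uniform from the run
seed. Classification threshold 0.5, with `p ≥ 0.5` classified pathogenic.

The row-sum bound often quoted for normalized adjacencies holds for the
random-walk form, not this symmetric form; the invariant actually enforced is
symmetry, entries in [0,1] and spectral radius ≤ 1.

All forward/backward passes are explicit numpy with hand-derived gradients,
validated against central finite differences to 1e-6 end to end (encoder
through decoder). Evaluation mode disables dropout and is bit-reproducible.

## Training

Pairs: positives = pathogenic variant × its diseases; negatives = benign
variant × its gene's disease neighbors (benign variants in genes with no
disease edge contribute nothing and are counted). Splits:

* **random** — seeded shuffle of pairs, 70/15/15 with floor-based sizes and
  the remainder to train;
* **per-gene balanced** — per gene, one variant reserved for validation and
  one for test, from different classes when both remain (reservation happens
  *before* balancing); remaining pairs are balanced exactly per gene at
  `min(pos, neg)` with surplus majority pairs held out and counted;
* **date** — pairs from variants submitted through 2022 split 80/20
  train/validation; 2023–2024 submissions form the test set; undated
  variants are excluded and counted.

Optimization is mini-batch SGD: learning rate 0.001, momentum 0.9, weight
decay 0.1, batch 64, up to 200 epochs with early stopping after 30 epochs
without validation improvement; the returned state is the epoch argmin of
validation binary cross-entropy (losses recorded with dropout off). Two
numerical choices matter and are deliberate:

* **Decoupled weight decay.** Folding a 0.1 decay into the momentum buffer
  amplifies it by 1/(1−0.9) = 10× and, at this learning rate, drives every
  weight to zero before the loss gradients can establish any signal (the
  output collapses to a constant). The decay is therefore applied directly
  to the weights (`p ← p − lr·(v + wd·p)`), which preserves the stated
  strength while letting the gradients compete. The classic coupled form
  remains available (`SGDOptimizer(coupled=True)`) for comparison.
* **Sum-reduced batch loss.** The per-batch gradient is the *sum* of
  per-pair BCE gradients, making the per-example update magnitude
  independent of batch size. With mean reduction at lr 0.001, parameter
  movement per epoch is orders of magnitude too small to learn in any
  reasonable budget at this data scale. Mean reduction is available via
  `TrainConfig(loss_reduction="mean")`.

Training arithmetic defaults to float32 (half the runtime, no effect on any
tested property); float64 is a config switch and is used in gradient checks.

## Evaluation statistics

Sensitivity, specificity, PPV, NPV from the confusion matrix, with undefined
rates reported as absent rather than zero; balanced accuracy =
(sensitivity + specificity)/2. Inference treats the balanced accuracy as a
proportion: successes = `round(balanced_accuracy × n_test)` (half away from
zero), feeding (a) a one-sided upper-tail exact binomial test against p = 0.5
— one-sided because the question is strictly "above chance" — and (b) a
Wilson score interval at 95%. A percentile bootstrap over (prediction, label)
pairs cross-checks the interval; replicates that lose a class are skipped.
The Wilson implementation is the closed form; tests compare it against
statsmodels and verify ≈95% empirical coverage (n = 500, p ∈ {0.5, 0.85},
10,000 draws).

## Synthetic data and what it shows

The generator replaces every external input: a uniform-random toy genome with
evenly spaced gene loci; a basic-graph knowledge graph (genes, 1:1 proteins,
pathways, 1–k diseases per gene, random PPI layer typed from simulated
co-expression), optionally extended with stub nodes of the remaining types; a
ClinVar-style variant table whose reference alleles are read off the genome
and whose labels, review statuses, origins and dates exercise every inclusion
filter and the date split; and per-node embeddings with a planted signal.

Defaults define the standard study: 50 genes, 2 diseases/gene, 40
variants/gene, pathogenic fraction 0.5, embedding width 32, signal strength
alpha = 0.9. Each disease carries a latent unit direction `u_d`; a pathogenic
variant's embedding is `sqrt(alpha)·u_d + sqrt(1−alpha)·noise`. Two modes:

* **direct** — disease nodes expose their own `u_d` as raw embedding, so
  even a graph-free model can match variant to disease;
* **relational** (default) — gene embeddings carry the mean direction of
  their diseases, *all disease nodes share one identical raw embedding*, and
  benign variants receive a decoy direction from another gene's diseases.
  The shared disease embedding is the crux: the raw input contains no
  disease identity at all (nothing to memorize), and a decoy direction on
  benign variants makes "has signal" uninformative — so discriminating a
  pair requires relating the variant's direction to the paired disease's
  gene context, which is reachable only through graph edges. This is what
  makes the graph model's advantage over the raw-embedding baseline
  structural rather than incidental, mirroring the qualitative finding that
  relational context carries the disease-specific signal.

Noise is isotropic Gaussian, mixed then renormalized, chosen for analyzable
separability.

What the generator does **not** emulate: real sequence-level signal (the
hashing embedder and the planted vectors carry no biology a DNA language
model would detect), allele-frequency structure, mutation spectra, ontology
structure among diseases, or the extreme class imbalance and annotation noise
of real ClinVar. Passing tests therefore demonstrate that the machinery —
graph construction, masking, training, splits, statistics — is correct and
that the model recovers a recoverable signal; they say nothing about
accuracy on real clinical data.

## Problem sizes and budgets

The reference suite and the reproduction script run the standard study at
100 training epochs and 3–5 independent seeds per condition — sizes chosen
so a full run completes in minutes on one CPU while leaving wide margins on
every tested property (balanced accuracy ≈ 0.92 ± 0.02 at alpha = 0.9 vs the
0.85 requirement; baseline at 0.50). The zero-signal control, the leakage
demonstration and the determinism check use 15–30 epochs, which is ample for
properties that do not require convergence.

## Known limitations

* The GCN treats all unmasked edge types as one homogeneous relation; an
  edge-type-aware (relational) convolution is an extension point. A
  configuration collapsing all PPI subtypes into one type exists
  (`collapse_ppi_types`) for ablations.
* Full-graph dense forward passes bound practical size to ~10⁵ nodes;
  neighbor sampling is out of scope.
* Insertion anchoring follows one dialect (payload inserted after the stated
  position; VCF-style anchored records normalized to it). Left-alignment of
  indels, liftover and structural variants are out of scope.
* Disease-name matching is string-based; two names for one disease become
  two nodes.
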