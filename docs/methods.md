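# Methods

## The model

`graphomics` embeds patients and molecular features — mRNAs, miRNAs,
circRNAs and methylation probes — as nodes of one undirected, multipartite
knowledge graph G = (V, E) and learns patient representations by sampled,
attention-weighted neighborhood aggregation.

**Graph.** Patient–feature edges carry the patient's normalized expression
of that feature (per-feature z-score by default), so expression acts as the
relationship measure between a patient and its molecular context.
Feature–feature edges come from curated regulatory relations — miRNA →
target gene, circRNA → sponged miRNA, methylation probe → annotated gene —
and carry weight 1. The edge-type vocabulary is closed (patient–mrna,
patient–mirna, patient–circrna, patient–probe, mirna–mrna, circrna–mirna,
probe–mrna); patient–patient edges never exist, so patients interact only
through shared molecular context. Although the regulatory relations are
directed biologically, the graph is stored undirected and the direction is
kept as edge-type metadata.

**Aggregation.** Every node starts from a fixed random embedding
h_u⁰ ~ N(0, I/d) with d = 100. One hop updates

    h_u^k = σ( Σ_{v ∈ N(u) ∪ {u}} α_uv · w_uv · W^k h_v^{k−1} )

where w_uv is the edge weight (1 for the self term and feature–feature
edges), σ is a rectifier on the hidden hop and identity on the final hop,
and N(u) is a sampled neighborhood capped at `neighbors_per_hop` (default
50). Two hops are applied, then an affine softmax layer on the patient
embeddings yields class probabilities; the whole stack is trained
end-to-end with cross-entropy loss and Adam (lr 1e-2, 200 epochs by
default). With the cap at or above the maximum degree the pass is
exhaustive and fully deterministic; one master seed derives the
initialization and sampling streams, so stochastic runs are bit-for-bit
reproducible.

Attention has two modes:

* `uniform` — α_uv = 1/|N(u) ∪ {u}|, which makes the update exactly the
  GraphSAGE mean aggregator over weighted messages (the package tests this
  identity to 1e-6 against an independently coded dense implementation);
* `learned` — a GAT-style additive score
  leakyReLU(a_dst(t)·W h_u + a_src(t)·W h_v) with one score-vector pair per
  edge type t (the self loop is its own type), softmax-normalized per
  destination. An optional multi-head variant averages the per-head
  softmax rows, and an optional `attention_score_weighting` flag
  additionally multiplies scores by the edge weight; both default off
  (measured to help neither prediction nor recovery — see "Design choices
  that were settled empirically").

## Design choices that were settled empirically

The two printed formulations of the update (mean over self ∪ neighbors vs
an attention-weighted sum over neighbors) are reconciled by including the
self node in the attention normalization set, so uniform attention with a
self loop reproduces the mean update exactly.

Three defaults were decided by measurement on synthetic cohorts rather
than by convention, and the alternatives remain available as flags:

* **Fixed vs trainable input embeddings.** Training the random input
  embeddings lets each patient memorize its label through its own
  embedding row: training accuracy reaches 1.0 while held-out accuracy
  stays at the majority rate. The default therefore keeps input embeddings
  fixed (the aggregation and classifier weights train); the patient's
  information then enters only through its expression-weighted edges, and
  held-out accuracy on planted-signal cohorts rises from chance to >0.9.
  `train_embeddings=True` re-enables trainable embeddings; the discovery
  protocol (below) uses it deliberately.
* **Neighborhood size.** With ~165 features per patient and ~20 of them
  informative, a 10-neighbor sample almost never contains the signal and
  training stalls; 50 neighbors per hop keeps the sampling regularization
  while letting the signal through.
* **Learning rate.** 1e-3 does not converge within 200 epochs at this
  scale; 1e-2 does, stably.

## Biomarker discovery

After training, each edge's attention weight is amplified by node
connectivity, score(u,v) = a(u,v) · √(deg(u)·deg(v)), the geometric mean
being symmetric in the pair and stable across graph scales; degrees are
counted on the full graph because sampling is a training device, not a
graph property. Edges above a threshold (99th percentile by default, or a
top-k rule) form candidate biomarker modules as connected components of
the kept edge set, with deterministic tie-breaking.

Two measurement choices matter here, both settled by experiment:

* **Deviation, not raw weight.** Across training restarts the optimizer is
  free to *suppress* an informative neighbor instead of amplifying it —
  the classifier simply flips the sign of the downstream weights, so
  per-run rankings of raw α are sign-unstable (recovery of planted
  features flipped between AUROC ≈ 1 and ≈ 0 across seeds). The magnitude
  of the deviation from the uninformative uniform weight,
  a(u,v) = |α_uv − 1/|N(u)||, is invariant to that sign and is the default
  attention measure for scoring (`centered=True`); the raw-α formula
  remains available (`centered=False`).
* **Ensembling restarts.** Which features a single run singles out is
  partly an accident of initialization; the planted-signal component is
  consistent. `ensemble_biomarker_scores` averages the centered scores
  over 2 restarts by default.

The discovery protocol trains with learned attention, trainable
embeddings and no self loops, transductively on all labels. Self loops
are removed because they provide a shortcut: a patient can carry its own
representation forward, leaving attention over the molecular neighbors
loss-irrelevant and therefore uninformative; with the shortcut removed,
all class information must flow through molecular edges. Trainable
embeddings are safe here (no held-out prediction is claimed) and necessary:
feature embeddings absorb the class structure of their expression
profiles, which is what makes the final-hop attention scores able to
distinguish informative features. First-hop attention can only read the
random initial embeddings and is capacity-limited; the final hop is
therefore the default scoring hop (exposed as a flag).

## The synthetic-data generator

Real cohorts of this kind are small and rarely deposited, so the package
ships a generator that plants a known regulatory cascade:

1. Root features — `n_informative` methylation probes, miRNAs and circRNAs
   each (default 5) — receive class-specific mean shifts: a random
   permutation of a centered ramp spanning ±`effect_size` (default 1.0)
   across the classes, so classes always differ when the effect is
   nonzero.
2. Methylation is simulated as Gaussian M-values (SD 1.5) and reported as
   beta values through the inverse logit, so betas always lie in (0, 1).
3. circRNAs sponge miRNAs: the reported miRNA level is the raw level minus
   `sponge_strength` (default 0.6) times the mean level of its sponging
   circRNAs — i.e. sponging destabilizes the miRNA, which also makes
   circRNA signal visible in the miRNA layer.
4. Genes are repressed by their promoter probes (M-value scale) and by
   their targeting miRNAs, each scaled by `repression_strength` (default
   0.6). Multiple probes on one gene are replicate reads of a single
   promoter state and are averaged; distinct miRNAs are independent
   repressors and their (centered) effects add.
5. Independent Gaussian noise with `noise_sd` (default 1.0, log-intensity
   scale) is added on every layer.

mRNA carries no roots of its own: its class signal arises purely through
the cascade, so integrating the layers is genuinely required to see the
full picture. The default cohort mirrors a small three-class etiology
study (8/14/8 patients); benchmark protocols scale the same 8:14:8 ratio
to n = 180 for stable estimates. The planted truth records both the roots
(the class-driving features) and every feature the cascade reaches.

What the generator does **not** emulate: array intensity distributions,
batch or chip effects, probe chemistry, heteroscedastic noise,
feature–feature correlation beyond the planted cascade, or realistic
feature counts (tens of thousands on real arrays). Passing tests therefore
show that the method recovers planted signal under idealized noise at desk
scale, not that it will perform equivalently on real array data.

## Probe quality control

Methylation probes are filtered in a fixed order, each removal reported
with the first rule that fired: SNP-overlapping probes, internal controls,
chrX/chrY probes, cross-reactive probes, probes with bead count < 3 in
more than 5% of samples, and probes with detection p > 0.05 in more than
1% of samples. Both rate thresholds are strict inequalities. The filter is
idempotent.

## Evaluation protocol

Baselines fit a gradient-boosted tree classifier (XGBoost, 100 trees,
depth 3, single-thread histogram method, seeded) on either one layer's raw
sample × feature matrix or on the GNN patient embeddings, under stratified
k-fold cross-validation (k = 5 by default), reporting accuracy, weighted
precision/recall/F1 and one-vs-rest macro AUC averaged over folds.

By default the GNN is retrained inside every fold with the held-out
patients' labels withheld; their expression edges remain in the graph
(standard transductive semi-supervised learning) but no label leaks —
verified by a test that corrupts held-out labels and checks the fitted
state is bit-identical. A `transductive=True` flag reproduces the simpler
train-on-all-labels protocol.

## Numerical details and degenerate inputs

Softmax computations subtract the per-row maximum; attention rows are
validated to sum to 1 within 1e-6. Constant features map to 0 under
z-scoring and 0.5 under min-max scaling. An isolated node aggregates from
itself even when self loops are off. A class absent from a training fold,
a probe missing from annotation, mismatched sample ids across layers, and
non-finite losses all raise typed errors (the command-line interface maps
them to distinct exit codes). Zero training epochs return the initial
state unchanged.

## Problem sizes

The shipped benchmark protocols use the n = 180 cohort above with a
60/30/15/60-feature network (~345 graph nodes, ~30,000 edges), 150
training epochs for prediction trials and 2 × 200 epochs for discovery
trials, and 10 trial seeds per experiment — sizes chosen so the full
benchmark battery completes in minutes on one CPU while leaving the
measured properties stable across seeds.

## Known limitations

* Attention-based recovery ranks the planted root features close to the
  information-theoretic ceiling measured by a per-feature one-way ANOVA
  oracle (~0.88 vs ~0.93 mean AUROC on the standard conditions), but
  features the cascade only weakly reaches remain hard for both.
* Learned attention does not improve *classification* over uniform
  attention on these cohorts; its value is interpretability (the discovery
  surface).
* The NumPy implementation is exact but not GPU-accelerated; graphs beyond
  ~10⁵ edges per hop will be slow to train.
* Multiclass AUC is one-vs-rest macro-averaged; with very small held-out
  folds a class can be absent and its one-vs-rest term is then dropped.
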