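# graphomics

Multi-omics knowledge-graph neural networks for patient classification and
attention-based biomarker discovery.

Small clinical cohorts profiled on several omics platforms at once — mRNA,
miRNA and circRNA expression plus genome-wide DNA methylation — are common
in translational studies such as stroke-etiology subtyping, where the
clinical question is which molecular interactions separate, say,
cardioembolic from atherothrombotic patients. Analyzing each layer alone
discards the regulatory couplings between them: promoter methylation
represses its gene, miRNAs repress their target mRNAs, and circRNAs sponge
miRNAs, de-repressing their targets. `graphomics` is for researchers who
want to exploit exactly those couplings: it integrates the layers on one
heterogeneous knowledge graph, classifies patients from learned graph
embeddings, and reads candidate biomarker modules out of the trained
attention weights.

## The model

Patients and molecular features are nodes of one undirected multipartite
graph G = (V, E). A patient–feature edge carries the patient's normalized
expression of that feature; feature–feature edges encode database-style
regulatory relations (miRNA → target gene, circRNA → sponged miRNA,
probe → annotated gene) with weight 1. Every node gets a random initial
embedding h_u⁰ ∈ R^d (d = 100) and is updated over two hops of sampled
neighborhood aggregation,

    h_u^k = σ( Σ_{v ∈ N(u) ∪ {u}} α_uv · w_uv · W^k h_v^{k−1} ),

where N(u) is a fixed-size sampled neighborhood (GraphSAGE-style), w_uv is
the edge weight, and the attention weight α_uv is either uniform,
α_uv = 1/|N(u) ∪ {u}| — which makes the update the mean aggregator — or a
learned GAT-style softmax score with per-edge-type parameters. A softmax
layer on the final patient embeddings predicts the class; everything is
trained end-to-end with cross-entropy and Adam.

For discovery, each edge's attention is amplified by node connectivity,
score(u,v) = a(u,v)·√(deg u · deg v), and edges above a threshold are
grouped into connected components — candidate biomarker modules spanning
the omics layers. See `docs/methods.md` for the full model description,
the synthetic-cohort generator, and the design choices.

Because cohorts of this kind are rarely deposited, the package ships a
first-class synthetic-data module that plants a known regulatory cascade
with class-specific root features, so every stage — probe QC, graph
construction, training, evaluation, biomarker recovery — is testable
against ground truth.

## Worked example

```python
import graphomics as go

# a regulatory network and a 3-class cohort with planted signal
network = go.simulate_network(n_genes=60, n_mirnas=30, n_circrnas=15,
                              n_probes=60, seed=7)
config  = go.CohortConfig(class_sizes=(48, 84, 48), effect_size=1.0, seed=7)
cohort  = go.simulate_cohort(network, config)

# fit the knowledge-graph GNN
model   = go.MultiOmicsGNN.from_cohort(cohort,
                                       config=go.TrainConfig(epochs=150, seed=7))
results = model.fit()
print(results.summary())

# cross-validated comparison against each single omics layer
table = go.compare_methods(cohort, k=5, seed=7,
                           train_config=go.TrainConfig(epochs=150, seed=7))
print(table.to_frame().round(2))

# biomarker modules from degree-amplified attention, scored against truth
scores  = go.ensemble_biomarker_scores(model.graph, cohort.labels,
                                       config=go.default_discovery_config(7))
modules = go.select_modules(scores, "percentile", 99)
report  = go.recovery_metrics(modules, cohort.truth, scores)
print(len(modules), round(report.auroc, 2))
```

Output:

```
Multi-omics knowledge-graph GNN
================================================
nodes: 345  edges: 29880  patients: 180
classes: atherothrombotic, cardioembolic, undetermined
hops: 2  embedding dim: 100  attention: uniform  self-loop: True
neighbors/hop: (50, 50)  epochs: 150  lr: 0.01
final loss: 0.5044
training accuracy: 1.000

           gnn_embeddings  raw_mrna  raw_mirna  raw_circrna  raw_methylation
accuracy             0.92      0.66       0.86         0.89             0.82
precision            0.93      0.67       0.87         0.89             0.83
recall               0.92      0.66       0.86         0.89             0.82
f1                   0.92      0.66       0.85         0.89             0.82
auc                  1.00      0.83       0.96         0.98             0.95
```

The comparison table is the headline readout: XGBoost on the fused graph
embeddings (92% five-fold accuracy here) beats the same classifier on any
single layer, because the class signal was deliberately split across the
methylation, miRNA and circRNA layers and only reaches mRNA through the
regulatory cascade. The discovery step then selects 4 modules and ranks
the planted root features against the background with AUROC 0.94.

The same pipeline runs from the shell:

```sh
graphomics simulate -c config.yaml -o data/      # write a cohort file set
graphomics run      -c config.yaml -o results/   # graph → train → biomarkers → CV
graphomics report   results/                     # render the tables
```

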