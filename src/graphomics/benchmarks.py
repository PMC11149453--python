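"""Standard synthetic study conditions and benchmark trials.

One place defines the cohort the package's headline properties are measured
on: a three-class stroke-etiology-shaped cohort (class ratio 8:14:8 scaled
to n = 180 for stable estimates), a regulatory network of 60 genes, 30
miRNAs, 15 circRNAs and 60 methylation probes, five informative root
features per root layer with a standardized effect of 1.0, and the default
cascade strengths.  The trial functions below run the three headline
experiments — held-out learning signal, integration advantage over single
layers, and planted-biomarker recovery — for one trial seed each, so test
suites and scripts report numbers from identical protocols.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synthetic as syn
from .biomarkers import (default_discovery_config, ensemble_biomarker_scores,
                         recovery_metrics, select_modules, RecoveryReport)
from .evaluation import compare_methods, gnn_heldout_accuracy
from .model import TrainConfig, cohort_graph

STUDY_NETWORK = dict(n_genes=60, n_mirnas=30, n_circrnas=15, n_probes=60,
                     targets_per_mirna=3, sponges_per_circ=2)
STUDY_CLASS_SIZES = (48, 84, 48)   # the 8:14:8 etiology ratio at n = 180

#: epochs used by the benchmark trials (enough for convergence at this scale)
TRIAL_EPOCHS = 150
DISCOVERY_RESTARTS = 2
DISCOVERY_EPOCHS = 200


def trial_seeds(master_seed: int, n_trials: int, stream: int = 0) -> list[int]:
    """Independent per-trial seeds derived from one master seed (< 2^31)."""
    ss = np.random.SeedSequence([int(master_seed), int(stream)])
    return [int(s) for s in ss.generate_state(n_trials) >> 1]


def study_cohort(seed: int, effect_size: float = 1.0,
                 class_sizes=STUDY_CLASS_SIZES) -> syn.SyntheticCohort:
    """One draw of the standard study conditions."""
    net_seed, cohort_seed = trial_seeds(seed, 2, stream=1)
    network = syn.simulate_network(**STUDY_NETWORK, seed=net_seed)
    config = syn.CohortConfig(class_sizes=class_sizes,
                              effect_size=effect_size, seed=cohort_seed)
    return syn.simulate_cohort(network, config)


def learning_signal_trial(seed: int, effect_size: float = 1.0,
                          epochs: int = TRIAL_EPOCHS) -> tuple[float, float]:
    """Held-out softmax accuracy of the GNN vs the majority-class rate."""
    cohort = study_cohort(seed, effect_size=effect_size)
    cfg = TrainConfig(epochs=epochs, seed=seed)
    return gnn_heldout_accuracy(cohort, cfg, seed=seed)


def integration_trial(seed: int, epochs: int = TRIAL_EPOCHS,
                      k: int = 5) -> pd.DataFrame:
    """Cross-validated metric panels: GNN embeddings vs each raw layer."""
    cohort = study_cohort(seed)
    cfg = TrainConfig(epochs=epochs, seed=seed)
    return compare_methods(cohort, k=k, seed=seed, train_config=cfg).to_frame()


def recovery_trial(seed: int, n_restarts: int = DISCOVERY_RESTARTS,
                   epochs: int = DISCOVERY_EPOCHS,
                   percentile: float = 99.0) -> RecoveryReport:
    """Planted-biomarker recovery under the ensembled discovery protocol."""
    cohort = study_cohort(seed)
    graph = cohort_graph(cohort)
    cfg = default_discovery_config(seed, epochs=epochs)
    scores = ensemble_biomarker_scores(graph, cohort.labels, config=cfg,
                                       n_restarts=n_restarts)
    modules = select_modules(scores, "percentile", percentile)
    return recovery_metrics(modules, cohort.truth, scores)
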