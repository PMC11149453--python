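"""Synthetic regulatory networks and patient cohorts with planted class signal.

Real multi-omics stroke cohorts of the kind this package targets are small
and rarely deposited, so every downstream stage (graph construction, GNN
training, biomarker recovery) is exercised on simulated data with known
ground truth.  The generative model follows the textbook regulatory logic
the knowledge graph encodes:

* promoter methylation of a probe represses its annotated gene;
* a miRNA represses the mRNAs it targets;
* a circRNA sponges miRNAs, lowering their effective level and thereby
  de-repressing their target mRNAs.

Class signal is planted only at the *roots* of this cascade (selected
probes, miRNAs and circRNAs); mRNA-level signal arises purely through
propagation, so integrating the layers is genuinely required to see the
full picture.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import io
from .errors import InputError
from .graph import OmicsMatrix

DEFAULT_CLASS_NAMES = ("atherothrombotic", "cardioembolic", "undetermined")

#: baseline mean / sd of log-intensity layers and of methylation M-values
_EXPR_BASE_MEAN, _EXPR_BASE_SD = 8.0, 1.0
_MVAL_BASE_SD = 1.5


@dataclass
class RegulatoryNetwork:
    """Planted feature sets and the directed regulatory relations among them."""

    gene_ids: list[str]
    mirna_ids: list[str]
    circrna_ids: list[str]
    probe_ids: list[str]
    mirna_targets: list[tuple[str, str]]   # miRNA -> gene
    circ_sponges: list[tuple[str, str]]    # circRNA -> miRNA
    probe_genes: list[tuple[str, str]]     # probe -> gene (exactly one per probe)
    probe_annotation: pd.DataFrame         # chromosome, snp_overlap, cross_reactive, is_control

    def validate(self) -> None:
        genes, mirnas = set(self.gene_ids), set(self.mirna_ids)
        circs, probes = set(self.circrna_ids), set(self.probe_ids)
        for name, table, src_set, tgt_set in (
            ("mirna_targets", self.mirna_targets, mirnas, genes),
            ("circ_sponges", self.circ_sponges, circs, mirnas),
            ("probe_genes", self.probe_genes, probes, genes),
        ):
            if len(set(table)) != len(table):
                raise InputError(f"duplicate pairs in {name}")
            for s, t in table:
                if s not in src_set or t not in tgt_set:
                    raise InputError(f"{name}: unknown endpoint in pair ({s!r}, {t!r})")
        probe_srcs = [s for s, _ in self.probe_genes]
        if sorted(probe_srcs) != sorted(self.probe_ids):
            raise InputError("each probe must map to exactly one gene")
        if set(self.probe_annotation.index) != probes:
            raise InputError("probe_annotation must cover exactly the probe ids")

    def targets_of_mirna(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for m, g in self.mirna_targets:
            out.setdefault(m, []).append(g)
        return out

    def sponges_of_mirna(self) -> dict[str, list[str]]:
        """miRNA -> list of circRNAs that sponge it."""
        out: dict[str, list[str]] = {}
        for c, m in self.circ_sponges:
            out.setdefault(m, []).append(c)
        return out

    def gene_of_probe(self) -> dict[str, str]:
        return dict(self.probe_genes)


def simulate_network(
    n_genes: int,
    n_mirnas: int,
    n_circrnas: int,
    n_probes: int,
    targets_per_mirna: int = 3,
    sponges_per_circ: int = 2,
    seed: int = 0,
    sex_fraction: float = 0.0,
    snp_fraction: float = 0.0,
    cross_reactive_fraction: float = 0.0,
    control_fraction: float = 0.0,
) -> RegulatoryNetwork:
    """Draw a random regulatory network.

    Each miRNA targets ``targets_per_mirna`` distinct genes; each circRNA
    sponges ``sponges_per_circ`` distinct miRNAs; each probe annotates one
    gene.  The annotation fractions assign exact counts of probes to
    chrX/chrY, SNP overlap, cross-reactivity and internal-control status
    (disjointly, in that priority order), so QC outcomes are predictable.
    """
    for name, val in (("n_genes", n_genes), ("n_mirnas", n_mirnas),
                      ("n_circrnas", n_circrnas), ("n_probes", n_probes),
                      ("targets_per_mirna", targets_per_mirna),
                      ("sponges_per_circ", sponges_per_circ)):
        if int(val) != val or val < 1:
            raise InputError(f"{name} must be a positive integer, got {val!r}")
    if targets_per_mirna > n_genes:
        raise InputError("targets_per_mirna cannot exceed n_genes")
    if sponges_per_circ > n_mirnas:
        raise InputError("sponges_per_circ cannot exceed n_mirnas")
    for name, frac in (("sex_fraction", sex_fraction), ("snp_fraction", snp_fraction),
                       ("cross_reactive_fraction", cross_reactive_fraction),
                       ("control_fraction", control_fraction)):
        if not 0 <= frac <= 1:
            raise InputError(f"{name} must lie in [0, 1], got {frac!r}")

    rng = np.random.default_rng(seed)
    genes = [f"gene{i:04d}" for i in range(n_genes)]
    mirnas = [f"mir{i:04d}" for i in range(n_mirnas)]
    circs = [f"circ{i:04d}" for i in range(n_circrnas)]
    probes = [f"cg{i:05d}" for i in range(n_probes)]

    mirna_targets = [(m, genes[j])
                     for m in mirnas
                     for j in sorted(rng.choice(n_genes, targets_per_mirna, replace=False))]
    circ_sponges = [(c, mirnas[j])
                    for c in circs
                    for j in sorted(rng.choice(n_mirnas, sponges_per_circ, replace=False))]
    probe_genes = [(p, genes[int(j)]) for p, j in zip(probes, rng.integers(0, n_genes, n_probes))]

    n_snp = round(snp_fraction * n_probes)
    n_ctrl = round(control_fraction * n_probes)
    n_sex = round(sex_fraction * n_probes)
    n_cross = round(cross_reactive_fraction * n_probes)
    if n_snp + n_ctrl + n_sex + n_cross > n_probes:
        raise InputError("annotation fractions sum to more than the probe count")
    order = rng.permutation(n_probes)
    snp_set = set(order[:n_snp])
    ctrl_set = set(order[n_snp:n_snp + n_ctrl])
    sex_set = set(order[n_snp + n_ctrl:n_snp + n_ctrl + n_sex])
    cross_set = set(order[n_snp + n_ctrl + n_sex:n_snp + n_ctrl + n_sex + n_cross])
    autosomes = [f"chr{c}" for c in range(1, 23)]
    chroms = []
    for i in range(n_probes):
        if i in sex_set:
            chroms.append("chrX" if rng.random() < 0.5 else "chrY")
        else:
            chroms.append(autosomes[int(rng.integers(0, 22))])
    annotation = pd.DataFrame({
        "chromosome": chroms,
        "snp_overlap": [i in snp_set for i in range(n_probes)],
        "cross_reactive": [i in cross_set for i in range(n_probes)],
        "is_control": [i in ctrl_set for i in range(n_probes)],
    }, index=pd.Index(probes, name="probe_id"))

    net = RegulatoryNetwork(genes, mirnas, circs, probes, mirna_targets,
                            circ_sponges, probe_genes, annotation)
    net.validate()
    return net


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort.

    ``effect_size`` is the standardized mean shift applied to each
    informative root feature (spread across classes as a centered ±pattern);
    ``repression_strength`` scales both methylation->gene and miRNA->gene
    suppression; ``sponge_strength`` scales circRNA de-repression of
    miRNAs; ``noise_sd`` is the residual standard deviation on every layer
    (log-intensity / M-value scale).
    """

    class_sizes: tuple[int, ...] = (8, 14, 8)
    class_names: tuple[str, ...] | None = None
    effect_size: float = 1.0
    n_informative: int = 5
    repression_strength: float = 0.6
    sponge_strength: float = 0.6
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_sizes = tuple(int(c) for c in self.class_sizes)
        if len(self.class_sizes) < 2:
            raise InputError("at least two classes are required")
        if any(c <= 0 for c in self.class_sizes):
            raise InputError("every class must have at least one patient")
        if self.class_names is None:
            if len(self.class_sizes) == len(DEFAULT_CLASS_NAMES):
                self.class_names = DEFAULT_CLASS_NAMES
            else:
                self.class_names = tuple(f"class{i}" for i in range(len(self.class_sizes)))
        if len(self.class_names) != len(self.class_sizes):
            raise InputError("class_names length must match class_sizes")
        for name in ("repression_strength", "sponge_strength"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InputError(f"{name} must lie in [0, 1], got {v!r}")
        if self.noise_sd <= 0:
            raise InputError(f"noise_sd must be positive, got {self.noise_sd!r}")
        if self.effect_size < 0:
            raise InputError("effect_size must be non-negative")
        if self.n_informative < 1:
            raise InputError("n_informative must be at least 1")

    @property
    def n_patients(self) -> int:
        return sum(self.class_sizes)

    @classmethod
    def large(cls, per_class: int = 60, **kw) -> "CohortConfig":
        """Balanced three-class cohort big enough for stable training checks."""
        return cls(class_sizes=(per_class,) * 3, **kw)


@dataclass
class CohortTruth:
    """Planted signal: informative features per node type and cascade edges."""

    features: dict[str, set[str]]          # node type -> ids carrying class signal
    roots: dict[str, set[str]]             # node type -> root ids that received shifts
    edges: set[tuple[str, str]]            # planted cascade pairs (source id, target id)

    def all_features(self) -> set[tuple[str, str]]:
        return {(t, f) for t, ids in self.features.items() for f in ids}


@dataclass
class SyntheticCohort:
    matrices: dict[str, OmicsMatrix]
    labels: pd.Series
    truth: CohortTruth
    network: RegulatoryNetwork
    config: CohortConfig

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)


def _class_shift_patterns(n_features: int, n_classes: int, effect: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Per-feature class-mean shifts: a random permutation of a centered
    ramp spanning ±effect, so classes always differ when effect > 0."""
    base = np.linspace(-1.0, 1.0, n_classes) * effect
    return np.stack([rng.permutation(base) for _ in range(n_features)])


def simulate_cohort(network: RegulatoryNetwork, config: CohortConfig) -> SyntheticCohort:
    """Generate one cohort through the planted regulatory cascade.

    Roots (``n_informative`` probes, miRNAs and circRNAs each) receive
    class-specific mean shifts of magnitude up to ``effect_size``.  Levels
    then propagate: circRNAs lower the miRNAs they sponge
    (``sponge_strength`` x mean sponging-circRNA level); genes are repressed
    by their promoter probes (M-value scale) and by the effective level of
    their targeting miRNAs (``repression_strength`` each).  Methylation is
    simulated as Gaussian M-values and reported as beta values in (0, 1);
    the reported miRNA matrix is the post-sponging effective level.
    """
    network.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    samples = [f"P{i:03d}" for i in range(n)]
    labels = pd.Series(
        np.repeat(list(config.class_names), config.class_sizes),
        index=pd.Index(samples, name="sample_id"), name="label")
    class_idx = np.repeat(np.arange(len(config.class_sizes)), config.class_sizes)

    def pick_roots(ids: list[str]) -> list[str]:
        if config.n_informative > len(ids):
            raise InputError(
                f"n_informative={config.n_informative} exceeds available features ({len(ids)})")
        sel = rng.choice(len(ids), config.n_informative, replace=False)
        return [ids[int(i)] for i in sorted(sel)]

    root_probes = pick_roots(network.probe_ids)
    root_mirnas = pick_roots(network.mirna_ids)
    root_circs = pick_roots(network.circrna_ids)

    def layer_values(ids: list[str], roots: list[str], base_mean: float,
                     base_sd: float) -> pd.DataFrame:
        k = len(ids)
        base = rng.normal(base_mean, base_sd, size=k)[:, None]
        shifts = np.zeros((k, n))
        patterns = _class_shift_patterns(len(roots), len(config.class_sizes),
                                         config.effect_size, rng)
        pos = {f: i for i, f in enumerate(ids)}
        for r, pat in zip(roots, patterns):
            shifts[pos[r]] = pat[class_idx]
        noise = rng.normal(0.0, config.noise_sd, size=(k, n))
        return pd.DataFrame(base + shifts + noise, index=ids, columns=samples)

    # roots and residual noise, before cascade propagation
    circ = layer_values(network.circrna_ids, root_circs, _EXPR_BASE_MEAN, _EXPR_BASE_SD)
    mirna_raw = layer_values(network.mirna_ids, root_mirnas, _EXPR_BASE_MEAN, _EXPR_BASE_SD)
    mvals = layer_values(network.probe_ids, root_probes, 0.0, _MVAL_BASE_SD)

    # circRNA sponging: effective miRNA = raw - sponge_strength * mean(sponging circRNAs)
    sponges = network.sponges_of_mirna()
    mirna_eff = mirna_raw.copy()
    for m, cs in sponges.items():
        mirna_eff.loc[m] = mirna_raw.loc[m] - config.sponge_strength * circ.loc[cs].mean(axis=0)

    # gene expression: baseline minus methylation and miRNA repression
    probes_of_gene: dict[str, list[str]] = {}
    for p, gtarget in network.probe_genes:
        probes_of_gene.setdefault(gtarget, []).append(p)
    mirnas_of_gene: dict[str, list[str]] = {}
    for m, gtarget in network.mirna_targets:
        mirnas_of_gene.setdefault(gtarget, []).append(m)

    k = len(network.gene_ids)
    base = rng.normal(_EXPR_BASE_MEAN, _EXPR_BASE_SD, size=k)[:, None]
    noise = rng.normal(0.0, config.noise_sd, size=(k, n))
    gene_vals = base + noise
    genes = pd.DataFrame(gene_vals, index=network.gene_ids, columns=samples)
    # probes on one gene are replicate reads of a single promoter state
    # (mean); distinct miRNAs are independent repressors (sum)
    for gname in network.gene_ids:
        if gname in probes_of_gene:
            genes.loc[gname] -= config.repression_strength * mvals.loc[probes_of_gene[gname]].mean(axis=0)
        if gname in mirnas_of_gene:
            genes.loc[gname] -= config.repression_strength * (
                mirna_eff.loc[mirnas_of_gene[gname]] - _EXPR_BASE_MEAN).sum(axis=0)

    beta = pd.DataFrame(expit(mvals.to_numpy()), index=mvals.index, columns=mvals.columns)

    matrices = {
        "mrna": OmicsMatrix("mrna", genes, "log-intensity"),
        "mirna": OmicsMatrix("mirna", mirna_eff, "log-intensity"),
        "circrna": OmicsMatrix("circrna", circ, "log-intensity"),
        "methylation": OmicsMatrix("methylation", beta, "beta"),
    }

    truth = _propagate_truth(network, root_probes, root_mirnas, root_circs)
    return SyntheticCohort(matrices=matrices, labels=labels, truth=truth,
                           network=network, config=config)


def _propagate_truth(network: RegulatoryNetwork, root_probes: list[str],
                     root_mirnas: list[str], root_circs: list[str]) -> CohortTruth:
    """Features reached from the roots through the planted cascade."""
    targets = network.targets_of_mirna()
    gene_of = network.gene_of_probe()

    mirnas = set(root_mirnas)
    edges: set[tuple[str, str]] = set()
    for c, m in network.circ_sponges:
        if c in set(root_circs):
            mirnas.add(m)
            edges.add((c, m))
    genes: set[str] = set()
    for p in root_probes:
        genes.add(gene_of[p])
        edges.add((p, gene_of[p]))
    for m in mirnas:
        for gtarget in targets.get(m, []):
            genes.add(gtarget)
            edges.add((m, gtarget))
    features = {
        "probe": set(root_probes),
        "mirna": mirnas,
        "circrna": set(root_circs),
        "mrna": genes,
    }
    roots = {"probe": set(root_probes), "mirna": set(root_mirnas),
             "circrna": set(root_circs)}
    return CohortTruth(features=features, roots=roots, edges=edges)


# ---------------------------------------------------------------------------
# on-disk round trip

LAYER_FILES = {"mrna": "mrna.tsv", "mirna": "mirna.tsv",
               "circrna": "circrna.tsv", "methylation": "methylation.tsv"}
ASSOC_FILES = {
    "mirna_targets": ("mirna_targets.tsv", "mirna", "mrna"),
    "circ_sponges": ("circ_sponges.tsv", "circrna", "mirna"),
    "probe_genes": ("probe_genes.tsv", "probe", "mrna"),
}


def write_cohort(cohort: SyntheticCohort, directory: str | os.PathLike) -> list[str]:
    """Write matrices, association tables, labels, annotation and truth;
    returns the list of file names written (all TSV/JSON text)."""
    import json

    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    written = []
    for layer, fname in LAYER_FILES.items():
        io.write_matrix(os.path.join(directory, fname), layer, cohort.matrices[layer].data)
        written.append(fname)
    net = cohort.network
    for attr, (fname, st, tt) in ASSOC_FILES.items():
        io.write_edge_table(os.path.join(directory, fname), st, tt, getattr(net, attr))
        written.append(fname)
    io.write_labels(os.path.join(directory, "labels.tsv"), cohort.labels)
    written.append("labels.tsv")
    net.probe_annotation.to_csv(os.path.join(directory, "probe_annotation.tsv"), sep="\t")
    written.append("probe_annotation.tsv")
    truth_obj = {
        "features": {t: sorted(ids) for t, ids in cohort.truth.features.items()},
        "roots": {t: sorted(ids) for t, ids in cohort.truth.roots.items()},
        "edges": sorted(map(list, cohort.truth.edges)),
    }
    with open(os.path.join(directory, "truth.json"), "w") as fh:
        json.dump(truth_obj, fh, indent=1, sort_keys=True)
    written.append("truth.json")
    return written


def read_cohort_files(directory: str | os.PathLike):
    """Load the matrices, association tables and labels written by
    :func:`write_cohort`; returns (matrices dict, associations list, labels)."""
    from .graph import AssociationTable

    directory = os.fspath(directory)
    matrices = {}
    for layer, fname in LAYER_FILES.items():
        data = io.read_matrix(os.path.join(directory, fname))
        scale = "beta" if layer == "methylation" else "log-intensity"
        matrices[layer] = OmicsMatrix(layer, data, scale)
    associations = []
    for fname, st, tt in ASSOC_FILES.values():
        src, tgt, pairs = io.read_edge_table(os.path.join(directory, fname))
        associations.append(AssociationTable(src, tgt, pairs))
    labels = io.read_labels(os.path.join(directory, "labels.tsv"))
    return matrices, associations, labels
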