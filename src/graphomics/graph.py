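"""Omics-layer QC, normalization, and knowledge-graph assembly.

The knowledge graph is a multipartite undirected graph over patients and
four molecular feature types (mRNA, miRNA, circRNA, methylation probes).
Patient--feature edges carry the patient's normalized expression value for
that feature; feature--feature edges come from curated association tables
(miRNA targets, circRNA sponges, probe-to-gene annotation) with weight 1.
Patient--patient edges never exist: patients interact only through shared
molecular context.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
import pandas as pd
import scipy.sparse as sp

from . import io
from .errors import InputError

logger = logging.getLogger(__name__)

LAYERS = ("mrna", "mirna", "circrna", "methylation")

#: node type used for methylation-probe nodes (the layer is "methylation",
#: but the graph entity is the probe)
LAYER_NODE_TYPE = {"mrna": "mrna", "mirna": "mirna", "circrna": "circrna",
                   "methylation": "probe"}

ALLOWED_EDGE_TYPES = frozenset({
    frozenset({"patient", "mrna"}),
    frozenset({"patient", "mirna"}),
    frozenset({"patient", "circrna"}),
    frozenset({"patient", "probe"}),
    frozenset({"mirna", "mrna"}),
    frozenset({"circrna", "mirna"}),
    frozenset({"probe", "mrna"}),
})

QC_REASONS = ("snp_overlap", "control", "sex_chromosome", "cross_reactive",
              "bead_count", "detection_p")

SEX_CHROMOSOMES = {"chrX", "chrY", "X", "Y"}


@dataclass
class OmicsMatrix:
    """One omics layer: a features x samples value matrix with a layer tag.

    ``value_scale`` is ``"log-intensity"`` for the expression layers,
    ``"beta"`` for methylation fractions in [0, 1], or the name of the
    normalization applied by :func:`normalize_layer`.
    """

    layer: str
    data: pd.DataFrame
    value_scale: str = "log-intensity"

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise InputError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise InputError(f"duplicate feature id {dup!r} in layer {self.layer}")
        if self.value_scale == "beta":
            vals = self.data.to_numpy(float)
            if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
                raise InputError("beta values must lie in [0, 1]")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(float)


@dataclass
class AssociationTable:
    """Typed directed feature-feature pairs (one knowledge-graph relation)."""

    source_type: str
    target_type: str
    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.source_type == self.target_type:
            raise InputError("association source and target types must differ")
        for s, t in self.pairs:
            if s == t:
                raise InputError(f"self pair ({s!r}, {t!r}) in association table")
        # deduplicate preserving order
        seen: set[tuple[str, str]] = set()
        unique = []
        for p in self.pairs:
            if p not in seen:
                seen.add(p)
                unique.append(p)
        self.pairs = unique


@dataclass
class ProbeQCReport:
    """Outcome of methylation probe filtering: reason per removed probe."""

    removed: dict[str, str]
    n_retained: int

    def counts(self) -> dict[str, int]:
        out = {r: 0 for r in QC_REASONS}
        for reason in self.removed.values():
            out[reason] += 1
        return out


def filter_methylation_probes(
    matrix: OmicsMatrix,
    annotation: pd.DataFrame,
    bead_counts: pd.DataFrame | None = None,
    detection_p: pd.DataFrame | None = None,
) -> tuple[OmicsMatrix, ProbeQCReport]:
    """Apply standard EPIC-array probe QC and return (filtered matrix, report).

    Rules fire in a fixed order and each removed probe is reported with the
    first reason that triggered: probes overlapping common SNPs, internal
    control probes, probes on chrX/chrY, cross-reactive probes, probes with
    bead count < 3 in more than 5% of samples, and probes with detection
    p-value > 0.05 in more than 1% of samples.

    ``annotation`` is indexed by probe id with boolean columns
    ``snp_overlap``, ``cross_reactive``, optional ``is_control``, and a
    ``chromosome`` column. ``bead_counts`` / ``detection_p`` are
    probe x sample frames aligned to ``matrix``; omitting one skips that rule.
    """
    if matrix.layer != "methylation":
        raise InputError(f"probe QC applies to the methylation layer, got {matrix.layer!r}")
    missing = [p for p in matrix.feature_ids if p not in annotation.index]
    if missing:
        raise InputError(f"probe {missing[0]!r} missing from annotation")
    for name, frame in (("bead_counts", bead_counts), ("detection_p", detection_p)):
        if frame is not None:
            if set(frame.index) < set(matrix.feature_ids) or list(frame.columns) != matrix.sample_ids:
                raise InputError(f"{name} matrix not aligned to the methylation matrix")

    removed: dict[str, str] = {}
    n_samples = len(matrix.sample_ids)
    for probe in matrix.feature_ids:
        ann = annotation.loc[probe]
        if bool(ann.get("snp_overlap", False)):
            removed[probe] = "snp_overlap"
        elif bool(ann.get("is_control", False)):
            removed[probe] = "control"
        elif str(ann.get("chromosome", "")) in SEX_CHROMOSOMES:
            removed[probe] = "sex_chromosome"
        elif bool(ann.get("cross_reactive", False)):
            removed[probe] = "cross_reactive"
        elif bead_counts is not None and (
            (bead_counts.loc[probe].to_numpy(float) < 3).mean() > 0.05
        ):
            removed[probe] = "bead_count"
        elif detection_p is not None and (
            (detection_p.loc[probe].to_numpy(float) > 0.05).mean() > 0.01
        ):
            removed[probe] = "detection_p"
    keep = [p for p in matrix.feature_ids if p not in removed]
    out = OmicsMatrix(matrix.layer, matrix.data.loc[keep], matrix.value_scale)
    logger.info("probe QC: removed %d of %d probes (%d samples)",
                len(removed), len(matrix.feature_ids), n_samples)
    return out, ProbeQCReport(removed=removed, n_retained=len(keep))


NORMALIZE_METHODS = ("zscore_per_feature", "minmax_per_feature", "none")


def normalize_layer(matrix: OmicsMatrix, method: str = "zscore_per_feature") -> OmicsMatrix:
    """Normalize each feature row across samples.

    ``zscore_per_feature`` maps constant rows to all zeros;
    ``minmax_per_feature`` maps constant rows to 0.5.
    """
    if method not in NORMALIZE_METHODS:
        raise InputError(f"unknown normalization method {method!r}; "
                         f"expected one of {NORMALIZE_METHODS}")
    if method == "none":
        return OmicsMatrix(matrix.layer, matrix.data.copy(), matrix.value_scale)
    vals = matrix.values
    if method == "zscore_per_feature":
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, keepdims=True)
        # rows constant up to float rounding of the mean count as constant
        nonconst = sd > 1e-13 * np.abs(mu)
        out = np.divide(vals - mu, sd, out=np.zeros_like(vals),
                        where=nonconst & (sd > 0))
    else:
        lo = vals.min(axis=1, keepdims=True)
        hi = vals.max(axis=1, keepdims=True)
        rng = hi - lo
        out = np.divide(vals - lo, rng, out=np.full_like(vals, 0.5), where=rng > 0)
    data = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return OmicsMatrix(matrix.layer, data, value_scale=method)


def load_association_table(path: str | os.PathLike, source_type: str,
                           target_type: str) -> AssociationTable:
    """Load a two-column edge table, checking the header against the expected types."""
    src, tgt, pairs = io.read_edge_table(path)
    if (src, tgt) != (source_type, target_type):
        raise InputError(
            f"{path}: header types ({src!r}, {tgt!r}) do not match expected "
            f"({source_type!r}, {target_type!r})"
        )
    return AssociationTable(source_type, target_type, pairs)


class HeteroGraph:
    """Multipartite patient-feature knowledge graph.

    Nodes are (type, id) pairs mapped to integer indices; edges are
    undirected and typed, each carrying a weight. Internally a CSR adjacency
    over both edge directions supports neighbor lookup and sampling.
    """

    def __init__(self) -> None:
        self.node_types: list[str] = []
        self.node_ids: list[str] = []
        self.node_index: dict[tuple[str, str], int] = {}
        self._src: list[int] = []
        self._dst: list[int] = []
        self._weight: list[float] = []
        self._etype: list[str] = []
        self._csr: sp.csr_matrix | None = None
        self.labels: pd.Series | None = None

    # -- construction -----------------------------------------------------
    def add_node(self, ntype: str, nid: str) -> int:
        key = (ntype, nid)
        if key in self.node_index:
            return self.node_index[key]
        idx = len(self.node_ids)
        self.node_index[key] = idx
        self.node_types.append(ntype)
        self.node_ids.append(nid)
        self._csr = None
        return idx

    def add_edge(self, u: int, v: int, weight: float) -> None:
        tu, tv = self.node_types[u], self.node_types[v]
        if u == v:
            raise InputError("self edges are not allowed in the knowledge graph")
        pair = frozenset({tu, tv})
        if pair not in ALLOWED_EDGE_TYPES:
            raise InputError(f"edge type ({tu}, {tv}) is not allowed")
        self._src.append(u)
        self._dst.append(v)
        self._weight.append(float(weight))
        self._etype.append("-".join(sorted((tu, tv))))
        self._csr = None

    # -- views -------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def m(self) -> int:
        return len(self._src)

    @property
    def edges(self) -> pd.DataFrame:
        return pd.DataFrame({
            "u": np.asarray(self._src, dtype=int),
            "v": np.asarray(self._dst, dtype=int),
            "weight": np.asarray(self._weight, dtype=float),
            "edge_type": self._etype,
        })

    def node_label(self, idx: int) -> str:
        return f"{self.node_types[idx]}:{self.node_ids[idx]}"

    @property
    def patient_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.node_types, dtype=object) == "patient")

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric weighted adjacency A (cached)."""
        if self._csr is None:
            src = np.asarray(self._src + self._dst, dtype=int)
            dst = np.asarray(self._dst + self._src, dtype=int)
            w = np.asarray(self._weight + self._weight, dtype=float)
            self._csr = sp.csr_matrix((w, (src, dst)), shape=(self.n, self.n))
        return self._csr

    def degrees(self) -> np.ndarray:
        """Neighbor counts per node on the full graph (no self loops)."""
        adj = self.adjacency()
        return np.diff(adj.indptr)

    def neighbors(self, u: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (neighbor indices, edge weights) of node ``u``."""
        adj = self.adjacency()
        sl = slice(adj.indptr[u], adj.indptr[u + 1])
        return adj.indices[sl], adj.data[sl]

    def directed_messages(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Both directions of every edge as (dst, src, weight) arrays,
        sorted by destination — the message list consumed by aggregation."""
        dst = np.concatenate([self._src, self._dst]).astype(int) if self.m else np.empty(0, int)
        src = np.concatenate([self._dst, self._src]).astype(int) if self.m else np.empty(0, int)
        w = np.concatenate([self._weight, self._weight]).astype(float) if self.m else np.empty(0)
        order = np.argsort(dst, kind="stable")
        return dst[order], src[order], w[order]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i in range(self.n):
            g.add_node(i, ntype=self.node_types[i], nid=self.node_ids[i])
        for u, v, w, t in zip(self._src, self._dst, self._weight, self._etype):
            g.add_edge(u, v, weight=w, edge_type=t)
        return g

    # -- persistence -------------------------------------------------------
    def save(self, directory: str | os.PathLike) -> None:
        """Write nodes.tsv / edges.tsv (+labels.tsv) for later reload."""
        directory = os.fspath(directory)
        os.makedirs(directory, exist_ok=True)
        nodes = pd.DataFrame({"node_type": self.node_types, "node_id": self.node_ids})
        nodes.to_csv(os.path.join(directory, "nodes.tsv"), sep="\t", index_label="index")
        edges = self.edges
        edges.to_csv(os.path.join(directory, "edges.tsv"), sep="\t", index=False,
                     float_format="%.12g")
        if self.labels is not None:
            io.write_labels(os.path.join(directory, "labels.tsv"), self.labels)

    @classmethod
    def load(cls, directory: str | os.PathLike) -> "HeteroGraph":
        directory = os.fspath(directory)
        nodes = pd.read_csv(os.path.join(directory, "nodes.tsv"), sep="\t", index_col=0)
        edges = pd.read_csv(os.path.join(directory, "edges.tsv"), sep="\t")
        g = cls()
        for _, row in nodes.iterrows():
            g.add_node(str(row["node_type"]), str(row["node_id"]))
        for _, row in edges.iterrows():
            g.add_edge(int(row["u"]), int(row["v"]), float(row["weight"]))
        labels_path = os.path.join(directory, "labels.tsv")
        if os.path.exists(labels_path):
            g.labels = io.read_labels(labels_path)
        return g


def build_graph(
    matrices: list[OmicsMatrix],
    associations: list[AssociationTable] = (),
    labels: pd.Series | None = None,
    normalize: str = "zscore_per_feature",
    top_k_per_patient: int | None = None,
) -> HeteroGraph:
    """Assemble the knowledge graph from normalized layers and associations.

    Patient--feature edges take the (normalized) expression value as weight,
    one edge per (patient, feature); optional ``top_k_per_patient`` keeps
    only the k largest-|weight| features per patient per layer. Association
    pairs referencing unknown feature ids are dropped with a logged count;
    retained pairs become feature--feature edges with weight 1.
    """
    if not matrices:
        raise InputError("at least one omics layer is required")
    ref = matrices[0].sample_ids
    for mat in matrices[1:]:
        if set(mat.sample_ids) != set(ref):
            diff = sorted(set(mat.sample_ids) ^ set(ref))
            raise InputError(
                f"sample ids differ between layers {matrices[0].layer!r} and "
                f"{mat.layer!r}; symmetric difference: {diff}"
            )
    if labels is not None:
        extra = sorted(set(labels.index) ^ set(ref))
        if extra:
            raise InputError(f"labels do not match sample ids; difference: {extra}")

    g = HeteroGraph()
    for sid in ref:
        g.add_node("patient", sid)

    seen_layers = set()
    for mat in matrices:
        if mat.layer in seen_layers:
            raise InputError(f"duplicate layer {mat.layer!r}")
        seen_layers.add(mat.layer)
        norm = normalize_layer(mat, normalize)
        # align sample order to the patient node order
        vals = norm.data[ref].to_numpy(float)
        ntype = LAYER_NODE_TYPE[mat.layer]
        fidx = np.array([g.add_node(ntype, f) for f in norm.feature_ids], dtype=int)
        if top_k_per_patient is not None and top_k_per_patient < len(fidx):
            for j, sid in enumerate(ref):
                col = vals[:, j]
                keep = np.argsort(-np.abs(col), kind="stable")[:top_k_per_patient]
                for i in sorted(keep):
                    g.add_edge(j, int(fidx[i]), col[i])
        else:
            for i in range(len(fidx)):
                for j in range(len(ref)):
                    g.add_edge(j, int(fidx[i]), vals[i, j])

    for table in associations:
        st = LAYER_NODE_TYPE.get(table.source_type, table.source_type)
        tt = LAYER_NODE_TYPE.get(table.target_type, table.target_type)
        dropped = 0
        for s, t in table.pairs:
            su, tv = g.node_index.get((st, s)), g.node_index.get((tt, t))
            if su is None or tv is None:
                dropped += 1
                continue
            g.add_edge(su, tv, 1.0)
        if dropped:
            logger.info("association %s->%s: dropped %d pairs with unknown ids",
                        table.source_type, table.target_type, dropped)

    if labels is not None:
        g.labels = labels.reindex(ref)
    return g
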