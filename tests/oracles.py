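"""Independent, loop-based reference implementations used by the tests.

Everything here is written against the mathematical definitions directly
(dense matrices, explicit Python loops, one node at a time) and shares no
code with the package's vectorized message-passing path.
"""

from __future__ import annotations

import numpy as np

LEAKY_SLOPE = 0.2


def _act(name: str, x: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(x, 0.0)
    return x


def _neighbor_lists(graph):
    """Adjacency as {node: [(neighbor, weight), ...]} from the edge table."""
    nbrs = {u: [] for u in range(graph.n)}
    for _, row in graph.edges.iterrows():
        u, v, w = int(row["u"]), int(row["v"]), float(row["weight"])
        nbrs[u].append((v, w))
        nbrs[v].append((u, w))
    return nbrs


def dense_forward(graph, H0, layer_params, *, self_loop=True,
                  attention_mode="uniform", score_weighting=False):
    """Exhaustive multi-hop aggregation computed node by node.

    Per hop, each node u aggregates over its full neighborhood (plus itself
    when ``self_loop``; an isolated node always keeps itself):

    * uniform: h_u' = act(W . sum_m alpha w_m h_m) with alpha = 1/|members|
      — the mean-aggregation update over weighted messages;
    * learned (single head): scores leaky(a_dst[t].Wh_u + a_src[t].Wh_v)
      per edge type t (optionally times the edge weight), softmax over the
      members, then the same weighted sum.

    Returns (H_final, attention per hop as {(u, v): alpha}).
    """
    import graphomics.model as gm

    nbrs = _neighbor_lists(graph)
    etype_codes = gm._etype_codes(graph)
    et_lookup = {}
    for _, row in graph.edges.iterrows():
        u, v = int(row["u"]), int(row["v"])
        code = etype_codes[row["edge_type"]]
        et_lookup[(u, v)] = code
        et_lookup[(v, u)] = code
    self_code = etype_codes[gm.SELF_EDGE_TYPE]

    H = np.asarray(H0, dtype=float)
    attn_hops = []
    for lp in layer_params:
        W = lp.W
        Z = np.array([W @ H[i] for i in range(graph.n)])
        H_next = np.zeros((graph.n, W.shape[0]))
        attn = {}
        for u in range(graph.n):
            members = list(nbrs[u])
            if self_loop or not members:
                members = members + [(u, 1.0)]
            if attention_mode == "uniform":
                alphas = [1.0 / len(members)] * len(members)
            else:
                def canon(a):
                    a = np.asarray(a, dtype=float)
                    if a.ndim == 1:
                        return a[None]
                    if a.ndim == 3:   # single-head oracle
                        return a[0]
                    return a
                a_dst, a_src = canon(lp.att_dst), canon(lp.att_src)
                n_et = a_dst.shape[0]
                scores = []
                for v, w in members:
                    t = (self_code if v == u else et_lookup[(u, v)]) % n_et
                    raw = float(a_dst[t] @ Z[u] + a_src[t] @ Z[v])
                    s = raw if raw > 0 else LEAKY_SLOPE * raw
                    if score_weighting:
                        s *= w
                    scores.append(s)
                scores = np.array(scores)
                e = np.exp(scores - scores.max())
                alphas = e / e.sum()
            total = np.zeros(W.shape[0])
            for (v, w), a in zip(members, alphas):
                total += a * w * Z[v]
                attn[(u, v)] = attn.get((u, v), 0.0) + float(a)
            H_next[u] = _act(lp.activation, total)
        H = H_next
        attn_hops.append(attn)
    return H, attn_hops


def mean_update(h_u, neighbors, W, activation="identity"):
    """Eq-style mean aggregation computed longhand."""
    stack = [np.asarray(h_u, float)] + [np.asarray(v, float) for v in neighbors]
    m = np.zeros_like(stack[0])
    for v in stack:
        m = m + v
    m = m / len(stack)
    return _act(activation, np.asarray(W, float) @ m)


def random_hetero_graph(rng, max_nodes=20):
    """A random small typed graph with random weights, built edge by edge."""
    from graphomics.graph import HeteroGraph

    g = HeteroGraph()
    n_pat = int(rng.integers(2, 5))
    n_mrna = int(rng.integers(1, 6))
    n_mirna = int(rng.integers(1, 4))
    n_circ = int(rng.integers(1, 3))
    n_probe = int(rng.integers(1, 4))
    pats = [g.add_node("patient", f"P{i}") for i in range(n_pat)]
    mrnas = [g.add_node("mrna", f"g{i}") for i in range(n_mrna)]
    mirnas = [g.add_node("mirna", f"m{i}") for i in range(n_mirna)]
    circs = [g.add_node("circrna", f"c{i}") for i in range(n_circ)]
    probes = [g.add_node("probe", f"cg{i}") for i in range(n_probe)]
    for p in pats:
        for group in (mrnas, mirnas, circs, probes):
            for f in group:
                if rng.random() < 0.6:
                    g.add_edge(p, f, float(rng.normal()))
    for m in mirnas:
        for t in mrnas:
            if rng.random() < 0.4:
                g.add_edge(m, t, 1.0)
    for c in circs:
        for m in mirnas:
            if rng.random() < 0.4:
                g.add_edge(c, m, 1.0)
    for pr in probes:
        if rng.random() < 0.7:
            g.add_edge(pr, mrnas[int(rng.integers(0, n_mrna))], 1.0)
    return g
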