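"""Independent reference implementations used to check the package.

Everything here is deliberately brute-force and shares no code with the
implementation under test: d-separation CI oracles, exhaustive enumeration
of tier-respecting Markov-equivalent DAGs, all-paths betweenness counting,
and exactly conditional-Gaussian null generators for calibration studies.
"""

from __future__ import annotations

from itertools import combinations, product
from types import SimpleNamespace

import networkx as nx
import numpy as np
import pandas as pd


class DSepOracle:
    """CI handle answering from d-separation in a known DAG (p is 0 or 1)."""

    def __init__(self, graph: nx.DiGraph):
        self.graph = graph

    def test(self, x, y, s=()):
        sep = nx.is_d_separator(self.graph, {x}, {y}, set(s))
        return SimpleNamespace(x=x, y=y, s=tuple(s), p=1.0 if sep else 0.0, statistic=0.0, df=1)


def v_structures(edges) -> set:
    """Canonical (min, w, max) triples u->w<-v with u, v non-adjacent."""
    g = nx.DiGraph(list(edges))
    adj = {frozenset(e) for e in edges}
    out = set()
    for w in g.nodes:
        for u, v in combinations(sorted(g.predecessors(w)), 2):
            if frozenset((u, v)) not in adj:
                out.add((u, w, v))
    return out


def tiered_cpdag_bruteforce(edges, tiers: dict) -> tuple[set, set]:
    """Orientation intersection over all tier-respecting DAGs Markov-equivalent
    to the DAG given by ``edges``.

    Enumerates every orientation of the skeleton, keeps those that are
    acyclic, respect the tiers, and share the truth's v-structures, then
    intersects edge directions.  Returns (directed set, undirected frozenset
    set).  Exponential in the edge count; only for small graphs.
    """
    edges = list(edges)
    skel = [tuple(sorted(e)) for e in {frozenset(e) for e in edges}]
    target_vs = v_structures(edges)
    nodes = sorted(tiers)
    members = []
    for bits in product((0, 1), repeat=len(skel)):
        cand = [(a, b) if bit == 0 else (b, a) for (a, b), bit in zip(skel, bits)]
        if any(tiers[p] > tiers[c] for p, c in cand):
            continue
        g = nx.DiGraph(cand)
        g.add_nodes_from(nodes)
        if not nx.is_directed_acyclic_graph(g):
            continue
        if v_structures(cand) != target_vs:
            continue
        members.append(set(cand))
    assert members, "truth must be a member of its own equivalence class"
    directed, undirected = set(), set()
    for a, b in skel:
        if all((a, b) in m for m in members):
            directed.add((a, b))
        elif all((b, a) in m for m in members):
            directed.add((b, a))
        else:
            undirected.add(frozenset((a, b)))
    return directed, undirected


def random_tiered_dag(rng: np.random.Generator, n_nodes: int, n_tiers: int = 3, p_edge: float = 0.4):
    """A random DAG over ``n_nodes`` with random tier labels; edges respect
    tiers and, within a tier, a fixed topological order."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    tiers = {v: int(rng.integers(0, n_tiers)) for v in nodes}
    order = sorted(nodes, key=lambda v: (tiers[v], v))
    edges = []
    for i, u in enumerate(order):
        for v in order[i + 1 :]:
            if rng.random() < p_edge:
                edges.append((u, v))
    return nodes, tiers, edges


def brute_betweenness(nodes, directed_edges) -> dict:
    """Betweenness by exhaustive simple-path enumeration.

    For each ordered (s, t), enumerates all simple directed paths, keeps the
    shortest length, and credits interior nodes with the fraction of
    shortest paths through them.
    """
    succ = {v: [] for v in nodes}
    for u, v in directed_edges:
        succ[u].append(v)

    def all_paths(s, t):
        paths, stack = [], [(s, [s])]
        while stack:
            v, path = stack.pop()
            if v == t:
                paths.append(path)
                continue
            for w in succ[v]:
                if w not in path:
                    stack.append((w, path + [w]))
        return paths

    scores = {v: 0.0 for v in nodes}
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            paths = all_paths(s, t)
            if not paths:
                continue
            shortest = min(len(p) for p in paths)
            sp = [p for p in paths if len(p) == shortest]
            for p in sp:
                for v in p[1:-1]:
                    scores[v] += 1.0 / len(sp)
    return scores


# -- exactly conditional-Gaussian null generators -----------------------------------


def cg_null_dataset(kind_x: str, kind_y: str, n_cond: int, n: int, rng: np.random.Generator):
    """Sample (x, y, S) with x independent of y given S from an exactly
    conditional-Gaussian joint distribution.

    The first conditioning variable mediates the x-y dependence; extra
    conditioning variables are independent N(0, 1) noise.  Binary variables
    are always upstream of continuous ones so the joint stays in the CG
    family (binary block multinomial, continuous Gaussian given it).

    Returns (DataFrame, kinds dict, conditioning names).
    """
    cols, kinds = {}, {}
    s_names = [f"s{i}" for i in range(n_cond)]
    if n_cond == 0:
        cols["x"] = _root(kind_x, n, rng)
        cols["y"] = _root(kind_y, n, rng)
    elif kind_x == "binary" and kind_y == "binary":
        s = (rng.random(n) < 0.5).astype(float)
        px = np.where(s == 1, 0.7, 0.3)
        py = np.where(s == 1, 0.65, 0.35)
        cols["x"] = (rng.random(n) < px).astype(float)
        cols["y"] = (rng.random(n) < py).astype(float)
        cols[s_names[0]] = s
        kinds[s_names[0]] = "binary"
    else:
        # put any binary endpoint at the root: bin -> s_cont -> other
        first, second = ("x", kind_x), ("y", kind_y)
        if kind_y == "binary":
            first, second = second, first
        root = _root(first[1], n, rng)
        s = 0.8 * root + rng.normal(size=n)
        leaf = 0.6 * s + rng.normal(size=n)
        cols[first[0]] = root
        cols[second[0]] = leaf
        cols[s_names[0]] = s
        kinds[s_names[0]] = "continuous"
    for nm in s_names[1:]:
        cols[nm] = rng.normal(size=n)
        kinds[nm] = "continuous"
    kinds["x"], kinds["y"] = kind_x, kind_y
    return pd.DataFrame(cols), kinds, s_names


def _root(kind: str, n: int, rng: np.random.Generator):
    if kind == "binary":
        return (rng.random(n) < 0.5).astype(float)
    return rng.normal(size=n)
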