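"""Tiered PC: constraint-based structure learning with temporal background knowledge.

Variables carry temporal tiers (e.g. baseline exposure, baseline biomarkers,
follow-up outcome).  The learner runs a PC-stable skeleton sweep whose
conditioning candidates respect the tiers, then orients:

1. every cross-tier edge from the earlier to the later tier,
2. v-structures from the recorded separating sets,
3. Meek rules 1-4 to closure.

Tier knowledge always dominates: an orientation rule that would demand a
later -> earlier edge is recorded as a conflict and skipped, and the tier
invariant (no directed edge against the tier order) is asserted after every
orientation step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from .cohort import CohortTable
from .mixed_ci import CGTester

__all__ = ["TieredPDAG", "learn_skeleton", "orient_edges", "tpc"]


@dataclass
class TieredPDAG:
    """Partially directed graph over tiered variables with sepset bookkeeping."""

    nodes: list[str]
    tiers: dict[str, int]
    directed: set = field(default_factory=set)  # (u, v) ordered pairs
    undirected: set = field(default_factory=set)  # frozenset pairs
    sepsets: dict = field(default_factory=dict)  # frozenset pair -> set
    conflicts: list = field(default_factory=list)
    audit: list = field(default_factory=list)  # (x, y, s, p) for every CI test

    # -- structure queries -------------------------------------------------------

    def adjacent(self, u: str) -> set:
        out = {v for a, v in self.directed if a == u}
        out |= {a for a, v in self.directed if v == u}
        out |= {next(iter(e - {u})) for e in self.undirected if u in e}
        return out

    def has_edge(self, u: str, v: str) -> bool:
        return (u, v) in self.directed or (v, u) in self.directed or frozenset((u, v)) in self.undirected

    def directed_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed)
        return g

    def skeleton_edges(self) -> set:
        return {frozenset(e) for e in self.directed} | set(self.undirected)

    def has_directed_path(self, u: str, v: str) -> bool:
        return nx.has_path(self.directed_graph(), u, v) if u in self.tiers and v in self.tiers else False

    # -- invariants --------------------------------------------------------------

    def assert_sound(self) -> None:
        """Hard invariants: acyclic directed part, tier-respecting edges,
        disjoint edge sets, no cross-tier undirected edge."""
        for u, v in self.directed:
            if self.tiers[u] > self.tiers[v]:
                raise AssertionError(f"directed edge {u}->{v} violates tiers")
            if frozenset((u, v)) in self.undirected or (v, u) in self.directed:
                raise AssertionError(f"edge {u}-{v} recorded twice")
        for e in self.undirected:
            a, b = tuple(e)
            if self.tiers[a] != self.tiers[b]:
                raise AssertionError(f"undirected edge {a}-{b} crosses tiers")
        if not nx.is_directed_acyclic_graph(self.directed_graph()):
            raise AssertionError("directed subgraph is cyclic")

    def copy(self) -> "TieredPDAG":
        return TieredPDAG(
            list(self.nodes),
            dict(self.tiers),
            set(self.directed),
            set(self.undirected),
            {k: set(v) for k, v in self.sepsets.items()},
            list(self.conflicts),
            list(self.audit),
        )

    # -- export ------------------------------------------------------------------

    def to_graphml(self, path: str) -> None:
        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(n, tier=self.tiers[n])
        for u, v in self.directed:
            g.add_edge(u, v, oriented="yes")
        for e in self.undirected:
            a, b = sorted(e)
            g.add_edge(a, b, oriented="no")
        nx.write_graphml(g, path)

    def to_dot(self, path: str) -> None:
        lines = ["digraph pdag {"]
        for n in self.nodes:
            lines.append(f'  "{n}" [tier={self.tiers[n]}];')
        for u, v in sorted(self.directed):
            lines.append(f'  "{u}" -> "{v}";')
        for e in sorted(self.undirected, key=sorted):
            a, b = sorted(e)
            lines.append(f'  "{a}" -> "{b}" [dir=none, style=dashed];')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


# -- skeleton ---------------------------------------------------------------------


def learn_skeleton(ci, nodes, tiers: dict[str, int], alpha: float, max_cond: int | None = None):
    """PC-stable skeleton search under tier constraints.

    ``ci`` is any object with ``test(x, y, s) -> result`` exposing ``.p``.
    Conditioning candidates for a pair (u, v) are drawn from the current
    adjacencies of u or v, excluding nodes in tiers strictly later than both
    endpoints (such nodes cannot d-separate them).  Deletions within one
    conditioning-set size use the adjacency snapshot taken at the start of
    that size, making the skeleton order-independent.

    Returns ``(adjacency dict, sepsets dict, audit list)``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    nodes = sorted(nodes)
    for u in nodes:
        if u not in tiers:
            raise ValueError(f"no tier assigned to node {u!r}")
    adj: dict[str, set] = {u: set(nodes) - {u} for u in nodes}
    sepsets: dict[frozenset, set] = {}
    audit: list[tuple] = []
    level = 0
    while True:
        snapshot = {u: sorted(adj[u]) for u in nodes}
        any_candidates = False
        for u in nodes:
            for v in sorted(adj[u]):
                if u >= v or v not in adj[u]:
                    continue
                removed = False
                for a, b in ((u, v), (v, u)):
                    cands = [
                        w
                        for w in snapshot[a]
                        if w != b and tiers[w] <= max(tiers[u], tiers[v])
                    ]
                    if len(cands) >= level:
                        any_candidates = True
                    for s in combinations(cands, level):
                        res = ci.test(u, v, s)
                        audit.append((u, v, s, res.p))
                        if res.p > alpha:
                            adj[u].discard(v)
                            adj[v].discard(u)
                            sepsets[frozenset((u, v))] = set(s)
                            removed = True
                            break
                    if removed:
                        break
        level += 1
        if not any_candidates or (max_cond is not None and level > max_cond):
            break
    return adj, sepsets, audit


# -- orientation ------------------------------------------------------------------


def _try_orient(pdag: TieredPDAG, u: str, v: str, reason: str) -> bool:
    """Orient u-v as u->v if legal; record a conflict otherwise."""
    if (u, v) in pdag.directed:
        return False
    if (v, u) in pdag.directed:
        pdag.conflicts.append(f"{reason}: wanted {u}->{v} but {v}->{u} already oriented")
        return False
    e = frozenset((u, v))
    if e not in pdag.undirected:
        return False
    if pdag.tiers[u] > pdag.tiers[v]:
        pdag.conflicts.append(f"{reason}: wanted {u}->{v} against tier order; tier constraint wins")
        return False
    if pdag.has_directed_path(v, u):
        pdag.conflicts.append(f"{reason}: orienting {u}->{v} would create a directed cycle")
        return False
    pdag.undirected.discard(e)
    pdag.directed.add((u, v))
    pdag.assert_sound()
    return True


def orient_edges(adj: dict, sepsets: dict, tiers: dict[str, int]) -> TieredPDAG:
    """Orient a skeleton: tier edges, v-structures, then Meek rules 1-4."""
    nodes = sorted(adj)
    pdag = TieredPDAG(nodes=nodes, tiers=dict(tiers), sepsets={k: set(v) for k, v in sepsets.items()})
    for u in nodes:
        for v in sorted(adj[u]):
            if u < v:
                if tiers[u] < tiers[v]:
                    pdag.directed.add((u, v))
                elif tiers[v] < tiers[u]:
                    pdag.directed.add((v, u))
                else:
                    pdag.undirected.add(frozenset((u, v)))
    pdag.assert_sound()

    # v-structures: unshielded u - w - v with w outside sepset(u, v)
    for w in nodes:
        neigh = sorted(adj[w])
        for u, v in combinations(neigh, 2):
            if v in adj[u]:
                continue  # shielded
            sep = sepsets.get(frozenset((u, v)))
            if sep is None or w in sep:
                continue
            _try_orient(pdag, u, w, f"v-structure {u}->{w}<-{v}")
            _try_orient(pdag, v, w, f"v-structure {u}->{w}<-{v}")

    _meek_closure(pdag, adj)
    pdag.assert_sound()
    return pdag


def _meek_closure(pdag: TieredPDAG, adj: dict) -> None:
    """Apply Meek rules 1-4 until fixpoint."""
    changed = True
    while changed:
        changed = False
        for e in sorted(pdag.undirected, key=sorted):
            a, b = sorted(e)
            for x, y in ((a, b), (b, a)):
                if _meek_applies(pdag, adj, x, y):
                    if _try_orient(pdag, x, y, "meek"):
                        changed = True
                    break
            if changed:
                break


def _meek_applies(pdag: TieredPDAG, adj: dict, a: str, b: str) -> bool:
    """Would any of Meek rules 1-4 orient the undirected edge a-b as a->b?"""
    directed = pdag.directed
    # R1: c->a, a-b, c and b non-adjacent  =>  a->b
    for c, t in directed:
        if t == a and b not in adj[c]:
            return True
    # R2: a->c->b with a-b  =>  a->b
    for c in adj[a]:
        if (a, c) in directed and (c, b) in directed:
            return True
    # R3: a-c, a-d, c->b, d->b, c and d non-adjacent  =>  a->b
    und_neighbors = [
        next(iter(e - {a})) for e in pdag.undirected if a in e and next(iter(e - {a})) != b
    ]
    into_b = [c for c in und_neighbors if (c, b) in directed]
    for c, d in combinations(sorted(into_b), 2):
        if d not in adj[c]:
            return True
    # R4: a-c, c->d, d->b, c and b non-adjacent  =>  a->b
    for c in und_neighbors:
        if b in adj[c]:
            continue
        for d in adj[c]:
            if (c, d) in directed and (d, b) in directed:
                return True
    return False


# -- composition ------------------------------------------------------------------


def tpc(
    table: CohortTable | None = None,
    tiers: dict[str, int] | None = None,
    alpha: float = 0.05,
    ci=None,
    max_cond: int | None = None,
) -> TieredPDAG:
    """Run the full tiered PC algorithm.

    Either ``table`` (from which a cached conditional-Gaussian tester is
    built) or a ready ``ci`` handle must be given.  Every CI test performed
    is logged to the result's ``audit`` list as ``(x, y, s, p)``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if ci is None:
        if table is None:
            raise ValueError("either a cohort table or a CI handle is required")
        ci = CGTester(table)
    if tiers is None:
        if table is None:
            raise ValueError("tiers are required when no table is given")
        tiers = table.tiers
    nodes = list(tiers) if table is None else table.names
    adj, sepsets, audit = learn_skeleton(ci, nodes, tiers, alpha, max_cond)
    pdag = orient_edges(adj, sepsets, tiers)
    pdag.audit = audit
    return pdag
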