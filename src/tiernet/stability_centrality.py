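"""Edge stability under resampling and centrality-based mediator nomination.

Robustness of a learned network is quantified by rerunning the tiered PC
algorithm on bootstrap resamples taken at several sample drop rates (default
100 iterations at each of 0%, 10% and 20% dropped, i.e. 300 graphs) and
recording how often each directed edge reappears.  A parallel sensitivity
sweep refits the network at several significance levels with a shared CI
cache, so an edge's presence flags across alphas are exactly monotone.

Mediator nomination follows the betweenness rule: nodes whose betweenness
centrality in the directed part of the network exceeds the mean, and which
lie on at least one directed exposure -> outcome path, are nominated as
candidate mediators.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import CohortTable
from .mixed_ci import CGTester
from .tiered_pc import TieredPDAG, tpc

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeStabilityReport",
    "CentralityResult",
    "bootstrap_stability",
    "alpha_sensitivity",
    "betweenness",
    "nominate_mediators",
    "render_frequency",
    "stable_edges",
]

PRESENT, ABSENT = "✔", "–"  # ✔ / – as in the stability table


def render_frequency(freq: float) -> str:
    """Render a bootstrap frequency the way the stability table prints it
    (``1.0`` -> ``"100%"``, ``0.997`` -> ``"99.7%"``)."""
    return f"{round(100.0 * freq, 1):g}%"


@dataclass
class EdgeStabilityReport:
    """Per-directed-edge bootstrap frequencies plus per-alpha presence flags."""

    frequencies: dict  # (u, v) -> fraction of graphs containing u->v
    n_graphs: int
    drop_rates: list
    alpha: float
    seed: int
    alpha_flags: dict = field(default_factory=dict)  # (u, v) -> tuple[bool, ...]
    alphas: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for e, f in self.frequencies.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency out of range for edge {e}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (u, v), f in sorted(self.frequencies.items(), key=lambda kv: (-kv[1], kv[0])):
            row = {"cause": u, "effect": v}
            flags = self.alpha_flags.get((u, v))
            for i, a in enumerate(self.alphas):
                present = bool(flags[i]) if flags is not None else False
                row[f"alpha_{a:g}"] = PRESENT if present else ABSENT
            row["frequency"] = f
            row["frequency_pct"] = render_frequency(f)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path: str) -> None:
        # %.17g keeps the frequency column exactly float-roundtrippable
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_stability_report(path: str, n_graphs: int, drop_rates, alpha: float, seed: int) -> EdgeStabilityReport:
    """Reconstruct an :class:`EdgeStabilityReport` from its emitted TSV."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    alphas = [float(c.split("_", 1)[1]) for c in df.columns if c.startswith("alpha_")]
    freqs, flags = {}, {}
    for _, r in df.iterrows():
        e = (r["cause"], r["effect"])
        freqs[e] = float(r["frequency"])
        flags[e] = tuple(r[f"alpha_{a:g}"] == PRESENT for a in alphas)
    return EdgeStabilityReport(freqs, n_graphs, list(drop_rates), alpha, seed, flags, alphas)


def bootstrap_stability(
    table: CohortTable,
    tiers: dict[str, int] | None = None,
    alpha: float = 0.05,
    n_boot: int = 100,
    drop_rates=(0.0, 0.1, 0.2),
    seed: int = 0,
    undirected_policy: str = "half",
    max_cond: int | None = None,
) -> EdgeStabilityReport:
    """Bootstrap x drop-rate edge stability.

    For each drop rate, ``n_boot`` resamples are drawn: first
    ``floor(rate * n)`` rows are dropped uniformly without replacement, then
    the kept rows are resampled with replacement to their own size, and the
    tiered PC algorithm is rerun.  An edge's frequency is the fraction of all
    ``n_boot * len(drop_rates)`` graphs in which it appears directed.  An
    undirected edge contributes 0.5 to each direction under the default
    ``"half"`` policy, or nothing under ``"skip"``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if any(not 0 <= r < 1 for r in drop_rates):
        raise ValueError("drop rates must lie in [0, 1)")
    if undirected_policy not in ("half", "skip"):
        raise ValueError("undirected_policy must be 'half' or 'skip'")
    tiers = table.tiers if tiers is None else tiers
    n = table.n
    rng = np.random.default_rng(seed)
    counts: dict[tuple, float] = {}
    n_graphs = 0
    for rate in drop_rates:
        n_kept = n - int(math.floor(rate * n))
        if n_kept < len(table.names) + 5:
            raise ValueError(f"drop rate {rate} leaves too few rows ({n_kept}) for {len(table.names)} variables")
        for _ in range(n_boot):
            kept = rng.choice(n, size=n_kept, replace=False)
            rows = kept[rng.integers(0, n_kept, size=n_kept)]
            boot_df = table.df.iloc[rows].reset_index(drop=True)
            boot = CohortTable(boot_df, list(table.specs))
            g = tpc(boot, tiers, alpha=alpha, max_cond=max_cond)
            n_graphs += 1
            for e in g.directed:
                counts[e] = counts.get(e, 0.0) + 1.0
            if undirected_policy == "half":
                for e in g.undirected:
                    a, b = tuple(e)
                    counts[(a, b)] = counts.get((a, b), 0.0) + 0.5
                    counts[(b, a)] = counts.get((b, a), 0.0) + 0.5
    freqs = {e: c / n_graphs for e, c in counts.items()}
    return EdgeStabilityReport(freqs, n_graphs, list(drop_rates), alpha, seed)


def alpha_sensitivity(
    table: CohortTable,
    tiers: dict[str, int] | None = None,
    alphas=(0.01, 0.05, 0.075),
    ci: CGTester | None = None,
    max_cond: int | None = None,
):
    """Refit the network at several significance levels with a shared CI cache.

    Returns ``(graphs, flags)`` where ``graphs`` maps alpha -> TieredPDAG and
    ``flags`` maps each ordered edge seen in any graph to its per-alpha
    presence vector.  Because every alpha reuses identical cached test
    statistics, skeleton presence is monotone in alpha by construction.
    """
    alphas = list(alphas)
    if any(b <= a for a, b in zip(alphas, alphas[1:])):
        raise ValueError("alphas must be strictly increasing")
    tiers = table.tiers if tiers is None else tiers
    if ci is None:
        ci = CGTester(table)
    graphs = {a: tpc(table, tiers, alpha=a, ci=ci, max_cond=max_cond) for a in alphas}
    edges = set()
    for g in graphs.values():
        edges |= set(g.directed)
        for e in g.undirected:
            a, b = tuple(e)
            edges.add((a, b))
            edges.add((b, a))
    flags = {}
    for u, v in sorted(edges):
        flags[(u, v)] = tuple(
            (u, v) in graphs[a].directed or frozenset((u, v)) in graphs[a].undirected for a in alphas
        )
    return graphs, flags


@dataclass
class CentralityResult:
    """Betweenness scores with the above-mean highlighting rule."""

    scores: dict
    mean_score: float
    above_mean: set
    nominated: list = field(default_factory=list)

    def __post_init__(self) -> None:
        expect = {v for v, s in self.scores.items() if s > self.mean_score}
        if expect != set(self.above_mean):
            raise ValueError("above_mean set inconsistent with scores")


def betweenness(graph: TieredPDAG, normalized: bool = False) -> CentralityResult:
    """Unnormalized betweenness centrality on the directed part of the PDAG.

    For every ordered node pair (s, t), each interior node v of the shortest
    directed s -> t paths accrues the fraction of those paths through it.
    Undirected leftovers are excluded from path counting (a warning is logged
    when any are dropped); isolated nodes score 0.
    """
    if not graph.nodes:
        raise ValueError("graph has no nodes")
    if graph.undirected:
        logger.warning("betweenness ignores %d undirected edges", len(graph.undirected))
    g = graph.directed_graph()
    scores = nx.betweenness_centrality(g, normalized=normalized)
    mean_score = float(np.mean(list(scores.values())))
    above = {v for v, s in scores.items() if s > mean_score}
    return CentralityResult({v: float(s) for v, s in scores.items()}, mean_score, above)


def nominate_mediators(
    graph: TieredPDAG, centrality: CentralityResult, exposure: str, outcome: str
) -> list[str]:
    """Above-mean-betweenness nodes lying on a directed exposure -> outcome path.

    Returned in decreasing centrality order; exposure and outcome themselves
    are never nominated.
    """
    if exposure == outcome:
        raise ValueError("exposure and outcome must differ")
    if exposure not in graph.tiers or outcome not in graph.tiers:
        raise ValueError("exposure and outcome must be graph nodes")
    g = graph.directed_graph()
    downstream = nx.descendants(g, exposure)
    out = [
        v
        for v in centrality.above_mean
        if v not in (exposure, outcome) and v in downstream and nx.has_path(g, v, outcome)
    ]
    out.sort(key=lambda v: (-centrality.scores[v], v))
    centrality.nominated = out
    return out


def stable_edges(report: EdgeStabilityReport, threshold: float = 0.8) -> set:
    """Edges meeting the downstream stability threshold (default 80%)."""
    return {e for e, f in report.frequencies.items() if f >= threshold}
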