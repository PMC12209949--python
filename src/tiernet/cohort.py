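"""Core containers: variable metadata, cohort tables and ground-truth causal models.

A cohort is a rectangular samples x variables table.  Every variable carries
three pieces of metadata that drive the whole pipeline:

* ``kind`` -- ``continuous`` or ``binary``; decides which branch of the
  conditional-Gaussian likelihood the variable enters.
* ``tier`` -- a non-negative temporal stratum (0 = baseline exposure block,
  1 = baseline biomarkers, 2 = follow-up outcome by default).  Causal edges
  may never point from a later tier to an earlier one.
* ``role`` -- exposure / biomarker / inflammatory / outcome / covariate;
  used by preprocessing (which columns get log-transformed, which rows may
  be masked) and by the downstream mediation stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

KINDS = ("continuous", "binary")
ROLES = ("exposure", "biomarker", "inflammatory", "outcome", "covariate")

__all__ = [
    "VariableSpec",
    "CohortTable",
    "GroundTruth",
    "validate_specs",
    "read_cohort",
    "KINDS",
    "ROLES",
]


@dataclass(frozen=True)
class VariableSpec:
    """Metadata for a single cohort variable."""

    name: str
    kind: str
    tier: int
    role: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r} for {self.name!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for {self.name!r}")
        if self.tier < 0:
            raise ValueError(f"tier must be non-negative for {self.name!r}")


def validate_specs(specs: list[VariableSpec]) -> None:
    """Check name uniqueness and temporal ordering of roles.

    Outcomes must occupy the maximal tier and the ordering
    exposure tier <= biomarker tier <= outcome tier must hold.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("variable names must be unique")
    tiers = {s.name: s.tier for s in specs}
    max_tier = max(tiers.values(), default=0)
    for s in specs:
        if s.role == "outcome" and s.tier != max_tier:
            raise ValueError(f"outcome {s.name!r} must sit in the maximal tier")
    exp_tiers = [s.tier for s in specs if s.role == "exposure"]
    bio_tiers = [s.tier for s in specs if s.role in ("biomarker", "inflammatory")]
    out_tiers = [s.tier for s in specs if s.role == "outcome"]
    if exp_tiers and bio_tiers and max(exp_tiers) > min(bio_tiers):
        raise ValueError("exposure tier must not exceed biomarker tier")
    if bio_tiers and out_tiers and max(bio_tiers) > min(out_tiers):
        raise ValueError("biomarker tier must not exceed outcome tier")


@dataclass
class CohortTable:
    """Samples x variables table with explicit missingness and provenance.

    ``df`` holds the data with ``NaN`` marking missing cells; binary columns
    contain only {0, 1, NaN}.  ``provenance`` is an append-only audit trail of
    the transformations the table has been through; preprocessing operations
    consult it to enforce their ordering contract.
    """

    df: pd.DataFrame
    specs: list[VariableSpec]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        validate_specs(self.specs)
        if list(self.df.columns) != [s.name for s in self.specs]:
            raise ValueError("dataframe columns must match spec names and order")
        if len(self.df) < 1:
            raise ValueError("cohort must contain at least one sample")
        for s in self.specs:
            if s.kind == "binary":
                col = self.df[s.name]
                vals = col.dropna().unique()
                if not np.isin(vals, (0.0, 1.0)).all():
                    raise ValueError(f"binary column {s.name!r} contains non-{{0,1}} values")

    # -- convenience accessors -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def spec(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def names_by_role(self, *roles: str) -> list[str]:
        return [s.name for s in self.specs if s.role in roles]

    def names_by_kind(self, kind: str) -> list[str]:
        return [s.name for s in self.specs if s.kind == kind]

    @property
    def tiers(self) -> dict[str, int]:
        return {s.name: s.tier for s in self.specs}

    @property
    def kinds(self) -> dict[str, str]:
        return {s.name: s.kind for s in self.specs}

    def n_missing(self) -> int:
        return int(self.df.isna().to_numpy().sum())

    def copy(self) -> "CohortTable":
        return CohortTable(self.df.copy(), list(self.specs), list(self.provenance))

    def with_provenance(self, entry: str) -> "CohortTable":
        out = self.copy()
        out.provenance.append(entry)
        return out

    def replace_spec(self, name: str, **changes) -> None:
        """Mutate one variable's metadata in place (e.g. after residualization)."""
        for i, s in enumerate(self.specs):
            if s.name == name:
                self.specs[i] = replace(s, **changes)
                return
        raise KeyError(name)

    # -- I/O: CSV with a tab-separated variable-metadata sidecar ----------------

    def to_csv(self, path: str) -> None:
        """Write the values as CSV (missing cells empty) plus ``<path>.vars.tsv``."""
        self.df.to_csv(path, index=False, na_rep="")
        meta = pd.DataFrame(
            {
                "name": [s.name for s in self.specs],
                "kind": [s.kind for s in self.specs],
                "tier": [s.tier for s in self.specs],
                "role": [s.role for s in self.specs],
            }
        )
        meta.to_csv(str(path) + ".vars.tsv", sep="\t", index=False)


def read_cohort(path: str) -> CohortTable:
    """Read a cohort CSV written by :meth:`CohortTable.to_csv`."""
    meta = pd.read_csv(str(path) + ".vars.tsv", sep="\t")
    specs = [
        VariableSpec(str(r["name"]), str(r["kind"]), int(r["tier"]), str(r["role"]))
        for _, r in meta.iterrows()
    ]
    df = pd.read_csv(path)
    df = df[[s.name for s in specs]].astype(float)
    return CohortTable(df, specs, provenance=[f"read from {path}"])


@dataclass
class GroundTruth:
    """A tier-respecting DAG with conditional-Gaussian / logistic parameters.

    Continuous children are generated as
    ``intercept + sum(weight * parent) + Normal(0, noise_sd)``;
    binary children as ``Bernoulli(logistic(intercept + sum(weight * parent)))``.
    ``annotations`` records designed features of the structure (mediating
    chains, designated non-mediators) so recovery tests can score against them.
    """

    specs: list[VariableSpec]
    edges: tuple[tuple[str, str], ...]
    weights: dict[tuple[str, str], float]
    noise_sd: dict[str, float]
    intercepts: dict[str, float]
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_specs(self.specs)
        tiers = {s.name: s.tier for s in self.specs}
        names = set(tiers)
        for p, c in self.edges:
            if p not in names or c not in names:
                raise ValueError(f"edge ({p}, {c}) references unknown variable")
            if tiers[p] > tiers[c]:
                raise ValueError(f"edge ({p}, {c}) points from tier {tiers[p]} to earlier tier {tiers[c]}")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ground-truth edge set is cyclic")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    @property
    def tiers(self) -> dict[str, int]:
        return {s.name: s.tier for s in self.specs}

    @property
    def kinds(self) -> dict[str, str]:
        return {s.name: s.kind for s in self.specs}

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.names)
        g.add_edges_from(self.edges)
        return g

    def parents(self, name: str) -> list[str]:
        return [p for p, c in self.edges if c == name]

    def topological_order(self) -> list[str]:
        pos = {n: i for i, n in enumerate(self.names)}
        return list(nx.lexicographical_topological_sort(self.graph(), key=lambda n: pos[n]))

    def skeleton(self) -> set[frozenset]:
        return {frozenset(e) for e in self.edges}

    def d_separated(self, x: str, y: str, s: set[str]) -> bool:
        return nx.is_d_separator(self.graph(), {x}, {y}, set(s))

    def all_directed_paths(self, source: str, target: str) -> list[list[str]]:
        return [list(p) for p in nx.all_simple_paths(self.graph(), source, target)]

    # -- export ------------------------------------------------------------------

    def to_graphml(self, path: str) -> None:
        g = self.graph()
        for s in self.specs:
            g.nodes[s.name]["tier"] = s.tier
            g.nodes[s.name]["kind"] = s.kind
            g.nodes[s.name]["role"] = s.role
        for e, w in self.weights.items():
            g.edges[e]["weight"] = float(w)
        nx.write_graphml(g, path)

    def to_dot(self, path: str) -> None:
        lines = ["digraph truth {"]
        for s in self.specs:
            lines.append(f'  "{s.name}" [tier={s.tier}, role="{s.role}"];')
        for p, c in self.edges:
            w = self.weights.get((p, c), 1.0)
            lines.append(f'  "{p}" -> "{c}" [label="{w:.2f}"];')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
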