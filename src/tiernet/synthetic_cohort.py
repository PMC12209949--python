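"""Synthetic cohorts with known causal structure.

Real psychiatric-cardiometabolic cohort data (depression status, NMR
metabolomics, inflammatory assays, follow-up cardiovascular events) are
access-restricted, so every downstream stage of the pipeline is exercised on
simulated cohorts whose generating DAG is known exactly.  The generator
emulates the statistical pathologies the pipeline has to survive: mixed
binary/continuous variables arranged in temporal tiers, a rare follow-up
outcome, non-MCAR missingness, and heavy right tails in inflammatory markers.

The default ``nesda_like_truth`` layout mirrors a depression cohort at
clinical scale: one binary exposure with ~49% prevalence, 24 continuous
log-scale biomarkers (three of them inflammatory), and one binary follow-up
outcome with ~10% prevalence reached through both a direct exposure->outcome
edge and designed mediated chains.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortTable, GroundTruth, VariableSpec, validate_specs

__all__ = [
    "nesda_like_truth",
    "sample_cohort",
    "inject_missingness",
    "inject_outliers",
    "exponentiate_biomarkers",
]

_EXPOSURE_PREVALENCE = 0.49  # 1115 / 2256 scale
_OUTCOME_PREVALENCE = 0.10  # ~210 / 2138 scale


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def nesda_like_truth(seed: int, n_biomarkers: int = 24, n_exposure_children: int | None = None) -> GroundTruth:
    """Build a ground truth shaped like a depression -> biomarker -> CVD cohort.

    Parameters
    ----------
    seed
        Drives the randomly placed biomarker-biomarker edges and their weights;
        the designed backbone (chains, direct edge, non-mediator) is fixed.
    n_biomarkers
        Number of continuous baseline biomarkers (tier 1).  Must be >= 3 so
        the structure can host both a direct exposure->outcome edge and a
        two-biomarker mediating chain.
    n_exposure_children
        How many biomarkers receive an edge from the exposure.  Defaults to
        the designed backbone children (6 when the cohort is large enough).

    The returned truth always contains:

    * a two-step chain  exposure -> B1 -> B2 -> outcome  (designed mediators),
    * at least two single-mediator paths  exposure -> B -> outcome,
    * a direct edge     exposure -> outcome,
    * one exposure child with no directed path to the outcome (designed
      non-mediator, used to check nomination specificity).

    Annotations under ``truth.annotations`` record the designed chains,
    mediators and non-mediator by name.
    """
    if n_biomarkers < 3:
        raise ValueError("n_biomarkers must be >= 3 to host both a direct and a chain-mediated path")
    rng = np.random.default_rng(seed)

    n_inflam = 3 if n_biomarkers >= 8 else 1
    inflam_names = ["crp", "il6", "tnfa"][:n_inflam]
    n_generic = n_biomarkers - n_inflam
    generic_names = [f"bm{i:02d}" for i in range(1, n_generic + 1)]

    specs = [VariableSpec("MDD", "binary", 0, "exposure")]
    specs += [VariableSpec(n, "continuous", 1, "biomarker") for n in generic_names]
    specs += [VariableSpec(n, "continuous", 1, "inflammatory") for n in inflam_names]
    specs += [VariableSpec("CVD", "binary", 2, "outcome")]
    validate_specs(specs)

    edges: list[tuple[str, str]] = []
    weights: dict[tuple[str, str], float] = {}

    def add(p: str, c: str, w: float) -> None:
        edges.append((p, c))
        weights[(p, c)] = w

    # Designed backbone.  With a small cohort (n_biomarkers == 3) the chain
    # runs through the two generic markers and the inflammatory marker carries
    # the second mediated path.
    b1, b2 = generic_names[0], generic_names[1]
    add("MDD", b1, 0.8)
    add(b1, b2, 0.6)
    add(b2, "CVD", 0.8)
    chains: list[list[str]] = [["MDD", b1, b2, "CVD"]]

    single_mediators: list[str] = []
    if n_generic >= 4:
        single_mediators = [generic_names[2], generic_names[3]]
    elif n_generic >= 3:
        single_mediators = [generic_names[2]]
    single_mediators += inflam_names[:1]  # CRP-like marker mediates
    for m in single_mediators:
        add("MDD", m, 0.8)
        add(m, "CVD", 0.8)
        chains.append(["MDD", m, "CVD"])

    add("MDD", "CVD", 0.7)

    # Exposure children without any outcome path: nomination specificity probes.
    non_mediator = inflam_names[-1] if n_inflam >= 2 else None
    if non_mediator is not None:
        add("MDD", non_mediator, 0.8)
    if n_inflam >= 3:
        add("MDD", inflam_names[1], 0.8)

    designed_children = {c for p, c in edges if p == "MDD" and c != "CVD"}
    if n_exposure_children is not None:
        extra_needed = n_exposure_children - len(designed_children)
        pool = [n for n in generic_names if n not in designed_children]
        for n in pool[: max(extra_needed, 0)]:
            add("MDD", n, 0.8)
            designed_children.add(n)

    # Seeded background dependence among the remaining biomarkers: each later
    # generic marker may depend on an earlier one, keeping tier 1 acyclic.
    core = {b1, b2, *single_mediators}
    background = [n for n in generic_names if n not in core and n not in designed_children]
    for i, child in enumerate(background):
        if i >= 1 and rng.random() < 0.5:
            parent = background[rng.integers(0, i)]
            w = rng.uniform(0.4, 0.7) * rng.choice([-1.0, 1.0])
            add(parent, child, float(w))

    noise_sd = {s.name: 1.0 for s in specs if s.kind == "continuous"}
    intercepts: dict[str, float] = {s.name: 0.0 for s in specs}
    intercepts["MDD"] = _logit(_EXPOSURE_PREVALENCE)
    # Give biomarkers a positive latent location so exp() yields concentrations
    # on a plausible log-normal scale.
    for n in generic_names + inflam_names:
        intercepts[n] = 3.0

    truth = GroundTruth(
        specs=specs,
        edges=tuple(edges),
        weights=weights,
        noise_sd=noise_sd,
        intercepts=intercepts,
        annotations={
            "chains": chains,
            "designed_mediators": [b1, b2],
            "single_mediators": single_mediators,
            "non_mediator": non_mediator,
            "exposure": "MDD",
            "outcome": "CVD",
        },
    )
    _calibrate_intercept(truth, "CVD", _OUTCOME_PREVALENCE, seed)
    return truth


def _calibrate_intercept(truth: GroundTruth, name: str, target: float, seed: int, tol: float = 0.01) -> None:
    """Bisect a binary variable's intercept until its marginal prevalence is
    within ``tol`` of ``target`` (logistic marginals have no closed form)."""
    rng = np.random.default_rng((int(seed) * 2654435761 + 17) % (2**31))
    n_mc = 100_000
    cols = _forward_sample(truth, n_mc, rng, stop_before=name)
    eta_base = np.full(n_mc, 0.0)
    for p in truth.parents(name):
        eta_base += truth.weights[(p, name)] * cols[p]

    lo, hi = -60.0, 60.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        prev = float(_sigmoid(eta_base + mid).mean())
        if abs(prev - target) <= tol * 0.5:
            break
        if prev > target:
            hi = mid
        else:
            lo = mid
    truth.intercepts[name] = 0.5 * (lo + hi)


def _forward_sample(truth: GroundTruth, n: int, rng: np.random.Generator, stop_before: str | None = None) -> dict[str, np.ndarray]:
    kinds = truth.kinds
    cols: dict[str, np.ndarray] = {}
    for v in truth.topological_order():
        if v == stop_before:
            continue
        eta = np.full(n, truth.intercepts.get(v, 0.0))
        for p in truth.parents(v):
            eta = eta + truth.weights[(p, v)] * cols[p]
        if kinds[v] == "continuous":
            cols[v] = eta + rng.normal(0.0, truth.noise_sd[v], size=n)
        else:
            cols[v] = rng.binomial(1, _sigmoid(eta), size=n).astype(float)
    return cols


def sample_cohort(truth: GroundTruth, n: int, seed: int) -> CohortTable:
    """Forward-sample ``n`` rows from the truth in topological order.

    Continuous children are linear-Gaussian, binary children Bernoulli with a
    logistic link; the output has no missing values.  Values are on the
    latent (log) scale the conditional-Gaussian model assumes; see
    :func:`exponentiate_biomarkers` for raw concentrations.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cols = _forward_sample(truth, n, rng)
    df = pd.DataFrame({s.name: cols[s.name] for s in truth.specs})
    return CohortTable(df, list(truth.specs), provenance=[f"sampled n={n} seed={seed}"])


def exponentiate_biomarkers(table: CohortTable) -> CohortTable:
    """Map biomarker/inflammatory columns to raw concentrations ``exp(x)``.

    The latent Gaussian scale becomes log-normal, giving inflammatory markers
    the heavy right tails seen in raw assay data and making the downstream
    ``log1p`` cleaning step meaningful.
    """
    out = table.with_provenance("exponentiated biomarkers to raw scale")
    for name in out.names_by_role("biomarker", "inflammatory"):
        out.df[name] = np.exp(out.df[name])
    return out


def inject_missingness(table: CohortTable, rate: float, mechanism: str = "MCAR", seed: int = 0) -> CohortTable:
    """Mask cells at an overall target ``rate`` under MCAR or MAR.

    Exposure and outcome columns are never masked.  Under MAR, biomarker cells
    in exposed rows are masked at three times the probability of unexposed
    rows, producing the exposure-dependent missingness pattern that makes
    Little's test reject.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if mechanism not in ("MCAR", "MAR"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    if rate == 0:
        return table
    rng = np.random.default_rng(seed)
    out = table.with_provenance(f"injected {mechanism} missingness rate={rate}")
    eligible = out.names_by_role("biomarker", "inflammatory", "covariate")
    if not eligible:
        return out
    n, p_total = out.n, len(out.names)
    # Per-eligible-cell probability scaled so the overall fraction hits `rate`.
    cell_rate = min(rate * p_total / len(eligible), 0.97)
    if mechanism == "MCAR":
        mask = rng.random((n, len(eligible))) < cell_rate
    else:
        exposures = out.names_by_role("exposure")
        if not exposures:
            raise ValueError("MAR mechanism requires an exposure column")
        x = out.df[exposures[0]].to_numpy()
        prev = float(np.nanmean(x))
        p1 = min(3.0 * cell_rate / (1.0 + 2.0 * prev), 0.97)
        p0 = p1 / 3.0
        row_p = np.where(x == 1.0, p1, p0)
        mask = rng.random((n, len(eligible))) < row_p[:, None]
    vals = out.df[eligible].to_numpy()
    vals[mask] = np.nan
    out.df[eligible] = vals
    return out


def inject_outliers(
    table: CohortTable, n_outliers: int, magnitude_sd: float = 8.0, seed: int = 0
) -> tuple[CohortTable, list[int]]:
    """Contaminate ``n_outliers`` rows with extreme inflammatory values.

    Mimics acute-inflammation spikes: selected rows have every
    inflammatory-role column inflated by ``magnitude_sd`` column standard
    deviations.  Returns the contaminated table and the true outlier row
    indices (positional).
    """
    if n_outliers > table.n:
        raise ValueError("n_outliers cannot exceed the number of rows")
    inflam = table.names_by_role("inflammatory")
    if not inflam:
        raise ValueError("no inflammatory-role columns to contaminate")
    if n_outliers == 0:
        return table, []
    rng = np.random.default_rng(seed)
    rows = rng.choice(table.n, size=n_outliers, replace=False)
    out = table.with_provenance(f"injected {n_outliers} outliers magnitude={magnitude_sd}sd")
    for name in inflam:
        col = out.df[name].to_numpy()
        sd = float(np.nanstd(col))
        col[rows] = col[rows] + magnitude_sd * sd
        out.df[name] = col
    return out, sorted(int(r) for r in rows)
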