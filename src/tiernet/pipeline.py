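"""End-to-end orchestration of the discovery pipeline from a single config.

Stages: cohort acquisition (synthetic or from CSV) -> preprocessing ->
ML biomarker refinement -> tiered PC discovery -> alpha sensitivity and
bootstrap stability -> betweenness centrality and mediator nomination ->
counterfactual mediation on the nominated mediators.  Every stage draws its
randomness from a seed derived deterministically from the master seed and
the stage name, so adding a stage never perturbs earlier stages' draws.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import CohortTable, read_cohort
from .feature_refine import importance_stability, select_features, tune_and_fit
from .mediation import estimate_acme
from .mixed_ci import CGTester
from .preprocess import (
    NotApplicableError,
    clean_biomarkers,
    detect_outliers,
    iterative_impute,
    little_mcar_test,
    remove_outliers,
    residualize_outcome,
)
from .stability_centrality import (
    alpha_sensitivity,
    betweenness,
    bootstrap_stability,
    nominate_mediators,
)
from .synthetic_cohort import (
    exponentiate_biomarkers,
    inject_missingness,
    inject_outliers,
    nesda_like_truth,
    sample_cohort,
)
from .tiered_pc import tpc

__all__ = ["PipelineConfig", "derive_seed", "run"]


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """All pipeline knobs in one place; YAML-loadable."""

    seed: int = 0
    outdir: str = "tiernet_out"
    # input: either a cohort CSV path (with .vars.tsv sidecar) or synthetic
    input_csv: str | None = None
    synthetic_n: int = 2000
    synthetic_biomarkers: int = 24
    missing_rate: float = 0.05
    missing_mechanism: str = "MAR"
    n_outliers: int = 40
    # preprocessing
    contamination: float | None = None  # default: n_outliers / n
    residualize_adjusters: list = field(default_factory=list)
    # feature refinement
    k_features: int = 24
    feature_n_boot: int = 20
    param_grid: dict | None = None
    # discovery
    alpha: float = 0.05
    alphas: list = field(default_factory=lambda: [0.01, 0.05, 0.075])
    max_cond: int | None = None
    # stability
    stability_n_boot: int = 100
    drop_rates: list = field(default_factory=lambda: [0.0, 0.1, 0.2])
    # mediation
    mediation_covariates: list = field(default_factory=list)
    mediation_n_boot: int = 200
    mediation_n_mc: int = 200
    # validation-only mode: skip discovery, mediate these mediators directly
    validation_mediators: list | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _exposure_outcome(table: CohortTable) -> tuple[str, str]:
    exposures = table.names_by_role("exposure")
    outcomes = table.names_by_role("outcome")
    if len(exposures) != 1 or len(outcomes) != 1:
        raise ValueError("pipeline expects exactly one exposure and one outcome variable")
    return exposures[0], outcomes[0]


def run(config: PipelineConfig, stop_after: str | None = None) -> dict:
    """Execute the pipeline and write the report bundle to ``config.outdir``.

    ``stop_after`` truncates the chain after a named stage
    (``preprocess`` / ``select`` / ``discover`` / ``stability`` /
    ``centrality``); the default runs everything through mediation.
    Returns a dict of in-memory results (table, graphs, reports, mediation).
    Deterministic: rerunning with the same config reproduces every output.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    results: dict = {}

    def stage_seed(name: str) -> int:
        s = derive_seed(config.seed, name)
        manifest["stages"][name] = {"seed": s}
        return s

    # -- data -----------------------------------------------------------------
    if config.input_csv:
        table = read_cohort(config.input_csv)
        truth = None
    else:
        s = stage_seed("simulate")
        truth = nesda_like_truth(s, n_biomarkers=config.synthetic_biomarkers)
        table = sample_cohort(truth, config.synthetic_n, seed=derive_seed(config.seed, "sample"))
        table = exponentiate_biomarkers(table)
        if config.missing_rate > 0:
            table = inject_missingness(
                table, config.missing_rate, config.missing_mechanism, seed=derive_seed(config.seed, "missing")
            )
        if config.n_outliers > 0:
            table, _ = inject_outliers(table, config.n_outliers, seed=derive_seed(config.seed, "outliers"))
        truth.to_graphml(str(out / "truth.graphml"))
        truth.to_dot(str(out / "truth.dot"))
    results["truth"] = truth
    exposure, outcome = _exposure_outcome(table)

    # -- preprocessing ----------------------------------------------------------
    table = clean_biomarkers(table)
    try:
        mcar = little_mcar_test(table)
        manifest["stages"]["mcar_test"] = {"statistic": mcar.statistic, "df": mcar.df, "p": mcar.p}
        results["mcar"] = mcar
    except NotApplicableError:
        results["mcar"] = None
    table = iterative_impute(table, seed=stage_seed("impute"))
    contamination = config.contamination
    if contamination is None:
        contamination = max(config.n_outliers, 1) / table.n
    report = detect_outliers(table, contamination, seed=stage_seed("outlier_detect"))
    table = remove_outliers(table, report)
    if config.residualize_adjusters:
        table = residualize_outcome(table, outcome, config.residualize_adjusters)
    table.to_csv(str(out / "cohort_clean.csv"))
    results["table"] = table
    if stop_after == "preprocess":
        _write_manifest(out, manifest)
        return results

    # -- validation-only mode ---------------------------------------------------
    if config.validation_mediators is not None:
        med = _mediate(table, config.validation_mediators, exposure, outcome, config, stage_seed("mediation"))
        med.to_csv(out / "mediation.tsv", sep="\t", index=False)
        results["mediation"] = med
        _write_manifest(out, manifest)
        return results

    # -- feature refinement -----------------------------------------------------
    s = stage_seed("features")
    grid = config.param_grid or {"max_depth": [2, 3], "learning_rate": [0.1], "n_estimators": [100]}
    model, tuned = tune_and_fit(table, exposure, param_grid=grid, seed=s)
    profile = importance_stability(
        table, exposure, n_boot=config.feature_n_boot, seed=s, params=tuned.params
    )
    k = min(config.k_features, len(profile.features))
    selected = select_features(profile, k)
    pd.DataFrame(
        {
            "feature": selected,
            "mean_importance": [profile.mean[f] for f in selected],
            "sd_importance": [profile.sd[f] for f in selected],
        }
    ).to_csv(out / "selected_features.tsv", sep="\t", index=False)
    manifest["stages"]["features"]["auc"] = tuned.auc
    results["profile"] = profile
    results["selected"] = selected
    if stop_after == "select":
        _write_manifest(out, manifest)
        return results

    keep = [exposure, *selected, outcome]
    sub = CohortTable(
        table.df[keep].reset_index(drop=True),
        [table.spec(n) for n in keep],
        list(table.provenance) + [f"restricted to exposure + {k} refined biomarkers + outcome"],
    )

    # -- discovery + sensitivity ------------------------------------------------
    ci = CGTester(sub)
    graphs, flags = alpha_sensitivity(sub, alphas=config.alphas, ci=ci, max_cond=config.max_cond)
    primary = graphs[config.alpha] if config.alpha in graphs else tpc(sub, alpha=config.alpha, ci=ci)
    for a, g in graphs.items():
        g.to_graphml(str(out / f"graph_alpha_{a:g}.graphml"))
        g.to_dot(str(out / f"graph_alpha_{a:g}.dot"))
    results["graphs"] = graphs
    results["primary_graph"] = primary
    if stop_after == "discover":
        _write_manifest(out, manifest)
        return results

    stab = bootstrap_stability(
        sub,
        alpha=config.alpha,
        n_boot=config.stability_n_boot,
        drop_rates=config.drop_rates,
        seed=stage_seed("stability"),
        max_cond=config.max_cond,
    )
    stab.alpha_flags = flags
    stab.alphas = list(config.alphas)
    stab.to_tsv(str(out / "edge_stability.tsv"))
    results["stability"] = stab
    if stop_after == "stability":
        _write_manifest(out, manifest)
        return results

    # -- centrality + nomination ------------------------------------------------
    cent = betweenness(primary)
    nominated = nominate_mediators(primary, cent, exposure, outcome)
    pd.DataFrame(
        {
            "node": list(cent.scores),
            "betweenness": [cent.scores[v] for v in cent.scores],
            "above_mean": [v in cent.above_mean for v in cent.scores],
            "nominated": [v in nominated for v in cent.scores],
        }
    ).to_csv(out / "centrality.tsv", sep="\t", index=False)
    results["centrality"] = cent
    results["nominated"] = nominated
    if stop_after == "centrality":
        _write_manifest(out, manifest)
        return results

    # -- mediation ---------------------------------------------------------------
    med = _mediate(table, nominated, exposure, outcome, config, stage_seed("mediation"))
    med.to_csv(out / "mediation.tsv", sep="\t", index=False)
    results["mediation"] = med

    _write_manifest(out, manifest)
    return results


def _mediate(table, mediators, exposure, outcome, config: PipelineConfig, seed: int) -> pd.DataFrame:
    rows = []
    for i, m in enumerate(mediators):
        r = estimate_acme(
            table,
            exposure,
            m,
            outcome,
            covariates=config.mediation_covariates,
            n_boot=config.mediation_n_boot,
            n_mc=config.mediation_n_mc,
            seed=(seed + i) % (2**31),
        )
        rows.append(
            {
                "mediator": m,
                "acme": r.acme,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "ade": r.ade,
                "total": r.total,
                "prop_mediated": r.prop_mediated,
            }
        )
    return pd.DataFrame(rows, columns=["mediator", "acme", "ci_low", "ci_high", "p", "ade", "total", "prop_mediated"])


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
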