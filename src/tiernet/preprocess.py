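"""Cohort cleaning: missingness diagnosis, imputation, outlier removal,
biomarker transformation and outcome residualization.

The default ordering mirrors the analysis pipeline the package implements:
diagnose missingness (Little's MCAR test), impute with a round-robin
conditional-model imputer, detect and remove isolation-based outliers, then
log-transform and tail-censor biomarkers.  Operations stamp the table's
provenance and the outlier detector refuses to run on tables that still
contain missing cells, enforcing the impute-first contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import IsolationForest
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

import statsmodels.api as sm

from .cohort import CohortTable, VariableSpec

__all__ = [
    "McarTestResult",
    "OutlierReport",
    "little_mcar_test",
    "iterative_impute",
    "detect_outliers",
    "remove_outliers",
    "clean_biomarkers",
    "residualize_outcome",
    "NotApplicableError",
    "UnimputableColumnError",
    "OrderOfOperationsError",
    "InvalidDataError",
    "SeparationError",
]


class NotApplicableError(RuntimeError):
    """The requested diagnostic is undefined on this table."""


class UnimputableColumnError(RuntimeError):
    """A column has no observed values to learn an imputation model from."""


class OrderOfOperationsError(RuntimeError):
    """An operation was invoked out of the pipeline's required order."""


class InvalidDataError(ValueError):
    """Raw values violate the operation's domain assumptions."""


class SeparationError(RuntimeError):
    """Logistic fit failed due to (quasi-)perfect separation."""


@dataclass(frozen=True)
class McarTestResult:
    """Little's MCAR chi-square test summary."""

    statistic: float
    df: int
    p: float
    n_patterns: int


@dataclass
class OutlierReport:
    """Isolation-based anomaly scores and the flagged row set."""

    scores: np.ndarray
    flagged: list[int]
    contamination: float


# -- Little's MCAR test -------------------------------------------------------------


def _em_mvnorm(X: np.ndarray, max_iter: int = 100, tol: float = 1e-5):
    """EM estimates of the mean and covariance of a multivariate normal
    from incompletely observed rows."""
    n, p = X.shape
    mask = np.isnan(X)
    mu = np.nanmean(X, axis=0)
    var = np.nanvar(X, axis=0)
    var[var <= 0] = 1.0
    sigma = np.diag(var)
    # group rows by missingness pattern
    codes = (mask @ (1 << np.arange(p))).astype(np.int64)
    patterns = {}
    for code in np.unique(codes):
        rows = np.where(codes == code)[0]
        obs = np.where(~mask[rows[0]])[0]
        patterns[int(code)] = (rows, obs)
    for _ in range(max_iter):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        for rows, obs in patterns.values():
            mis = np.setdiff1d(np.arange(p), obs)
            xo = X[np.ix_(rows, obs)]
            xhat = np.empty((len(rows), p))
            xhat[:, obs] = xo
            if len(mis):
                if len(obs):
                    soo = sigma[np.ix_(obs, obs)]
                    smo = sigma[np.ix_(mis, obs)]
                    b = np.linalg.solve(soo, smo.T).T
                    cond_mean = mu[mis] + (xo - mu[obs]) @ b.T
                    cond_cov = sigma[np.ix_(mis, mis)] - b @ smo.T
                else:
                    cond_mean = np.tile(mu[mis], (len(rows), 1))
                    cond_cov = sigma[np.ix_(mis, mis)]
                xhat[:, mis] = cond_mean
                sum_xx[np.ix_(mis, mis)] += len(rows) * cond_cov
            sum_x += xhat.sum(axis=0)
            sum_xx += xhat.T @ xhat
        mu_new = sum_x / n
        sigma_new = sum_xx / n - np.outer(mu_new, mu_new)
        delta = max(np.abs(mu_new - mu).max(), np.abs(sigma_new - sigma).max())
        mu, sigma = mu_new, sigma_new
        if delta < tol:
            break
    return mu, sigma, patterns


def little_mcar_test(table: CohortTable, max_iter: int = 100) -> McarTestResult:
    """Little's test of the MCAR hypothesis on the continuous columns.

    Fits a grand mean and covariance by EM, then sums, over missingness
    patterns j, the Mahalanobis distances
    ``n_j (ybar_j - mu_obs)' Sigma_obs^{-1} (ybar_j - mu_obs)`` of the
    pattern means from the EM grand mean, referred to a chi-square with
    ``sum_j p_j - p`` degrees of freedom.  Binary columns are excluded.
    The statistic is invariant to affine rescaling of the columns.
    """
    cols = table.names_by_kind("continuous")
    if not cols:
        raise NotApplicableError("no continuous columns to test")
    X = table.df[cols].to_numpy(dtype=float)
    mask = np.isnan(X)
    codes = (mask @ (1 << np.arange(len(cols)))).astype(np.int64)
    if len(np.unique(codes)) < 2:
        raise NotApplicableError("a single missingness pattern (complete data?) leaves nothing to compare")
    mu, sigma, patterns = _em_mvnorm(X, max_iter=max_iter)
    p = len(cols)
    stat, df = 0.0, 0
    for rows, obs in patterns.values():
        if len(obs) == 0:
            continue
        ybar = X[np.ix_(rows, obs)].mean(axis=0)
        diff = ybar - mu[obs]
        soo = sigma[np.ix_(obs, obs)]
        stat += len(rows) * float(diff @ np.linalg.solve(soo, diff))
        df += len(obs)
    df -= p
    pval = float(stats.chi2.sf(stat, df)) if df > 0 else float("nan")
    return McarTestResult(float(stat), int(df), pval, len(patterns))


# -- imputation ---------------------------------------------------------------------


def iterative_impute(table: CohortTable, max_iter: int = 10, seed: int = 0) -> CohortTable:
    """Round-robin conditional-model imputation of all missing cells.

    Each variable is regressed on all others (ridge-regularized Bayesian
    linear models) and the cycle repeats until the largest change drops
    below 1e-3 or ``max_iter`` sweeps.  Observed cells are preserved exactly;
    binary columns are imputed on the linear scale then thresholded at 0.5.
    """
    fully_missing = [c for c in table.names if table.df[c].isna().all()]
    if fully_missing:
        raise UnimputableColumnError(f"column(s) with no observed values: {', '.join(fully_missing)}")
    if table.n_missing() == 0:
        return table
    imputer = IterativeImputer(max_iter=max_iter, tol=1e-3, random_state=seed, sample_posterior=False)
    filled = imputer.fit_transform(table.df.to_numpy(dtype=float))
    out = table.with_provenance(f"iterative imputation max_iter={max_iter} seed={seed}")
    mask = table.df.isna().to_numpy()
    values = table.df.to_numpy(dtype=float)
    values[mask] = filled[mask]
    for j, spec in enumerate(out.specs):
        if spec.kind == "binary":
            col_mask = mask[:, j]
            values[col_mask, j] = (values[col_mask, j] > 0.5).astype(float)
    out.df = pd.DataFrame(values, columns=out.names)
    return out


# -- outlier detection --------------------------------------------------------------


def detect_outliers(
    table: CohortTable, contamination: float, seed: int = 0, n_estimators: int = 500
) -> OutlierReport:
    """Two-pass isolation-forest anomaly scoring over biomarker and
    inflammatory columns.

    A first forest flags a provisional top-``contamination`` fraction; the
    forest is then refit on the remaining bulk and every row is re-scored
    against it.  The refinement pass matters when outliers cluster (e.g.
    acute-inflammation spikes shift several markers coherently): a dense
    outlier clump partly masks itself in a single fit, whereas scoring
    against the cleaned bulk isolates it sharply.  Flags exactly
    ``ceil(contamination * n)`` rows with the highest final scores.
    Requires a complete table: missing cells must be imputed first.
    """
    if not 0 < contamination < 0.5:
        raise ValueError("contamination must be in (0, 0.5)")
    if table.n_missing() > 0:
        raise OrderOfOperationsError("table contains missing cells; run iterative_impute first")
    cols = table.names_by_role("biomarker", "inflammatory")
    if not cols:
        raise ValueError("no biomarker/inflammatory columns to score")
    X = table.df[cols].to_numpy(dtype=float)
    k = math.ceil(contamination * table.n)

    first = IsolationForest(n_estimators=n_estimators, random_state=seed).fit(X)
    provisional = np.argsort(first.score_samples(X), kind="stable")[:k]
    bulk = np.setdiff1d(np.arange(table.n), provisional)
    second = IsolationForest(n_estimators=n_estimators, random_state=seed).fit(X[bulk])
    scores = -second.score_samples(X)  # higher = more anomalous

    order = np.lexsort((np.arange(table.n), -scores))
    flagged = sorted(int(i) for i in order[:k])
    return OutlierReport(scores=scores, flagged=flagged, contamination=contamination)


def remove_outliers(table: CohortTable, report: OutlierReport) -> CohortTable:
    """Drop the flagged rows, stamping provenance."""
    keep = np.setdiff1d(np.arange(table.n), np.array(report.flagged, dtype=int))
    out = table.with_provenance(f"removed {len(report.flagged)} outlier rows")
    out.df = out.df.iloc[keep].reset_index(drop=True)
    return out


# -- biomarker transformation -------------------------------------------------------


def clean_biomarkers(
    table: CohortTable, sd_limit: float = 5.0, censor_roles=("biomarker",)
) -> CohortTable:
    """Log-transform biomarkers, then censor extreme metabolite tails.

    Per biomarker/inflammatory column: ``x <- ln(1 + x)`` (raw concentrations
    must be non-negative).  Then, for columns whose role is in
    ``censor_roles``, any cell further than ``sd_limit`` standard deviations
    from the column mean — both computed on the transformed, observed
    values — is set to missing.  The order is fixed as transform-then-censor.

    Censoring defaults to metabolite (biomarker-role) columns only, matching
    NMR-platform quantification protocols; inflammatory assay columns are
    log-transformed but keep their extreme values, which the outlier stage
    handles at the row level instead.
    """
    cols = table.names_by_role("biomarker", "inflammatory")
    out = table.with_provenance(
        f"log1p on {len(cols)} columns + {sd_limit}SD censoring on roles {tuple(censor_roles)}"
    )
    for c in cols:
        x = out.df[c].to_numpy(dtype=float)
        if np.nanmin(x) < 0:
            raise InvalidDataError(f"negative raw concentration in column {c!r}")
        x = np.log1p(x)
        if out.spec(c).role in censor_roles:
            mean, sd = np.nanmean(x), np.nanstd(x)
            if sd > 0:
                x[np.abs(x - mean) > sd_limit * sd] = np.nan
        out.df[c] = x
    return out


# -- outcome residualization --------------------------------------------------------


def residualize_outcome(
    table: CohortTable, outcome: str, adjusters, residual_type: str = "pearson"
) -> CohortTable:
    """Replace a binary outcome by its logistic-regression residuals.

    Fits outcome ~ adjusters by maximum likelihood and substitutes Pearson
    residuals ``(y - p) / sqrt(p (1 - p))`` (or deviance residuals), marking
    the column continuous.  The raw outcome is retained under
    ``<outcome>_raw`` with covariate role.
    """
    if residual_type not in ("pearson", "deviance"):
        raise ValueError("residual_type must be 'pearson' or 'deviance'")
    spec = table.spec(outcome)
    if spec.kind != "binary":
        raise ValueError(f"outcome {outcome!r} must be binary")
    adjusters = list(adjusters)
    sub = table.df[[outcome] + adjusters].dropna()
    y = sub[outcome].to_numpy(dtype=float)
    X = sm.add_constant(sub[adjusters].to_numpy(dtype=float)) if adjusters else np.ones((len(y), 1))
    try:
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    except Exception as exc:  # pragma: no cover - statsmodels failure modes vary
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    coefs = np.asarray(fit.params)
    if np.abs(coefs[1:]).max(initial=0.0) > 30:
        worst = adjusters[int(np.argmax(np.abs(coefs[1:])))]
        raise SeparationError(f"perfect separation by adjuster {worst!r}")
    phat = np.asarray(fit.predict(X))
    if residual_type == "pearson":
        resid = (y - phat) / np.sqrt(phat * (1 - phat))
    else:
        resid = np.sign(y - phat) * np.sqrt(-2 * (y * np.log(phat) + (1 - y) * np.log(1 - phat)))
    out = table.with_provenance(f"residualized {outcome} on {adjusters or 'intercept only'} ({residual_type})")
    raw_name = f"{outcome}_raw"
    out.df[raw_name] = out.df[outcome]
    new_col = np.full(table.n, np.nan)
    new_col[sub.index.to_numpy()] = resid
    out.df[outcome] = new_col
    out.replace_spec(outcome, kind="continuous")
    out.specs.append(VariableSpec(raw_name, "binary", spec.tier, "covariate"))
    out.df = out.df[[s.name for s in out.specs]]
    return out
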