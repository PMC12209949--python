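"""Counterfactual mediation: the two-model average causal mediation effect.

For an exposure D, candidate mediator M and outcome Y with covariates C,
two models are fitted:

* mediator model:  M ~ D + C  by ordinary least squares,
* outcome model:   Y ~ D + M + C  by logistic regression (binary Y) or
  least squares (continuous Y, used by the linear test variant).

Counterfactual mediator values M(d) are simulated from the mediator model
(fitted mean plus Gaussian noise draws, common random numbers across arms)
and the average causal mediation effect under arm d is

    ACME_d = mean over units and draws of [ P(Y=1 | d, M(1), C) - P(Y=1 | d, M(0), C) ]

reported on the risk-difference scale and averaged over d in {0, 1}.
Inference is by nonparametric bootstrap (resampled rows, both models refit
per resample) with percentile confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CohortTable
from .preprocess import SeparationError

__all__ = [
    "MediationResult",
    "fit_mediator_model",
    "fit_outcome_model",
    "estimate_acme",
    "adjusted_associations",
    "CollinearityError",
]


class CollinearityError(ValueError):
    """Design matrix is rank-deficient."""


@dataclass(frozen=True)
class MediationResult:
    """ACME/ADE decomposition with percentile-bootstrap inference."""

    acme: float
    ade: float
    total: float
    prop_mediated: float
    ci_low: float
    ci_high: float
    p: float
    n_boot: int
    covariates: tuple
    acme_control: float
    acme_treated: float


def _design(df: pd.DataFrame, cols) -> np.ndarray:
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in cols])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(f"rank-deficient design over columns {list(cols)}")
    return X


@dataclass(frozen=True)
class LinearFit:
    """OLS coefficients (intercept first) and ML residual SD."""

    columns: tuple
    params: np.ndarray
    resid_sd: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.params


def fit_mediator_model(table: CohortTable, mediator: str, exposure: str, covariates=()) -> LinearFit:
    """OLS fit of ``mediator ~ exposure + covariates``."""
    if table.spec(mediator).kind != "continuous":
        raise ValueError(f"mediator {mediator!r} must be continuous")
    if table.spec(exposure).kind != "binary":
        raise ValueError(f"exposure {exposure!r} must be binary")
    cols = [exposure, *covariates]
    X = _design(table.df, cols)
    y = table.df[mediator].to_numpy(dtype=float)
    params, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ params
    return LinearFit(tuple(cols), params, float(np.sqrt(np.mean(resid**2))))


def fit_outcome_model(table: CohortTable, outcome: str, exposure: str, mediator: str, covariates=()):
    """ML logistic fit of ``outcome ~ exposure + mediator + covariates``."""
    if table.spec(outcome).kind != "binary":
        raise ValueError(f"outcome {outcome!r} must be binary")
    cols = [exposure, mediator, *covariates]
    X = _design(table.df, cols)
    y = table.df[outcome].to_numpy(dtype=float)
    params = _fit_logit(X, y)
    return LinearFit(tuple(cols), params, 0.0)


def _fit_logit(X: np.ndarray, y: np.ndarray, maxiter: int = 100) -> np.ndarray:
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=maxiter)
    except Exception as exc:
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    params = np.asarray(fit.params)
    if not np.all(np.isfinite(params)) or np.abs(params).max() > 50:
        raise SeparationError("perfect or quasi-perfect separation in outcome model")
    return params


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _effects_once(
    df: pd.DataFrame,
    exposure: str,
    mediator: str,
    outcome: str,
    covariates: tuple,
    outcome_binary: bool,
    n_mc: int,
    rng: np.random.Generator,
) -> tuple[float, float, float, float, float]:
    """Fit both models on ``df`` and Monte-Carlo integrate the effects.

    Returns (acme, ade, total, acme_control, acme_treated).
    """
    n = len(df)
    med_cols = [exposure, *covariates]
    Xm = np.column_stack([np.ones(n)] + [df[c].to_numpy(dtype=float) for c in med_cols])
    m_obs = df[mediator].to_numpy(dtype=float)
    mp, _, _, _ = np.linalg.lstsq(Xm, m_obs, rcond=None)
    sigma = float(np.sqrt(np.mean((m_obs - Xm @ mp) ** 2)))

    out_cols = [exposure, mediator, *covariates]
    Xo = np.column_stack([np.ones(n)] + [df[c].to_numpy(dtype=float) for c in out_cols])
    y = df[outcome].to_numpy(dtype=float)
    if outcome_binary:
        op = _fit_logit(Xo, y)
    else:
        op, _, _, _ = np.linalg.lstsq(Xo, y, rcond=None)

    # counterfactual mediator means under each exposure arm
    Xm_d = Xm.copy()
    Xm_d[:, 1] = 1.0
    mu1 = Xm_d @ mp
    Xm_d[:, 1] = 0.0
    mu0 = Xm_d @ mp

    b0, bd, bm = op[0], op[1], op[2]
    bc = op[3:]
    cov_term = (
        np.column_stack([df[c].to_numpy(dtype=float) for c in covariates]) @ bc
        if covariates
        else np.zeros(n)
    )
    link = _sigmoid if outcome_binary else (lambda x: x)

    chunk = max(1, min(n_mc, 200))
    done = 0
    acc = {key: 0.0 for key in ((0, 0), (0, 1), (1, 0), (1, 1))}
    while done < n_mc:
        k = min(chunk, n_mc - done)
        eps = rng.normal(0.0, sigma, size=(n, k))
        m1 = mu1[:, None] + eps
        m0 = mu0[:, None] + eps  # common random numbers across arms
        base = b0 + cov_term
        for d in (0, 1):
            eta_base = base + bd * d
            acc[(d, 1)] += float(link(eta_base[:, None] + bm * m1).mean() * k)
            acc[(d, 0)] += float(link(eta_base[:, None] + bm * m0).mean() * k)
        done += k
    mean_y = {key: v / n_mc for key, v in acc.items()}
    acme0 = mean_y[(0, 1)] - mean_y[(0, 0)]
    acme1 = mean_y[(1, 1)] - mean_y[(1, 0)]
    ade0 = mean_y[(1, 0)] - mean_y[(0, 0)]
    ade1 = mean_y[(1, 1)] - mean_y[(0, 1)]
    total = mean_y[(1, 1)] - mean_y[(0, 0)]
    return 0.5 * (acme0 + acme1), 0.5 * (ade0 + ade1), total, acme0, acme1


def estimate_acme(
    table: CohortTable,
    exposure: str,
    mediator: str,
    outcome: str,
    covariates=(),
    n_boot: int = 1000,
    n_mc: int = 1000,
    seed: int = 0,
) -> MediationResult:
    """Two-model counterfactual mediation with nonparametric bootstrap.

    The point estimate comes from the full sample; ``n_boot`` row resamples
    (each refitting both models and re-integrating the counterfactuals with
    ``n_mc`` mediator noise draws) give percentile confidence intervals and a
    two-sided sign-based p-value.  Resamples in which the binary outcome is
    constant are redrawn (at most 10 retries each).
    """
    covariates = tuple(covariates)
    use_cols = [exposure, mediator, outcome, *covariates]
    df = table.df[use_cols].dropna().reset_index(drop=True)
    outcome_binary = table.spec(outcome).kind == "binary"
    rng = np.random.default_rng(seed)
    acme, ade, total, acme0, acme1 = _effects_once(
        df, exposure, mediator, outcome, covariates, outcome_binary, n_mc, rng
    )
    n = len(df)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        for attempt in range(10):
            rows = rng.integers(0, n, size=n)
            sub = df.iloc[rows].reset_index(drop=True)
            if not outcome_binary or 0 < sub[outcome].sum() < n:
                break
        else:
            raise RuntimeError("could not draw a bootstrap resample with both outcome classes")
        try:
            boots[b], _, _, _, _ = _effects_once(
                sub, exposure, mediator, outcome, covariates, outcome_binary, n_mc, rng
            )
        except SeparationError:
            boots[b] = np.nan
    boots = boots[np.isfinite(boots)]
    if len(boots) == 0:
        raise RuntimeError("all bootstrap resamples failed")
    ci_low, ci_high = (float(v) for v in np.percentile(boots, [2.5, 97.5]))
    p = float(min(1.0, 2.0 * min((boots <= 0).mean(), (boots >= 0).mean())))
    prop = float(acme / total) if abs(total) > 1e-12 else float("nan")
    return MediationResult(
        acme=float(acme),
        ade=float(ade),
        total=float(total),
        prop_mediated=prop,
        ci_low=ci_low,
        ci_high=ci_high,
        p=p,
        n_boot=int(len(boots)),
        covariates=covariates,
        acme_control=float(acme0),
        acme_treated=float(acme1),
    )


def adjusted_associations(table: CohortTable, target: str, predictors, covariates=()) -> pd.DataFrame:
    """Covariate-adjusted standardized logistic coefficients per predictor.

    For each predictor (standardized to unit variance), fits
    ``target ~ predictor + covariates`` by logistic regression and reports the
    standardized beta with its Wald 95% CI and p-value — the forest-plot
    contract for validating nominated mediators.
    """
    if table.spec(target).kind != "binary":
        raise ValueError(f"target {target!r} must be binary")
    rows = []
    for pred in predictors:
        cols = [pred, *covariates]
        sub = table.df[[target, *cols]].dropna()
        z = sub[pred].to_numpy(dtype=float)
        z = (z - z.mean()) / z.std()
        X = np.column_stack([np.ones(len(sub)), z] + [sub[c].to_numpy(dtype=float) for c in covariates])
        y = sub[target].to_numpy(dtype=float)
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0)
        beta = float(fit.params[1])
        se = float(fit.bse[1])
        rows.append(
            {
                "predictor": pred,
                "beta_std": beta,
                "ci_low": beta - 1.959964 * se,
                "ci_high": beta + 1.959964 * se,
                "p": float(fit.pvalues[1]),
                "n": len(sub),
            }
        )
    return pd.DataFrame(rows)
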