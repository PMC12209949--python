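"""Likelihood-ratio conditional-independence testing for mixed data.

The conditional-Gaussian (CG) model treats the binary variables in a set as
jointly multinomial and the continuous variables as Gaussian within each
binary configuration (stratum).  The test of X independent of Y given S
compares maximized CG log-likelihoods:

    G2 = 2 * [ l(X,Y,S) + l(S) - l(X,S) - l(Y,S) ]

referred to a chi-square whose degrees of freedom are the matching
difference of free-parameter counts.  With no binary variables this reduces
to the Gaussian partial-correlation likelihood-ratio test (df = 1); with
only binary variables it reduces to the classical G-test on the contingency
table.

``CGTester`` holds the data once and caches both log-likelihoods (keyed by
variable set) and test results (keyed by pair + conditioning set), so a full
PC run — and a sensitivity sweep across several alpha levels — reuses every
statistic it has already computed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable

logger = logging.getLogger(__name__)

__all__ = ["MixedCIResult", "CGTester", "cg_loglik", "lr_ci_test", "NumericalDegeneracyError"]

_LN_2PI = math.log(2.0 * math.pi)


class NumericalDegeneracyError(RuntimeError):
    """Raised when a stratum covariance stays singular even after pooling."""


@dataclass(frozen=True)
class MixedCIResult:
    """Outcome of one likelihood-ratio CI test."""

    x: str
    y: str
    s: tuple[str, ...]
    statistic: float
    df: int
    p: float
    degenerate: bool = False

    def independent(self, alpha: float) -> bool:
        return self.p > alpha


class CGTester:
    """Conditional-Gaussian likelihood machinery over a fixed data matrix.

    Parameters
    ----------
    data
        A :class:`~tiernet.cohort.CohortTable` or a DataFrame plus ``kinds``.
    kinds
        Mapping name -> {"continuous", "binary"}; required for raw frames.
    covariance
        ``"stratum"`` (default) fits a separate covariance per binary
        configuration, falling back to a pooled within-stratum covariance
        whenever any non-empty stratum has fewer rows than the continuous
        dimension + 2; ``"pooled"`` always shares the covariance.
    """

    def __init__(self, data, kinds: dict[str, str] | None = None, covariance: str = "stratum"):
        if isinstance(data, CohortTable):
            df, kinds = data.df, data.kinds
        elif isinstance(data, pd.DataFrame):
            df = data
            if kinds is None:
                raise ValueError("kinds mapping required when passing a bare DataFrame")
        else:
            raise TypeError(f"unsupported data container {type(data)!r}")
        if covariance not in ("stratum", "pooled"):
            raise ValueError("covariance must be 'stratum' or 'pooled'")
        self.names: list[str] = list(df.columns)
        self._idx = {n: i for i, n in enumerate(self.names)}
        self.X = np.ascontiguousarray(df.to_numpy(dtype=np.float64))
        self.n = self.X.shape[0]
        self.is_binary = np.array([kinds[n] == "binary" for n in self.names])
        self.covariance = covariance
        self._ll_cache: dict[frozenset, tuple[float, int]] = {}
        self._test_cache: dict[tuple, MixedCIResult] = {}
        self.n_tests = 0

    # -- log-likelihood ---------------------------------------------------------

    def loglik(self, variables) -> tuple[float, int]:
        """Maximized CG log-likelihood and free-parameter count for a set."""
        idx = frozenset(self._idx[v] if isinstance(v, str) else int(v) for v in variables)
        if not idx:
            raise ValueError("variable set must be non-empty")
        cached = self._ll_cache.get(idx)
        if cached is None:
            cached = self._loglik_uncached(idx)
            self._ll_cache[idx] = cached
        return cached

    def _loglik_uncached(self, idx: frozenset) -> tuple[float, int]:
        disc = sorted(i for i in idx if self.is_binary[i])
        cont = sorted(i for i in idx if not self.is_binary[i])
        n = self.n
        cols = self.X[:, disc + cont]
        if np.isnan(cols).any():
            raise ValueError("missing cells among test variables; impute first")

        ll = 0.0
        n_params = 0
        if disc:
            code = np.zeros(n, dtype=np.int64)
            for j, i in enumerate(disc):
                code |= (self.X[:, i] > 0.5).astype(np.int64) << j
            counts = np.bincount(code, minlength=2 ** len(disc))
            nz = counts[counts > 0]
            ll += float(np.sum(nz * np.log(nz / n)))
            n_params += 2 ** len(disc) - 1
            if not cont:
                return ll, n_params
            order = np.argsort(code, kind="stable")
            Xc = self.X[np.ix_(order, cont)]
            bounds = np.concatenate(([0], np.cumsum(counts)))
            groups = [
                Xc[bounds[k] : bounds[k + 1]]
                for k in range(len(counts))
                if counts[k] > 0
            ]
        else:
            groups = [self.X[:, cont]]

        c = len(cont)
        m = len(groups)
        pooled = self.covariance == "pooled" or any(g.shape[0] < c + 2 for g in groups)
        if not pooled:
            total = 0.0
            for g in groups:
                val = self._gauss_ml_ll(g)
                if val is None:
                    pooled = True
                    break
                total += val
            if not pooled:
                ll += total
                n_params += m * (c + c * (c + 1) // 2)
                return ll, n_params
        # pooled within-stratum covariance, stratum-specific means
        sw = np.zeros((c, c))
        for g in groups:
            if g.shape[0] == 0:
                continue
            d = g - g.mean(axis=0)
            sw += d.T @ d
        sw /= n
        sign, logdet = np.linalg.slogdet(sw)
        if sign <= 0 or not np.isfinite(logdet):
            raise NumericalDegeneracyError("pooled covariance singular")
        ll += -0.5 * n * (c * _LN_2PI + logdet + c)
        n_params += m * c + c * (c + 1) // 2
        return ll, n_params

    @staticmethod
    def _gauss_ml_ll(g: np.ndarray) -> float | None:
        nk, c = g.shape
        d = g - g.mean(axis=0)
        s = (d.T @ d) / nk
        sign, logdet = np.linalg.slogdet(s)
        if sign <= 0 or not np.isfinite(logdet):
            return None
        return -0.5 * nk * (c * _LN_2PI + logdet + c)

    # -- the test ---------------------------------------------------------------

    def test(self, x: str, y: str, s=()) -> MixedCIResult:
        """Likelihood-ratio test of ``x`` independent of ``y`` given ``s``."""
        if x == y:
            raise ValueError("x and y must differ")
        s_t = tuple(sorted(s))
        if x in s_t or y in s_t:
            raise ValueError("x and y must not appear in the conditioning set")
        a, b = sorted((x, y))
        key = (a, b, s_t)
        cached = self._test_cache.get(key)
        if cached is not None:
            return cached
        self.n_tests += 1
        result = self._test_uncached(a, b, s_t)
        # store under canonical order but report caller's orientation-free names
        self._test_cache[key] = result
        return result

    def _test_uncached(self, x: str, y: str, s_t: tuple[str, ...]) -> MixedCIResult:
        s_set = set(s_t)
        try:
            ll_xs, k_xs = self.loglik({x} | s_set)
            ll_ys, k_ys = self.loglik({y} | s_set)
            if s_set:
                ll_s, k_s = self.loglik(s_set)
            else:
                ll_s, k_s = 0.0, 0
        except NumericalDegeneracyError as exc:
            logger.warning("degenerate CI test (%s, %s | %s): %s — treated as independent", x, y, s_t, exc)
            return MixedCIResult(x, y, s_t, 0.0, 1, 1.0, degenerate=True)
        try:
            ll_xys, k_xys = self.loglik({x, y} | s_set)
        except NumericalDegeneracyError:
            # the null terms are fine but the saturated covariance is singular:
            # x and y are linearly deterministic given s — maximal dependence
            return MixedCIResult(x, y, s_t, float("inf"), 1, 0.0)
        stat = 2.0 * (ll_xys + ll_s - ll_xs - ll_ys)
        if stat < 0:
            if stat < -1e-6:
                logger.warning("negative LR statistic %.3g for (%s, %s | %s); clamped", stat, x, y, s_t)
            stat = 0.0
        df = k_xys + k_s - k_xs - k_ys
        if df <= 0:
            logger.warning("non-positive df for (%s, %s | %s) — treated as independent", x, y, s_t)
            return MixedCIResult(x, y, s_t, stat, 1, 1.0, degenerate=True)
        p = float(stats.chi2.sf(stat, df))
        return MixedCIResult(x, y, s_t, float(stat), int(df), p)


def cg_loglik(table: CohortTable, variables) -> tuple[float, int]:
    """Maximized conditional-Gaussian log-likelihood of a variable set.

    Convenience wrapper over :class:`CGTester` for one-off use; build a
    tester directly when evaluating many sets on the same table.
    """
    return CGTester(table).loglik(variables)


def lr_ci_test(table: CohortTable, x: str, y: str, s=()) -> MixedCIResult:
    """One-off likelihood-ratio CI test of ``x`` and ``y`` given ``s``."""
    return CGTester(table).test(x, y, s)
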