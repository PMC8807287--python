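"""Classical endpoints: pooled-variance t-tests (from raw data or printed
summaries), JZS Bayes factors, chi-square for 2x2 tables, Spearman and
partial Spearman correlations, PCA composite scores and Bonferroni
adjustment.

Conventions
-----------
* The two-sample t is the pooled-variance Student form with
  df = n_a + n_b - 2 (Welch available behind a flag): every recomputable
  published value in this family of study tables matches the pooled form.
* Bayes factors follow the Jeffreys-Zellner-Siow default: a Cauchy prior of
  scale r (default sqrt(2)/2) on the standardized effect, integrated over the
  variance-mixture parameter g with an inverse-gamma(1/2, r^2/2) prior.  Both
  directions are always reported: bf10 (evidence for a difference) and
  bf01 = 1/bf10.
* Printed-table reproduction rounds statistics to one decimal, half away
  from zero (:func:`round_printed`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .resampling import InferenceError

__all__ = [
    "TTestResult",
    "CompositeScore",
    "pooled_t_from_summary",
    "two_sample_t",
    "one_sample_t",
    "jzs_bayes_factor",
    "chi_square_2x2",
    "spearman",
    "partial_spearman",
    "pca_composite",
    "bonferroni",
    "round_printed",
]

DEFAULT_CAUCHY_SCALE = math.sqrt(2.0) / 2.0


def round_printed(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, as journal tables do."""
    if np.isnan(x):
        return x
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    bf10: float
    bf01: float
    mean_diff: float
    summary_a: Tuple[float, float, int]  # (mean, sd, n)
    summary_b: Optional[Tuple[float, float, int]]
    kind: str  # "pooled", "welch" or "one-sample"

    def to_dict(self) -> dict:
        d = {
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "bf10": self.bf10,
            "bf01": self.bf01,
            "mean_diff": self.mean_diff,
            "kind": self.kind,
            "summary_a": list(self.summary_a),
        }
        if self.summary_b is not None:
            d["summary_b"] = list(self.summary_b)
        return d


def jzs_bayes_factor(
    t: float,
    n_a: int,
    n_b: Optional[int] = None,
    cauchy_scale: float = DEFAULT_CAUCHY_SCALE,
) -> Tuple[float, float]:
    """Jeffreys-Zellner-Siow Bayes factor for a t statistic.

    For a two-sample design pass both group sizes (effective
    N = n_a*n_b/(n_a+n_b), df = n_a+n_b-2); for one-sample pass only ``n_a``
    (N = n_a, df = n_a-1).  Returns ``(bf10, bf01)``.

    The marginal likelihood under the alternative is the one-dimensional
    integral over g of

        (1 + N g)^(-1/2) * (1 + t^2 / ((1 + N g) df))^(-(df+1)/2) * pi(g)

    with pi(g) inverse-gamma(1/2, r^2/2) — the mixture representation of the
    Cauchy(0, r) prior on the standardized effect — divided by the null
    likelihood (1 + t^2/df)^(-(df+1)/2).
    """
    if n_b is None:
        eff_n = float(n_a)
        df = n_a - 1
    else:
        eff_n = n_a * n_b / (n_a + n_b)
        df = n_a + n_b - 2
    if df < 1:
        raise InferenceError(f"JZS Bayes factor needs df >= 1, got df={df}")
    if not np.isfinite(t):
        raise InferenceError("JZS Bayes factor undefined for non-finite t")
    r2 = cauchy_scale**2
    t2 = float(t) ** 2

    def integrand(g: float) -> float:
        shrink = 1.0 + eff_n * g
        like = shrink**-0.5 * (1.0 + t2 / (shrink * df)) ** (-(df + 1) / 2.0)
        prior = (
            (r2 / 2.0) ** 0.5
            / math.gamma(0.5)
            * g**-1.5
            * math.exp(-r2 / (2.0 * g))
        )
        return like * prior

    alt, abserr = integrate.quad(
        integrand, 0.0, np.inf, epsabs=0.0, epsrel=1e-10, limit=200
    )
    if not np.isfinite(alt) or alt <= 0 or abserr > 1e-6 * alt:
        raise InferenceError(
            f"JZS quadrature did not converge (value={alt!r}, abserr={abserr!r})"
        )
    null = (1.0 + t2 / df) ** (-(df + 1) / 2.0)
    bf10 = alt / null
    return bf10, 1.0 / bf10


def _finish_two_sample(
    t: float, df: float, summary_a, summary_b, kind: str
) -> TTestResult:
    if np.isfinite(t):
        p = 2.0 * stats.t.sf(abs(t), df)
        try:
            bf10, bf01 = jzs_bayes_factor(t, summary_a[2], summary_b[2])
        except InferenceError:
            bf10 = bf01 = math.nan
    else:
        p, bf10, bf01 = 0.0, math.inf, 0.0
    return TTestResult(
        t=t,
        df=df,
        p=p,
        bf10=bf10,
        bf01=bf01,
        mean_diff=summary_a[0] - summary_b[0],
        summary_a=summary_a,
        summary_b=summary_b,
        kind=kind,
    )


def pooled_t_from_summary(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
) -> TTestResult:
    """Student pooled-variance two-sample t from group summaries.

    Equals the raw-data pooled t for any samples having these summaries.  A
    zero pooled variance gives t = 0 when the means agree and signed infinity
    (flagged via p = 0, bf10 = inf) otherwise.
    """
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    if n_a < 2 or n_b < 2:
        raise InferenceError("each group needs n >= 2")
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    diff = mean_a - mean_b
    if sp2 == 0.0:
        t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    else:
        t = diff / math.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    return _finish_two_sample(
        t, df, (mean_a, sd_a, n_a), (mean_b, sd_b, n_b), "pooled"
    )


def two_sample_t(
    values_a: Sequence[float], values_b: Sequence[float], welch: bool = False
) -> TTestResult:
    """Two-sample t from raw data; pooled-variance Student by default, Welch
    behind the flag.  Missing values dropped per group."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise InferenceError("each group needs n >= 2 non-missing values")
    sa = (float(a.mean()), float(a.std(ddof=1)), int(a.size))
    sb = (float(b.mean()), float(b.std(ddof=1)), int(b.size))
    if not welch:
        return pooled_t_from_summary(*sa, *sb)
    t, _ = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return _finish_two_sample(float(t), float(df), sa, sb, "welch")


def one_sample_t(values: Sequence[float], mu0: float = 0.0) -> TTestResult:
    """One-sample Student t against ``mu0``; df = n - 1."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 2:
        raise InferenceError("one-sample t needs n >= 2")
    sd = float(x.std(ddof=1))
    diff = float(x.mean()) - mu0
    df = n - 1
    if sd == 0.0:
        t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    else:
        t = diff / (sd / math.sqrt(n))
    if np.isfinite(t):
        p = 2.0 * stats.t.sf(abs(t), df)
        try:
            bf10, bf01 = jzs_bayes_factor(t, n)
        except InferenceError:
            bf10 = bf01 = math.nan
    else:
        p, bf10, bf01 = 0.0, math.inf, 0.0
    return TTestResult(
        t=t,
        df=df,
        p=p,
        bf10=bf10,
        bf01=bf01,
        mean_diff=diff,
        summary_a=(float(x.mean()), sd, n),
        summary_b=None,
        kind="one-sample",
    )


def chi_square_2x2(counts) -> Tuple[float, int, float]:
    """Pearson chi-square without continuity correction on a 2x2 table.

    Returns ``(chi2, df=1, p)``; a zero row or column marginal leaves the
    statistic undefined and yields ``(nan, 1, nan)``.
    """
    table = np.asarray(counts)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if np.any(table < 0) or not np.all(np.equal(np.mod(table, 1), 0)):
        raise ValueError("table entries must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return math.nan, 1, math.nan
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def spearman(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; p-value via the
    t-approximation.  Pairs with missing values are dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise InferenceError("Spearman correlation needs n >= 3 complete pairs")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    covariates: Optional[np.ndarray] = None,
) -> Tuple[float, float]:
    """Partial Spearman correlation of x and y given covariates.

    All variables are rank-transformed (average ranks), x and y are
    residualized on the covariate ranks (plus intercept) by least squares,
    and the residuals are Pearson-correlated; p uses the t-approximation
    with df = n - 2 - k.  With no covariates this reduces exactly to
    :func:`spearman`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None or (hasattr(covariates, "__len__") and len(covariates) == 0):
        return spearman(x, y)
    Z = np.atleast_2d(np.asarray(covariates, dtype=float))
    if Z.shape[0] != x.size:
        Z = Z.T
    ok = ~(np.isnan(x) | np.isnan(y) | np.isnan(Z).any(axis=1))
    x, y, Z = x[ok], y[ok], Z[ok]
    n, k = Z.shape
    if n < k + 4:
        raise InferenceError(f"too few complete cases (n={n}) for {k} covariates")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rz = np.column_stack([np.ones(n)] + [stats.rankdata(Z[:, j]) for j in range(k)])
    if np.linalg.matrix_rank(rz) < rz.shape[1]:
        raise InferenceError("covariate matrix is rank deficient after ranking")
    def _resid(v: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(rz, v, rcond=None)
        return v - rz @ beta
    ex, ey = _resid(rx), _resid(ry)
    denom = math.sqrt(float(ex @ ex) * float(ey @ ey))
    if denom == 0.0:
        raise InferenceError("zero rank variance after residualization")
    rho = float(ex @ ey) / denom
    df = n - 2 - k
    tstat = rho * math.sqrt(df / max(1e-300, 1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(tstat), df)
    return rho, float(p)


@dataclass
class CompositeScore:
    """First-principal-component composite over z-scored measures."""

    loadings: pd.Series
    scores: np.ndarray
    variance_explained: float
    orientation: int  # +1 if no sign flip was applied, -1 otherwise
    dropped_columns: Tuple[str, ...] = ()


def pca_composite(table: pd.DataFrame) -> CompositeScore:
    """First principal component of z-scored columns as a global index.

    Columns are standardized (ddof=1); zero-variance columns are dropped
    with a warning.  The component sign is oriented so the composite
    correlates positively with the row mean of the z-scored inputs, making
    "higher composite = better on average" stable across runs.
    """
    if table.isna().any().any():
        raise InferenceError("pca_composite requires complete cases (drop missing upstream)")
    if len(table) < 2:
        raise InferenceError("pca_composite needs at least 2 rows")
    sds = table.std(ddof=1)
    dropped = tuple(table.columns[sds == 0.0])
    if dropped:
        warnings.warn(f"dropping zero-variance columns: {dropped}", stacklevel=2)
        table = table.drop(columns=list(dropped))
    if table.shape[1] == 0:
        raise InferenceError("no columns with variance remain")
    Z = (table - table.mean()) / table.std(ddof=1)
    Zv = Z.to_numpy(dtype=float)
    corr = Zv.T @ Zv / (len(Z) - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    v1 = eigvecs[:, 0]
    scores = Zv @ v1
    orientation = 1
    row_mean = Zv.mean(axis=1)
    if scores.size > 1 and np.dot(scores - scores.mean(), row_mean - row_mean.mean()) < 0:
        v1, scores, orientation = -v1, -scores, -1
    total = eigvals.sum()
    var_explained = float(eigvals[0] / total) if total > 0 else math.nan
    return CompositeScore(
        loadings=pd.Series(v1, index=table.columns, name="pc1"),
        scores=scores,
        variance_explained=var_explained,
        orientation=orientation,
        dropped_columns=dropped,
    )


def bonferroni(p_values: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m).  ``m`` defaults to the number of
    p-values and must be at least that."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than number of tests {p.size}")
    return np.minimum(1.0, p * m)
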