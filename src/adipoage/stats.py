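"""Shared statistical primitives.

Small, heavily reused pieces: the two-sample Wilcoxon rank-sum wrapper (the
workhorse test throughout the single-cell and proportion comparisons), the
rank-based inverse-normal transform used to normalise phenotypes, ordinary
least squares via explicit normal equations, and multiple-testing
adjustments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


def rank_sum(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    Returns ``(u, p)`` where ``u`` is the Mann-Whitney U statistic of the
    first group (rank sum of ``x`` minus its minimum), the convention printed
    by common statistical software.  Uses the exact null distribution when
    there are no ties and both groups are small, otherwise the normal
    approximation with tie correction and continuity correction.

    Degenerate case: if every pooled value is identical the test carries no
    information and ``(n1*n2/2, 1.0)`` is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return x.size * y.size / 2.0, 1.0
    n_small = max(x.size, y.size) <= 25
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (n_small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse-normal transform.

    Maps values onto standard-normal quantiles via
    ``Phi^{-1}((rank - 0.5) / n)`` with average ranks for ties.  Monotone in
    the input.  Raises if the input is constant (the transform is undefined).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-d vector")
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values in input")
    if np.all(v == v[0]):
        raise ValueError("inverse-normal transform undefined for constant input")
    ranks = sps.rankdata(v, method="average")
    return sps.norm.ppf((ranks - 0.5) / v.size)


@dataclass
class OLSFit:
    """Least-squares fit summary: per-column coefficients and Wald t tests."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    df_resid: int
    sigma2: float
    n: int

    def term(self, name: str) -> dict:
        i = self.names.index(name)
        return {
            "term": name,
            "beta": float(self.beta[i]),
            "se": float(self.se[i]),
            "z": float(self.tvalues[i]),
            "p": float(self.pvalues[i]),
        }


def ols_fit(X: np.ndarray, y: np.ndarray, names: list[str] | None = None) -> OLSFit:
    """OLS of ``y`` on the columns of ``X`` with t-reference Wald tests.

    ``X`` must already contain an intercept column if one is wanted.  Raises
    on rank deficiency, naming the first collinear column.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if names is None:
        names = [f"x{i}" for i in range(k)]
    if n <= k:
        raise ValueError("more parameters than observations")
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = max(n, k) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    bad = np.where(diag <= tol)[0]
    if bad.size:
        raise ValueError(f"design matrix rank-deficient; collinear column: {names[bad[0]]}")
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - X @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    rinv = np.linalg.inv(r)
    cov = sigma2 * (rinv @ rinv.T)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * sps.t.sf(np.abs(tvals), df)
    return OLSFit(list(names), beta, se, tvals, np.clip(pvals, 0.0, 1.0), df, sigma2, n)


def adjust_pvalues(p, method: str = "bonferroni") -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjustment; order-invariant."""
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "bh":
        order = np.argsort(p, kind="mergesort")
        ranked = p[order] * m / (np.arange(m) + 1)
        cummin = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(cummin, 1.0)
        return out
    raise ValueError(f"unknown adjustment method: {method}")
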