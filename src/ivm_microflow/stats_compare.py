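"""Longitudinal cohort statistics: repeated-measures ANOVA with
Greenhouse-Geisser correction, Bonferroni post-tests, mean +/- SD summaries.

The design is one within-subject factor (observation day).  Sphericity is
checked with Mauchly's test; when violated (p < 0.05, configurable) both
numerator and denominator degrees of freedom are multiplied by the
Greenhouse-Geisser epsilon computed from the sample covariance of the time
points.  Post-hoc paired comparisons between individual days are run only
once the omnibus test is significant, with Bonferroni adjustment
p_adj = min(1, m * p).  Subjects with incomplete series (e.g. fracture
censoring) are listwise-deleted, as classical RM-ANOVA requires complete
cases.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import InsufficientDataError

__all__ = [
    "StatsResult",
    "rm_anova",
    "bonferroni",
    "summarize",
    "gg_epsilon",
    "mauchly_test",
    "simulate_null_type_one_error",
]

SPHERICITY_ALPHA = 0.05
OMNIBUS_ALPHA = 0.05


@dataclass
class StatsResult:
    """Outcome of the repeated-measures ANOVA layer."""

    F: float
    df1: float
    df2: float
    p: float
    epsilon_gg: float
    sphericity_applied: bool
    mauchly_W: float
    mauchly_p: float
    n_subjects: int
    k_levels: int
    posthoc: list[tuple[tuple[int, int], float, float]] = field(
        default_factory=list
    )  # (pair, raw p, Bonferroni-adjusted p)
    summary: pd.DataFrame | None = None


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a k x k time-point covariance matrix.

    epsilon = tr(S*)^2 / ((k-1) * tr(S*^2)) with S* the double-centered
    covariance; bounded in [1/(k-1), 1].
    """
    S = np.asarray(cov, dtype=float)
    k = S.shape[0]
    C = np.eye(k) - np.ones((k, k)) / k
    Sc = C @ S @ C
    num = np.trace(Sc) ** 2
    den = (k - 1) * np.sum(Sc * Sc)
    if den <= 0:
        return 1.0
    eps = float(num / den)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def mauchly_test(X: np.ndarray) -> tuple[float, float]:
    """Mauchly's sphericity test on an (n subjects x k levels) data matrix.

    Returns (W, p).  With k = 2 sphericity holds trivially (W = 1, p = 1).
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if k <= 2:
        return 1.0, 1.0
    S = np.cov(X, rowvar=False)
    # orthonormal contrasts (normalized Helmert)
    C = np.zeros((k - 1, k))
    for i in range(k - 1):
        C[i, : i + 1] = 1.0
        C[i, i + 1] = -(i + 1)
        C[i] /= np.sqrt((i + 1) + (i + 1) ** 2)
    A = C @ S @ C.T
    eig = np.linalg.eigvalsh(A)
    eig = np.clip(eig, 1e-300, None)
    q = k - 1
    W = float(np.exp(np.sum(np.log(eig)) - q * np.log(np.mean(eig))))
    d = 1.0 - (2.0 * q * q + q + 2.0) / (6.0 * q * (n - 1))
    chi2 = -(n - 1) * d * np.log(max(W, 1e-300))
    dof = q * (q + 1) / 2.0 - 1.0
    p = float(_sps.chi2.sf(chi2, dof))
    return W, p


def _rm_anova_matrix(X: np.ndarray) -> tuple[float, float, float]:
    """One-way within-subject F from sums of squares on (n x k) data."""
    n, k = X.shape
    grand = X.mean()
    col_means = X.mean(axis=0)
    row_means = X.mean(axis=1)
    ss_time = n * np.sum((col_means - grand) ** 2)
    resid = X - col_means[None, :] - row_means[:, None] + grand
    ss_err = np.sum(resid ** 2)
    df1 = k - 1
    df2 = (n - 1) * (k - 1)
    ms_time = ss_time / df1
    ms_err = ss_err / df2
    F = ms_time / ms_err if ms_err > 0 else np.inf
    return float(F), float(df1), float(df2)


def rm_anova(
    table: pd.DataFrame,
    value: str = "value",
    within: str = "day",
    subject: str = "subject_id",
    sphericity_alpha: float = SPHERICITY_ALPHA,
    posthoc_alpha: float = OMNIBUS_ALPHA,
) -> StatsResult:
    """One-way repeated-measures ANOVA over the within-subject factor.

    Incomplete subjects are listwise-deleted.  When Mauchly's test rejects
    sphericity at ``sphericity_alpha``, the p-value is recomputed with both
    degrees of freedom multiplied by the Greenhouse-Geisser epsilon.
    Bonferroni-adjusted paired t-tests between factor levels are run when
    the omnibus test is significant.
    """
    wide = table.pivot_table(
        index=subject, columns=within, values=value, aggfunc="first"
    ).dropna()
    X = wide.to_numpy(dtype=float)
    n, k = X.shape
    if n < 2 or k < 2:
        raise InsufficientDataError(
            f"need >= 2 complete subjects and >= 2 levels, got n={n}, k={k}"
        )
    F, df1, df2 = _rm_anova_matrix(X)
    W, p_sph = mauchly_test(X)
    eps = gg_epsilon(np.cov(X, rowvar=False)) if k > 2 else 1.0
    applied = bool(k > 2 and p_sph < sphericity_alpha)
    if applied:
        df1_adj, df2_adj = df1 * eps, df2 * eps
    else:
        df1_adj, df2_adj = df1, df2
    p = float(_sps.f.sf(F, df1_adj, df2_adj))

    posthoc: list[tuple[tuple[int, int], float, float]] = []
    if p < posthoc_alpha and k >= 2:
        levels = list(wide.columns)
        pairs = list(itertools.combinations(range(k), 2))
        raw = []
        for i, j in pairs:
            t_res = _sps.ttest_rel(X[:, i], X[:, j])
            raw.append(float(t_res.pvalue))
        adj = bonferroni(raw)
        posthoc = [
            ((levels[i], levels[j]), rp, ap)
            for (i, j), rp, ap in zip(pairs, raw, adj)
        ]

    summary = pd.DataFrame(
        {
            within: list(wide.columns),
            "mean": X.mean(axis=0),
            "sd": X.std(axis=0, ddof=1),
            "n": n,
        }
    )
    return StatsResult(
        F=F,
        df1=df1_adj,
        df2=df2_adj,
        p=p,
        epsilon_gg=eps,
        sphericity_applied=applied,
        mauchly_W=W,
        mauchly_p=p_sph,
        n_subjects=n,
        k_levels=k,
        posthoc=posthoc,
        summary=summary,
    )


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Bonferroni adjustment: p_adj = min(1, m * p); m defaults to len(p)."""
    p = list(map(float, p_values))
    if m is None:
        m = len(p)
    if m < 1:
        raise ValueError("m must be >= 1")
    return [min(1.0, m * pi) for pi in p]


def summarize(
    table: pd.DataFrame,
    value: str = "value",
    by: tuple[str, ...] = ("group", "day"),
) -> pd.DataFrame:
    """Mean +/- SD (ddof=1) and n per cell; SD is NaN for single-value cells."""
    if table.empty:
        raise InsufficientDataError("empty table")
    g = table.groupby(list(by))[value]
    out = g.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
    return out.reset_index()


def simulate_null_type_one_error(
    n_subjects: int,
    covariance: np.ndarray,
    n_replicates: int,
    seed: int,
    alpha: float = 0.05,
    sphericity_alpha: float = SPHERICITY_ALPHA,
) -> float:
    """Empirical type-I error of the sphericity-corrected RM-ANOVA.

    Draws ``n_replicates`` null datasets (zero mean, the given time-point
    covariance), runs the two-stage Mauchly/Greenhouse-Geisser procedure on
    each, and returns the rejection fraction at ``alpha``.
    """
    cov = np.asarray(covariance, dtype=float)
    k = cov.shape[0]
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(cov)
    rejections = 0
    for _ in range(n_replicates):
        X = rng.standard_normal((n_subjects, k)) @ L.T
        F, df1, df2 = _rm_anova_matrix(X)
        _, p_sph = mauchly_test(X)
        if k > 2 and p_sph < sphericity_alpha:
            eps = gg_epsilon(np.cov(X, rowvar=False))
            df1, df2 = df1 * eps, df2 * eps
        if _sps.f.sf(F, df1, df2) < alpha:
            rejections += 1
    return rejections / n_replicates
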