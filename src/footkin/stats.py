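"""Inferential statistics for the turnout study design, from first
principles.

* One-way repeated-measures ANOVA with the Greenhouse-Geisser sphericity
  correction and Bonferroni-adjusted paired-t pairwise comparisons.
* SPSS-style stepwise multiple linear regression (forward entry at
  p <= 0.05, backward removal at p >= 0.10 by default).
* Pearson product-moment correlation with a two-sided t-based p-value.

Only ``numpy`` linear algebra and ``scipy.stats`` distribution functions
are used; the sums of squares, the epsilon estimate and the selection
logic are computed explicitly so they can be audited against brute-force
oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "RmAnovaResult",
    "StepwiseResult",
    "rm_anova_gg",
    "stepwise_regression",
    "pearson_r",
]


@dataclass
class RmAnovaResult:
    """One-way within-subject ANOVA with Greenhouse-Geisser correction."""

    F: float
    df_num: int
    df_den: int
    epsilon_gg: float
    p_gg: float
    p_uncorrected: float
    pairwise_p: np.ndarray  # (k, k) Bonferroni-adjusted paired-t p-values
    condition_means: np.ndarray = field(default_factory=lambda: np.array([]))


def rm_anova_gg(data: np.ndarray) -> RmAnovaResult:
    """Repeated-measures ANOVA on a complete subjects x conditions matrix.

    The F ratio is MS_conditions / MS_(subject x condition); the
    Greenhouse-Geisser epsilon is

        eps = (tr S)^2 / ((k - 1) tr S^2)

    with S the double-centred covariance of the condition columns, and the
    corrected p uses the F distribution at (eps (k-1), eps (k-1)(n-1))
    degrees of freedom.  Pairwise comparisons are two-sided paired t-tests
    with Bonferroni factor m = k(k-1)/2, capped at 1.

    Raises
    ------
    ValueError
        For missing cells, fewer than 2 subjects, or a single condition.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be a subjects x conditions matrix")
    if not np.isfinite(X).all():
        raise ValueError("missing cells: the design must be complete")
    n, k = X.shape
    if k < 2:
        raise ValueError("need >= 2 conditions")
    if n < 2:
        raise ValueError("need >= 2 subjects")

    grand = X.mean()
    subj = X.mean(axis=1)
    cond = X.mean(axis=0)
    ss_cond = n * np.sum((cond - grand) ** 2)
    resid = X - subj[:, None] - cond[None, :] + grand
    ss_err = np.sum(resid**2)
    df_num = k - 1
    df_den = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_num
    ms_err = ss_err / df_den
    F = ms_cond / ms_err

    # Greenhouse-Geisser epsilon from the double-centred covariance
    S = np.cov(X, rowvar=False, ddof=1)
    C = np.eye(k) - 1.0 / k
    S_t = C @ S @ C
    tr = np.trace(S_t)
    tr2 = np.sum(S_t * S_t)  # trace of S_t @ S_t for symmetric S_t
    eps = (tr**2) / (df_num * tr2)
    eps = float(min(eps, 1.0))

    p_unc = float(sps.f.sf(F, df_num, df_den))
    p_gg = float(sps.f.sf(F, eps * df_num, eps * df_den))

    m = k * (k - 1) // 2
    pw = np.full((k, k), np.nan)
    for i in range(k):
        pw[i, i] = 1.0
        for j in range(i + 1, k):
            d = X[:, i] - X[:, j]
            sd = d.std(ddof=1)
            if sd == 0:
                p_raw = 0.0 if d.mean() != 0 else 1.0
            else:
                t = d.mean() / (sd / np.sqrt(n))
                p_raw = float(2 * sps.t.sf(abs(t), n - 1))
            pw[i, j] = pw[j, i] = min(1.0, m * p_raw)

    return RmAnovaResult(
        F=float(F),
        df_num=df_num,
        df_den=df_den,
        epsilon_gg=eps,
        p_gg=p_gg,
        p_uncorrected=p_unc,
        pairwise_p=pw,
        condition_means=cond,
    )


@dataclass
class StepwiseResult:
    """Stepwise-regression outcome: retained predictors and final OLS fit."""

    selected: list[int]
    names: list[str]
    coefficients: np.ndarray  # intercept first, then selected predictors
    r_squared: float
    adj_r_squared: float
    F: float
    df_num: int
    df_den: int
    p_value: float


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Least-squares fit with intercept.  Returns (beta, rss, XtX_inv)."""
    A = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    XtX = A.T @ A
    cond = np.linalg.cond(XtX)
    if cond > 1e12:
        raise np.linalg.LinAlgError(f"rank-deficient design (condition {cond:.3g})")
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ A.T @ y
    rss = float(np.sum((y - A @ beta) ** 2))
    return beta, rss, XtX_inv


def _coef_p_values(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Two-sided t-test p-value per (non-intercept) coefficient."""
    n, p = X.shape
    beta, rss, XtX_inv = _ols(y, X)
    dof = n - p - 1
    if dof <= 0:
        raise ValueError("not enough observations for the candidate model")
    sigma2 = rss / dof
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv)[1:], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1:] / se, np.inf)
    return 2 * sps.t.sf(np.abs(t), dof)


def stepwise_regression(
    y: np.ndarray,
    X: np.ndarray,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    names: list[str] | None = None,
) -> StepwiseResult:
    """Forward-entry / backward-removal multiple linear regression.

    At each step the excluded predictor with the smallest partial-F
    (equivalently coefficient-t) p-value enters if it is <= ``entry_p``;
    then included predictors with p >= ``removal_p`` are dropped (worst
    first).  Iterates to a fixed point.  With both thresholds at 1 every
    predictor enters and none leaves: the result is the full OLS fit.

    Raises
    ------
    numpy.linalg.LinAlgError
        For a rank-deficient candidate design.
    ValueError
        If n <= candidate count + 1.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if names is None:
        names = [f"x{j + 1}" for j in range(p)]
    if n <= p + 1:
        raise ValueError(f"need n > {p + 1} observations for {p} candidates")

    selected: list[int] = []
    for _ in range(2 * p + 2):  # fixed-point iteration with a cycle guard
        changed = False
        # forward step: best excluded candidate enters if p <= entry_p
        best_j, best_p = None, np.inf
        for j in (j for j in range(p) if j not in selected):
            pj = _coef_p_values(y, X[:, selected + [j]])[-1]
            if pj < best_p:
                best_j, best_p = j, pj
        if best_j is not None and best_p <= entry_p:
            selected.append(best_j)
            changed = True
        # backward steps: drop included predictors with p > removal_p
        while selected:
            pv = _coef_p_values(y, X[:, selected])
            worst = int(np.argmax(pv))
            if pv[worst] > removal_p:
                selected.pop(worst)
                changed = True
            else:
                break
        if not changed:
            break

    beta, rss, _ = _ols(y, X[:, selected] if selected else np.empty((n, 0)))
    tss = float(np.sum((y - y.mean()) ** 2))
    q = len(selected)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - q - 1) if n - q - 1 > 0 else np.nan
    if q and (1.0 - r2) > 0:
        F = (r2 / q) / ((1 - r2) / (n - q - 1))
        p_val = float(sps.f.sf(F, q, n - q - 1))
    elif q:
        F, p_val = np.inf, 0.0
    else:
        F, p_val = np.nan, np.nan
    return StepwiseResult(
        selected=list(selected),
        names=[names[j] for j in selected],
        coefficients=beta,
        r_squared=float(r2),
        adj_r_squared=float(adj),
        F=float(F),
        df_num=q,
        df_den=n - q - 1,
        p_value=p_val,
    )


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided p-value from
    t = r sqrt((n-2) / (1-r^2)).

    Raises
    ------
    ValueError
        For n < 3 or zero variance in either input.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero variance input")
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = float(2 * sps.t.sf(abs(t), n - 2))
    return r, p
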