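"""Inferential machinery: permutation ANOVA (PERMANOVA on scalars),
permutation post-hoc tests, Benjamini-Hochberg FDR, correlation tests, and a
multilinear regression validated with nested 5-fold cross-validation.

Permutation p-values use the add-one convention (1 + exceedances)/(1 + n_perm)
so the minimal attainable p is 1/(n_perm + 1), never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationTestResult",
    "RegressionReport",
    "permanova_oneway",
    "perm_posthoc",
    "fdr_bh",
    "pearson_test",
    "spearman",
    "nrmse",
    "nested_cv_regression",
]


@dataclass
class PermutationTestResult:
    statistic: float
    p_perm: float
    n_perm: int
    seed: int | None = None


@dataclass
class RegressionReport:
    """Full-sample OLS coefficients plus cross-validated prediction metrics."""

    beta: pd.Series
    beta_p: pd.Series
    f_stat: float
    df: tuple[int, int]
    f_p: float
    r2: float
    nrmse: float
    spearman: float
    residuals: np.ndarray = field(repr=False)
    n_iterations: int = 0
    seed: int | None = None


def _f_stat(values: np.ndarray, group_idx: list[np.ndarray], sst: float) -> float:
    n, g = values.size, len(group_idx)
    ssb = 0.0
    grand = values.mean()
    for idx in group_idx:
        ssb += idx.size * (values[idx].mean() - grand) ** 2
    ssw = sst - ssb
    return (ssb / (g - 1)) / (ssw / (n - g))


def permanova_oneway(
    values: Sequence[float],
    labels: Sequence[str],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PermutationTestResult:
    """One-way permutation ANOVA on a per-subject scalar.

    The statistic is the classical one-way ANOVA F, which equals the
    PERMANOVA pseudo-F under the Euclidean distance on scalars; the null is
    built by permuting group labels n_perm times.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need >= 2 groups")
    group_idx = [np.flatnonzero(labels == g) for g in uniq]
    if min(idx.size for idx in group_idx) < 2:
        small = uniq[int(np.argmin([idx.size for idx in group_idx]))]
        raise ValueError(f"group {small!r} has < 2 members")
    sst = float(((values - values.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("zero total variance")
    f_obs = _f_stat(values, group_idx, sst)
    rng = np.random.default_rng(seed)
    # vectorized permutations: shuffle values, group index positions fixed
    perms = rng.permuted(np.broadcast_to(values, (n_perm, values.size)), axis=1)
    grand = values.mean()
    g = uniq.size
    n = values.size
    ssb = np.zeros(n_perm)
    for idx in group_idx:
        ssb += idx.size * (perms[:, idx].mean(axis=1) - grand) ** 2
    f_null = (ssb / (g - 1)) / ((sst - ssb) / (n - g))
    p = (1 + int((f_null >= f_obs).sum())) / (1 + n_perm)
    return PermutationTestResult(statistic=float(f_obs), p_perm=p, n_perm=n_perm, seed=seed)


def perm_posthoc(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PermutationTestResult:
    """Two-group permutation test on the absolute mean difference."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    obs = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    perms = rng.permuted(
        np.broadcast_to(pooled, (n_perm, pooled.size)), axis=1
    )
    diff = np.abs(perms[:, : a.size].mean(axis=1) - perms[:, a.size :].mean(axis=1))
    p = (1 + int((diff >= obs).sum())) / (1 + n_perm)
    return PermutationTestResult(statistic=float(obs), p_perm=p, n_perm=n_perm, seed=seed)


def fdr_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson on average ranks)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    return float(sps.spearmanr(x, y).statistic)


def nrmse(y_pred: Sequence[float], y_true: Sequence[float]) -> float:
    """Root-mean-square error normalized by the observed range of y_true."""
    y_pred = np.asarray(y_pred, dtype=np.float64)
    y_true = np.asarray(y_true, dtype=np.float64)
    if y_pred.size != y_true.size:
        raise ValueError("length mismatch")
    rng_ = float(y_true.max() - y_true.min())
    if rng_ <= 0:
        raise ValueError("zero range in y_true")
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)) / rng_)


def _zscore_cols(X: pd.DataFrame) -> pd.DataFrame:
    sd = X.std(ddof=1)
    flat = sd.index[sd == 0].tolist()
    if flat:
        raise ValueError(f"zero-variance predictor(s): {flat}")
    return (X - X.mean()) / sd


def nested_cv_regression(
    X: pd.DataFrame,
    y: Sequence[float],
    k: int = 5,
    n_iter: int = 4000,
    seed: int | None = None,
    r2_definition: str = "ss",
) -> RegressionReport:
    """Multilinear model with nested k-fold cross-validated prediction.

    Predictors are z-scored on the full sample so the betas are standardized
    and comparable.  The full-sample OLS fit supplies beta, per-coefficient
    two-sided p-values, and the overall F.  Prediction quality comes from the
    nested CV: each iteration draws a random outer k-fold split; within each
    outer-training set an inner k-fold split fits OLS on every inner-training
    set and the coefficient set with the lowest inner-validation NRMSE
    predicts the outer test fold.  Pooled out-of-fold predictions yield
    per-iteration NRMSE, R^2 and Spearman; reported metrics are means over
    ``n_iter`` iterations.  R^2 defaults to 1 - SSE/SST on the pooled
    predictions (``r2_definition='corr'`` uses the squared Pearson r instead).
    """
    X = pd.DataFrame(X).astype(np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("X and y must align")
    if n < 2 * k:
        raise ValueError(f"need n >= 2k = {2 * k} samples")
    if X.isna().any().any() or not np.isfinite(y).all():
        raise ValueError("missing values not allowed")
    if r2_definition not in ("ss", "corr"):
        raise ValueError("r2_definition must be 'ss' or 'corr'")
    Xz = _zscore_cols(X)
    D = np.column_stack([np.ones(n), Xz.to_numpy()])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        # identify collinear columns via rank-revealing QR diagonal
        _, r = np.linalg.qr(D)
        bad = [
            Xz.columns[i - 1]
            for i in range(1, D.shape[1])
            if abs(r[i, i]) < 1e-10 * abs(r[0, 0])
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    ols = sm.OLS(y, D).fit()
    names = list(Xz.columns)
    beta = pd.Series(ols.params[1:], index=names, name="beta")
    beta_p = pd.Series(ols.pvalues[1:], index=names, name="p")
    resid = ols.resid / ols.resid.std(ddof=1)

    rng = np.random.default_rng(seed)
    Xmat = Xz.to_numpy()
    sst_parts_range = float(y.max() - y.min())
    if sst_parts_range <= 0:
        raise ValueError("zero range in y")
    metrics = np.zeros((n_iter, 3))  # nrmse, r2, spearman
    for it in range(n_iter):
        y_hat = np.empty(n)
        outer = KFold(n_splits=k, shuffle=True, random_state=int(rng.integers(2**31)))
        for train_idx, test_idx in outer.split(Xmat):
            best_coef, best_err = None, np.inf
            inner = KFold(
                n_splits=k, shuffle=True, random_state=int(rng.integers(2**31))
            )
            for in_tr, in_val in inner.split(train_idx):
                tr, val = train_idx[in_tr], train_idx[in_val]
                A = np.column_stack([np.ones(tr.size), Xmat[tr]])
                coef, *_ = np.linalg.lstsq(A, y[tr], rcond=None)
                pred = np.column_stack([np.ones(val.size), Xmat[val]]) @ coef
                err = np.sqrt(np.mean((pred - y[val]) ** 2))
                if err < best_err:
                    best_err, best_coef = err, coef
            y_hat[test_idx] = (
                np.column_stack([np.ones(test_idx.size), Xmat[test_idx]]) @ best_coef
            )
        sse = float(((y - y_hat) ** 2).sum())
        sst = float(((y - y.mean()) ** 2).sum())
        if r2_definition == "ss":
            r2_it = 1.0 - sse / sst
        else:
            r2_it = float(np.corrcoef(y, y_hat)[0, 1] ** 2) if np.std(y_hat) > 0 else 0.0
        rho = (
            float(sps.spearmanr(y, y_hat).statistic) if np.std(y_hat) > 0 else 0.0
        )
        metrics[it] = (np.sqrt(sse / n) / sst_parts_range, r2_it, rho)

    m = metrics.mean(axis=0)
    return RegressionReport(
        beta=beta,
        beta_p=beta_p,
        f_stat=float(ols.fvalue),
        df=(int(ols.df_model), int(ols.df_resid)),
        f_p=float(ols.f_pvalue),
        r2=float(m[1]),
        nrmse=float(m[0]),
        spearman=float(m[2]),
        residuals=np.asarray(resid),
        n_iterations=n_iter,
        seed=seed,
    )
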