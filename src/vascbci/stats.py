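"""Small-cohort predictor screen: Spearman correlations, Lasso selection,
and exact nonparametric rank tests.

At cohort scale (n around 9-10) asymptotic p-values are unreliable, so
the Spearman test enumerates the full permutation null for small n and
the rank tests use exact null distributions.  Screening is uncorrected
by design — the analysis is exploratory — with Benjamini-Hochberg
available behind a flag.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats
from sklearn.linear_model import Lasso, lasso_path

EXACT_PERM_MAX_N = 9


@functools.lru_cache(maxsize=4)
def _perm_table(n: int) -> np.ndarray:
    """All n! permutations of range(n) as an (n!, n) index array."""
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


@dataclass
class PredictorMatrix:
    """Participants x factors design with a response (best signal strength)."""

    table: pd.DataFrame
    factors: list[str]
    response: str = "signal_strength"

    def __post_init__(self) -> None:
        missing = [f for f in self.factors + [self.response] if f not in self.table]
        if missing:
            raise ValueError(f"columns missing from table: {missing}")
        if self.table[self.response].isna().any():
            raise ValueError("response contains missing values")

    @property
    def X(self) -> np.ndarray:
        return self.table[self.factors].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.table[self.response].to_numpy(dtype=float)

    def zero_variance_factors(self) -> list[str]:
        return [f for f in self.factors if self.table[f].nunique() <= 1]


@dataclass
class ScreenReport:
    """Ranked Spearman screen: one row per factor, ordered by |rho|."""

    table: pd.DataFrame  # columns: factor, rho, p, rank

    def top_factor(self) -> str:
        return str(self.table.iloc[0]["factor"])

    def row(self, factor: str) -> pd.Series:
        return self.table.set_index("factor").loc[factor]


@dataclass
class LassoReport:
    """Standardized Lasso coefficients at the selected penalty."""

    coefficients: pd.Series  # indexed by factor, standardized scale
    alpha: float
    nonzero: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.nonzero:
            nz = self.coefficients[self.coefficients != 0.0]
            self.nonzero = list(nz.abs().sort_values(ascending=False).index)


def _spearman_rho(xr: np.ndarray, yr: np.ndarray) -> float:
    """Pearson correlation of midranks."""
    xd = xr - xr.mean()
    yd = yr - yr.mean()
    denom = math.sqrt((xd**2).sum() * (yd**2).sum())
    if denom == 0:
        raise ValueError("zero variance after ranking")
    return float((xd * yd).sum() / denom)


def spearman(
    x: np.ndarray, y: np.ndarray, method: str = "auto"
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    ``exact_perm`` enumerates all n! permutations of one rank vector
    (feasible at cohort scale, n <= 9); ``t_approx`` uses the t
    approximation with n-2 degrees of freedom.  ``auto`` picks the exact
    test for n <= 9.  Ties are handled by midranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.unique(x).size <= 1 or np.unique(y).size <= 1:
        raise ValueError("zero variance input")
    xr = spstats.rankdata(x)
    yr = spstats.rankdata(y)
    rho = _spearman_rho(xr, yr)

    if method == "auto":
        method = "exact_perm" if n <= EXACT_PERM_MAX_N else "t_approx"
    if method == "exact_perm":
        # vectorized enumeration: rho over every permutation of one rank
        # vector reduces to a matrix-vector product of centered ranks
        P = _perm_table(n)
        xc = xr - xr.mean()
        yc = yr - yr.mean()
        denom = math.sqrt((xc**2).sum() * (yc**2).sum())
        rhos = (yc[P] @ xc) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    elif method == "t_approx":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * spstats.t.sf(abs(t), df=n - 2)
    else:
        raise ValueError(f"unknown method {method!r}")
    return rho, float(min(p, 1.0))


def screen_factors(
    matrix: PredictorMatrix,
    method: str = "auto",
    fdr: bool = False,
) -> ScreenReport:
    """One Spearman test per factor against the response, ranked by |rho|.

    P-values are uncorrected by default; ``fdr=True`` adds a
    Benjamini-Hochberg adjusted column.
    """
    if len(matrix.table) < 3:
        raise ValueError("need at least 3 participants")
    if not matrix.factors:
        raise ValueError("need at least one factor")
    y = matrix.y
    degenerate = set(matrix.zero_variance_factors())
    rows = []
    for f in matrix.factors:
        if f in degenerate:
            # a constant factor carries no rank information; flag it and
            # rank it last rather than failing the whole screen
            rows.append({"factor": f, "rho": np.nan, "p": np.nan, "degenerate": True})
            continue
        rho, p = spearman(matrix.table[f].to_numpy(dtype=float), y, method=method)
        rows.append({"factor": f, "rho": rho, "p": p, "degenerate": False})
    rep = pd.DataFrame(rows)
    order = rep["rho"].abs().fillna(-1.0).sort_values(ascending=False, kind="stable").index
    rep = rep.reindex(order)
    rep["rank"] = np.arange(1, len(rep) + 1)
    if fdr:
        ok = rep["p"].notna()
        rep.loc[ok, "p_fdr"] = spstats.false_discovery_control(rep.loc[ok, "p"], method="bh")
    return ScreenReport(table=rep.reset_index(drop=True))


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd_safe, mu, sd


def lasso_fit(X: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """L1-penalized least squares minimizing
    ``1/(2n) ||y - X b||^2 + alpha ||b||_1`` (no intercept)."""
    model = Lasso(alpha=alpha, fit_intercept=False, max_iter=50_000, tol=1e-10)
    model.fit(X, y)
    return model.coef_


def lasso_select(
    matrix: PredictorMatrix,
    n_alphas: int = 60,
    eps: float = 1e-3,
    one_se: bool = True,
) -> LassoReport:
    """Lasso feature selection with leave-one-out cross-validation.

    Features are standardized to zero mean and unit variance and the
    response is centered, so coefficients are comparable across factors.
    The penalty is chosen on a log-spaced path by leave-one-out CV,
    optionally with the one-standard-error rule (the largest penalty
    whose CV error is within one SE of the minimum) for sparser, more
    stable selections at small n.
    """
    X = matrix.X
    y = matrix.y
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 participants")
    if np.ptp(y) == 0:
        return LassoReport(
            coefficients=pd.Series(0.0, index=matrix.factors), alpha=np.inf
        )
    Xs, _, sd = _standardize(X)
    Xs[:, sd == 0] = 0.0
    yc = y - y.mean()

    alpha_max = np.max(np.abs(Xs.T @ yc)) / n
    alphas = np.logspace(np.log10(alpha_max), np.log10(alpha_max * eps), n_alphas)

    # leave-one-out CV over the shared path; standardization is refit
    # inside each fold — with p > n, scaling by full-data moments leaks
    # the held-out response into the design and voids the CV error
    sq_err = np.zeros((n, len(alphas)))
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        mu_t = X[tr].mean(axis=0)
        sd_t = X[tr].std(axis=0)
        sd_t[sd_t == 0] = 1.0
        Xt = (X[tr] - mu_t) / sd_t
        ym = y[tr].mean()
        _, coefs, _ = lasso_path(Xt, y[tr] - ym, alphas=alphas, max_iter=50_000)
        pred = ym + ((X[i] - mu_t) / sd_t) @ coefs  # (n_alphas,)
        sq_err[i] = (y[i] - pred) ** 2
    mse = sq_err.mean(axis=0)
    se = sq_err.std(axis=0, ddof=1) / math.sqrt(n)
    best = int(np.argmin(mse))
    if one_se:
        ok = np.flatnonzero(mse <= mse[best] + se[best])
        # alphas descend along the path; the sparsest admissible model is
        # the earliest (largest) alpha
        best = int(ok.min())
    alpha = float(alphas[best])

    coef = lasso_fit(Xs, yc, alpha)
    return LassoReport(
        coefficients=pd.Series(coef, index=matrix.factors), alpha=alpha
    )


def rank_tests(
    a: np.ndarray, b: np.ndarray, paired: bool
) -> tuple[float, float]:
    """Wilcoxon signed-rank (paired) or Mann-Whitney rank-sum (unpaired)
    test, two-sided.

    Exact null distributions are used for small samples (signed-rank
    n <= 12 after dropping zero differences; rank-sum n + m <= 20); the
    normal approximation with tie correction applies above.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired samples must have equal length")
        diff = a - b
        nz = diff[diff != 0]
        if len(nz) == 0:
            raise ValueError("all paired differences are zero")
        if len(diff) < 5:
            raise ValueError("need at least 5 pairs")
        method = "exact" if len(nz) <= 12 and np.unique(np.abs(nz)).size == len(nz) else "approx"
        res = spstats.wilcoxon(a, b, alternative="two-sided", method=method)
    else:
        if min(len(a), len(b)) < 2 or len(a) + len(b) < 5:
            raise ValueError("samples too small")
        pooled = np.concatenate([a, b])
        no_ties = np.unique(pooled).size == len(pooled)
        method = "exact" if (len(a) + len(b) <= 20 and no_ties) else "asymptotic"
        res = spstats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
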