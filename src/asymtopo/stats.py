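"""Permutation statistics for landscape densities and asymmetry summaries.

The analyses this module supports:

* nonparametric linear regression of a landscape density (or mean ROI
  asymmetry) on a predictor of interest with nuisance covariates,
  p-values by Freedman-Lane residual permutation;
* a one-sample test of the per-participant 0-cycle minus 2-cycle density
  difference (Wilcoxon signed-rank with sign-flip permutation, exact for
  small n), plus the percent-positive summary;
* effect-size conversions (t to r, t to Cohen's d) and the Fisher-z test
  comparing two correlation coefficients using regression degrees of
  freedom.

Freedman-Lane: the reduced model (covariates only) is fitted once; its
residuals are permuted, added back to the reduced-model fit, and the full
model is refitted to each permuted response.  This respects the nuisance
structure while permuting only what is exchangeable under the null.  A
fixed permutation count with a seed keeps every p-value reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

DEFAULT_N_PERM = 4999

#: Exact sign-flip enumeration is used up to this sample size (2^12 = 4096).
EXACT_WILCOXON_MAX_N = 12


@dataclass(frozen=True)
class RegressionResult:
    """Permutation-regression summary for one predictor."""

    predictor: str
    coefficient: float
    t_statistic: float
    df: int
    p_permutation: float
    cohens_d: float
    r_equivalent: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p_permutation <= 1.0:
            raise ValueError(f"p_permutation out of (0, 1]: {self.p_permutation}")


@dataclass
class DensityDifferenceSummary:
    """Cohort summary of per-participant 0-cycle minus 2-cycle density."""

    roi_label: str
    differences: np.ndarray
    mean: float
    p_value: float
    percent_positive: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_positive <= 100.0:
            raise ValueError("percent_positive must lie in [0, 100]")


def _as_design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    """Intercept plus optional covariate columns."""
    if covariates is None:
        return np.ones((n, 1))
    Z = np.asarray(covariates, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    return np.column_stack([np.ones(n), Z])


def build_covariate_matrix(cohort: pd.DataFrame, columns: list[str]) -> np.ndarray:
    """Numeric covariate matrix with categorical columns dummy-coded.

    ``sex`` is coded as a male indicator (male = 1); ``site`` expands to
    k-1 dummies.  Other columns are taken as numeric.
    """
    pieces = []
    for col in columns:
        s = cohort[col]
        if col == "sex" or s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            if col == "sex":
                pieces.append((s == "male").astype(float).to_numpy()[:, None])
            else:
                d = pd.get_dummies(s, drop_first=True, dtype=float)
                pieces.append(d.to_numpy())
        else:
            pieces.append(s.to_numpy(dtype=float)[:, None])
    return np.column_stack(pieces)


def perm_lm(response: np.ndarray, predictor: np.ndarray,
            covariates: np.ndarray | None = None,
            n_perm: int = DEFAULT_N_PERM, seed: int = 0,
            predictor_name: str = "x") -> RegressionResult:
    """OLS regression with a Freedman-Lane permutation p-value.

    The coefficient, t-statistic and residual degrees of freedom come
    from the ordinary least-squares fit of
    ``response ~ 1 + covariates + predictor``.  The permutation p-value
    for the predictor permutes residuals of the reduced (covariates-only)
    model: p = (1 + #{|t*| >= |t|}) / (1 + n_perm), which can never be
    exactly zero.
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    n = y.size
    if x.size != n:
        raise ValueError(f"length mismatch: response {n}, predictor {x.size}")
    if n_perm < 99:
        raise ValueError(f"n_perm must be >= 99, got {n_perm}")
    if np.ptp(y) == 0:
        raise ValueError("response is constant")
    Z = _as_design(n, covariates)
    X = np.column_stack([Z, x])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")

    fit = sm.OLS(y, X).fit()
    coef = float(fit.params[-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t_obs = float(fit.tvalues[-1])
    df = int(fit.df_resid)

    # reduced model: covariates only
    beta_red, *_ = np.linalg.lstsq(Z, y, rcond=None)
    y_hat = Z @ beta_red
    resid = y - y_hat

    # vectorized refit of the full model for all permuted responses
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T
    jj = XtX_inv[-1, -1]
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    Y_star = y_hat[None, :] + resid[perms]
    B = Y_star @ H.T
    R = Y_star - B @ X.T
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = (R ** 2).sum(axis=1) / df
        t_star = B[:, -1] / np.sqrt(sigma2 * jj)
    exceed = int(np.sum(np.abs(t_star) >= abs(t_obs) - 1e-12))
    p = (1 + exceed) / (1 + n_perm)

    return RegressionResult(
        predictor=predictor_name,
        coefficient=coef,
        t_statistic=t_obs,
        df=df,
        p_permutation=p,
        cohens_d=d_from_t(t_obs, df),
        r_equivalent=t_to_r(t_obs, df),
    )


def wilcoxon_signed_rank(values: np.ndarray, n_perm: int = DEFAULT_N_PERM,
                         seed: int = 0) -> float:
    """Two-sided one-sample signed-rank test of median zero.

    Exact zeros are dropped first.  For n <= 12 the full 2^n sign-flip
    distribution is enumerated (exact p); otherwise Monte-Carlo sign
    flips are used with the given seed.
    """
    v = np.asarray(values, dtype=float)
    v = v[v != 0]
    n = v.size
    if n == 0:
        raise ValueError("all values are zero")
    if n < 5:
        raise ValueError(f"need at least 5 nonzero values, got {n}")
    ranks = sps.rankdata(np.abs(v))
    w = float(ranks[v > 0].sum())
    mu = float(ranks.sum()) / 2.0
    stat = abs(w - mu)
    if n <= EXACT_WILCOXON_MAX_N:
        # enumerate all sign patterns: each subset of ranks may be positive
        signs = np.array(list(product((0.0, 1.0), repeat=n)))
        w_all = signs @ ranks
        p = float(np.mean(np.abs(w_all - mu) >= stat - 1e-12))
    else:
        rng = np.random.default_rng(seed)
        flips = rng.integers(0, 2, size=(n_perm, n)).astype(float)
        w_star = flips @ ranks
        exceed = int(np.sum(np.abs(w_star - mu) >= stat - 1e-12))
        p = (1 + exceed) / (1 + n_perm)
    return min(p, 1.0)


def t_to_r(t: float, df: int) -> float:
    """Equivalent correlation of a regression t: r = t / sqrt(t^2 + df)."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if not np.isfinite(t):
        return float(np.sign(t))
    return float(t / np.sqrt(t * t + df))


def d_from_t(t: float, df: int) -> float:
    """Unsigned Cohen's d from a regression t: d = 2|t| / sqrt(df)."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if not np.isfinite(t):
        return float("inf")
    return float(2.0 * abs(t) / np.sqrt(df))


def compare_correlations(r1: float, df1: int, r2: float, df2: int
                         ) -> tuple[float, float]:
    """Fisher-z test of two independent correlations.

    Uses the regression degrees of freedom in place of n - 3:
    z = (atanh(r1) - atanh(r2)) / sqrt(1/(df1 - 1) + 1/(df2 - 1)),
    two-sided normal p.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError(f"|r| must be < 1, got {r}")
    for df in (df1, df2):
        if df <= 3:
            raise ValueError(f"df must exceed 3, got {df}")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (df1 - 1) + 1.0 / (df2 - 1)
    )
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


def density_difference_summary(differences: np.ndarray, n_perm: int = DEFAULT_N_PERM,
                               seed: int = 0, roi_label: str = "",
                               test: str = "wilcoxon") -> DensityDifferenceSummary:
    """Cohort test of whether 0-cycle density exceeds 2-cycle density.

    Reports the mean difference, a two-sided p-value (signed-rank by
    default, ``test='t'`` for a one-sample t-test) and the percentage of
    participants with a positive difference.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 5:
        raise ValueError(f"need at least 5 participants, got {d.size}")
    if test == "wilcoxon":
        p = wilcoxon_signed_rank(d, n_perm=n_perm, seed=seed)
    elif test == "t":
        p = float(sps.ttest_1samp(d, 0.0).pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return DensityDifferenceSummary(
        roi_label=roi_label,
        differences=d,
        mean=float(d.mean()),
        p_value=p,
        percent_positive=float(100.0 * np.mean(d > 0)),
    )
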