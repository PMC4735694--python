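"""Parental-age statistics: linear models, permutation, bootstrap, GAM.

All procedures operate on a per-trio table with a count response (default
column ``n_dnm``) and covariates ``father_age``, ``mother_age``,
``is_natural_conception``, ``is_preterm`` plus optional batch columns.  The
ordinary least squares machinery is statsmodels; the permutation and
bootstrap loops use a closed-form batched solver for speed; the generalized
additive model is a penalized cubic B-spline smoother with GCV-selected
penalties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.interpolate import BSpline

logger = logging.getLogger(__name__)

AGE_COVARIATES = ("father_age", "mother_age")


@dataclass
class RegressionResult:
    """Coefficient table plus model-level summaries for one OLS fit."""

    params: pd.DataFrame  # index: term; columns: estimate, se, t, p
    r2: float
    vif: pd.Series
    nobs: int
    resid: np.ndarray = field(repr=False, default=None)
    model: object = field(repr=False, default=None)

    def estimate(self, term: str) -> float:
        return float(self.params.loc[term, "estimate"])

    def pvalue(self, term: str) -> float:
        return float(self.params.loc[term, "p"])

    def conf_int(self, term: str, alpha: float = 0.05) -> tuple[float, float]:
        df = self.nobs - len(self.params)
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        est = self.params.loc[term, "estimate"]
        se = self.params.loc[term, "se"]
        return float(est - tcrit * se), float(est + tcrit * se)


def _design(data: pd.DataFrame, covariates) -> pd.DataFrame:
    X = pd.DataFrame(index=data.index)
    for cov in covariates:
        if cov == "difference_in_parents_ages":
            X[cov] = data["mother_age"] - data["father_age"]
        elif cov.startswith("C(") and cov.endswith(")"):
            col = cov[2:-1]
            levels = sorted(data[col].unique())
            if len(levels) < 2:
                logger.warning("batch column %r has a single level; dummy dropped", col)
                continue
            for lvl in levels[1:]:
                X[f"{col}[{lvl}]"] = (data[col] == lvl).astype(float)
        else:
            X[cov] = pd.to_numeric(data[cov])
    return X.astype(float)


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per covariate: 1 / (1 - R^2_j)."""
    out = {}
    cols = list(design.columns)
    if len(cols) < 2:
        return pd.Series({c: 1.0 for c in cols})
    for j, col in enumerate(cols):
        others = sm.add_constant(design.drop(columns=col))
        r2 = sm.OLS(design[col], others).fit().rsquared
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def fit_mlr(
    data: pd.DataFrame,
    covariates=AGE_COVARIATES,
    response: str = "n_dnm",
) -> RegressionResult:
    """Ordinary least squares of the count response on the given covariates.

    ``difference_in_parents_ages`` is accepted as a derived covariate
    (mother minus father age); ``C(col)`` expands a categorical column into
    treatment dummies.
    """
    X = _design(data, covariates)
    y = pd.to_numeric(data[response]).astype(float)
    if len(data) <= X.shape[1] + 1:
        raise ValueError("not enough observations for the requested model")
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax() if len(X.columns) > 1 else (X.columns[0],)
        raise ValueError(f"design matrix is rank deficient; near-collinear columns: {worst}")
    fit = sm.OLS(y, Xc).fit()
    params = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    return RegressionResult(
        params=params,
        r2=float(fit.rsquared),
        vif=vif(X),
        nobs=int(fit.nobs),
        resid=np.asarray(fit.resid),
        model=fit,
    )


def bonferroni_outlier_test(result: RegressionResult, alpha: float = 0.05) -> np.ndarray:
    """Indices of outliers by externally studentized residuals.

    Two-sided p-values from the t distribution with n - k - 2 degrees of
    freedom, Bonferroni-multiplied by n; indices with corrected p < alpha
    are returned.
    """
    fit = result.model
    if fit.nobs <= len(result.params) + 2:
        raise ValueError("too few observations for an outlier test")
    from statsmodels.stats.outliers_influence import OLSInfluence

    student = OLSInfluence(fit).resid_studentized_external
    p = 2 * stats.t.sf(np.abs(student), fit.df_resid - 1)
    corrected = np.minimum(p * fit.nobs, 1.0)
    return np.flatnonzero(corrected < alpha)


def fit_exponential(
    data: pd.DataFrame, covariates=AGE_COVARIATES, response: str = "n_dnm"
) -> RegressionResult:
    """OLS on log(counts): slopes are per-year log-rate increases."""
    y = pd.to_numeric(data[response])
    if (y <= 0).any():
        raise ValueError(
            "exponential model requires strictly positive counts; add an offset or drop zeros"
        )
    logged = data.copy()
    logged[response] = np.log(y.astype(float))
    return fit_mlr(logged, covariates, response)


def fit_per_chromosome(
    chrom_counts: pd.DataFrame,
    cohort: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-chromosome OLS of counts on father's age and the age difference.

    ``chrom_counts`` is wide (one column per chromosome, plus trio_id).
    Returns one row per chromosome with both slopes, p-values, and a
    significance class in {both, father_only, neither, mother_only}.
    """
    merged = chrom_counts.merge(cohort, on="trio_id")
    rows = []
    for chrom in [c for c in chrom_counts.columns if c != "trio_id"]:
        res = fit_mlr(
            merged, ("father_age", "difference_in_parents_ages"), response=chrom
        )
        p_f = res.pvalue("father_age")
        p_d = res.pvalue("difference_in_parents_ages")
        if p_f < alpha and p_d < alpha:
            klass = "both"
        elif p_f < alpha:
            klass = "father_only"
        elif p_d < alpha:
            klass = "mother_only"
        else:
            klass = "neither"
        rows.append(
            {
                "chrom": chrom,
                "beta_father": res.estimate("father_age"),
                "p_father": p_f,
                "beta_diff": res.estimate("difference_in_parents_ages"),
                "p_diff": p_d,
                "significance": klass,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# permutation and bootstrap (batched closed-form OLS)
# ---------------------------------------------------------------------------

def _batched_two_age_t(F, M, y):
    """t statistics for the mother-age slope, batched over rows of M.

    F, y are (n,) arrays; M is (b, n).  The model is y ~ 1 + F + M.
    Returns (beta (b,3), t_mother (b,)).
    """
    b, n = M.shape
    ones = np.ones(n)
    SF, SFF, Sy, SyF = F.sum(), F @ F, y.sum(), y @ F
    SM = M.sum(axis=1)
    SMM = np.einsum("bn,bn->b", M, M)
    SFM = M @ F
    SyM = M @ y
    XtX = np.empty((b, 3, 3))
    XtX[:, 0, 0] = n
    XtX[:, 0, 1] = XtX[:, 1, 0] = SF
    XtX[:, 0, 2] = XtX[:, 2, 0] = SM
    XtX[:, 1, 1] = SFF
    XtX[:, 1, 2] = XtX[:, 2, 1] = SFM
    XtX[:, 2, 2] = SMM
    Xty = np.stack([np.full(b, Sy), np.full(b, SyF), SyM], axis=1)
    XtX_inv = np.linalg.inv(XtX)
    beta = np.einsum("bij,bj->bi", XtX_inv, Xty)
    rss = y @ y - np.einsum("bi,bi->b", beta, Xty)
    sigma2 = rss / (n - 3)
    t_m = beta[:, 2] / np.sqrt(sigma2 * XtX_inv[:, 2, 2])
    return beta, t_m


@dataclass
class PermutationResult:
    observed_t: float
    permuted_t: np.ndarray
    p_value: float
    n_perm: int
    seed: int


def permutation_test_maternal(
    data: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
    response: str = "n_dnm",
) -> PermutationResult:
    """Permutation test for the maternal-age effect.

    Each replicate shuffles the per-family parental age differences
    d_i = mother_i - father_i across families, sets mother*_i = father_i +
    d_perm(i) (father ages untouched), refits the two-age model, and records
    the maternal t.  The empirical p is the fraction of permuted t values at
    least as large as the observed one.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    F = data["father_age"].to_numpy(float)
    M = data["mother_age"].to_numpy(float)
    y = pd.to_numeric(data[response]).to_numpy(float)
    d = M - F
    n = len(F)
    _, t_obs = _batched_two_age_t(F, M[None, :], y)
    t_obs = float(t_obs[0])
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    M_star = F[None, :] + d[perms]
    _, t_perm = _batched_two_age_t(F, M_star, y)
    p = float(np.mean(t_perm >= t_obs))
    return PermutationResult(t_obs, t_perm, p, n_perm, seed)


def bootstrap_slope_ci(
    data: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    response: str = "n_dnm",
    alpha: float = 0.05,
) -> dict:
    """Percentile bootstrap CIs for both age slopes (resampling trios).

    Degenerate (rank-deficient) resamples are redrawn and counted.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    F = data["father_age"].to_numpy(float)
    M = data["mother_age"].to_numpy(float)
    y = pd.to_numeric(data[response]).to_numpy(float)
    n = len(F)
    X = np.stack([np.ones(n), F, M], axis=1)
    betas = np.empty((n_boot, 3))
    redrawn = 0
    done = 0
    while done < n_boot:
        todo = n_boot - done
        idx = rng.integers(0, n, size=(todo, n))
        G = X[idx]  # (todo, n, 3)
        yb = y[idx]
        XtX = np.einsum("bni,bnj->bij", G, G)
        Xty = np.einsum("bni,bn->bi", G, yb)
        dets = np.linalg.det(XtX)
        ok = np.abs(dets) > 1e-6
        redrawn += int((~ok).sum())
        sol = np.linalg.solve(XtX[ok], Xty[ok][..., None])[..., 0]
        betas[done : done + int(ok.sum())] = sol
        done += int(ok.sum())
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    return {
        "father_age": tuple(np.percentile(betas[:, 1], [lo, hi])),
        "mother_age": tuple(np.percentile(betas[:, 2], [lo, hi])),
        "n_redrawn": redrawn,
        "replicates": betas,
    }


def median_split_slopes(
    data: pd.DataFrame, split_by: str = "mother", response: str = "n_dnm"
) -> dict:
    """Fit the two-age model separately below/above the median of one age.

    Ties at the median go to the lower half.  Returns {"younger": ...,
    "older": ...} RegressionResults plus the median used.
    """
    col = {"father": "father_age", "mother": "mother_age"}[split_by]
    med = float(data[col].median())
    lower = data[data[col] <= med]
    upper = data[data[col] > med]
    if len(lower) < 20 or len(upper) < 20:
        raise ValueError("median split leaves fewer than 20 trios in a half")
    return {
        "median": med,
        "younger": fit_mlr(lower, AGE_COVARIATES, response),
        "older": fit_mlr(upper, AGE_COVARIATES, response),
    }


def batch_effect_regression(data: pd.DataFrame, response: str = "n_dnm") -> dict:
    """The three batch-covariate model forms around the age MLR.

    Fits the two-age model augmented with (a) software-version dummies,
    (b) the fully-called genome fraction, (c) the gross mapping yield.
    """
    return {
        "software_version": fit_mlr(
            data, ("father_age", "mother_age", "C(batch_label)"), response
        ),
        "fully_called_fraction": fit_mlr(
            data, ("father_age", "mother_age", "fully_called_fraction"), response
        ),
        "gross_mapping_yield": fit_mlr(
            data, ("father_age", "mother_age", "gross_mapping_yield"), response
        ),
    }


def cluster_robustness_scan(
    sites: pd.DataFrame,
    cohort: pd.DataFrame,
    windows=tuple(10**k for k in range(1, 9)),
    response: str = "n_dnm",
) -> pd.DataFrame:
    """Refit the two-age model after removing site clusters at each window."""
    from .caller import count_dnms, remove_clusters

    rows = []
    for w in windows:
        filtered = remove_clusters(sites, int(w))
        counts = count_dnms(filtered, cohort)
        merged = counts.merge(cohort, on="trio_id")
        if merged[response].sum() == 0 or merged[response].nunique() == 1:
            rows.append({"window": w, "n_sites": len(filtered),
                         "p_father": 1.0, "p_mother": 1.0,
                         "beta_father": 0.0, "beta_mother": 0.0})
            continue
        res = fit_mlr(merged, AGE_COVARIATES, response)
        rows.append(
            {
                "window": w,
                "n_sites": len(filtered),
                "beta_father": res.estimate("father_age"),
                "beta_mother": res.estimate("mother_age"),
                "p_father": res.pvalue("father_age"),
                "p_mother": res.pvalue("mother_age"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# generalized additive model (penalized cubic B-splines, GCV)
# ---------------------------------------------------------------------------

@dataclass
class GamResult:
    terms: pd.DataFrame  # index: term; columns: edf, F, p
    gcv: float
    bic: float
    deviance: float
    edf_total: float
    alphas: dict
    fitted: np.ndarray = field(repr=False, default=None)


def _bspline_basis(x: np.ndarray, n_basis: int = 10) -> np.ndarray:
    """Uniform-knot cubic B-spline basis, column-centered (P-spline setup).

    With equally spaced knots the second-difference penalty's null space is
    exactly the linear functions of x, so an infinite penalty reduces the
    smooth to a straight line.
    """
    degree = 3
    n_interior = n_basis - degree - 1
    lo, hi = x.min(), x.max()
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    design = BSpline.design_matrix(x, knots, degree, extrapolate=True).toarray()
    return design - design.mean(axis=0)


def _penalty(n_basis: int) -> np.ndarray:
    D = np.diff(np.eye(n_basis), n=2, axis=0)
    return D.T @ D


def fit_gam(
    data: pd.DataFrame,
    response: str = "n_dnm",
    terms=AGE_COVARIATES,
    n_basis: int = 10,
    alphas=None,
    gcv_gamma: float = 1.4,
) -> GamResult:
    """Additive model with a penalized cubic B-spline smooth per age term.

    The two smoothing penalties are selected jointly by generalized cross
    validation over a log-spaced grid; ``gcv_gamma`` inflates the degrees
    of freedom in the GCV denominator (the usual guard against GCV
    undersmoothing).  Effective degrees of freedom per term are the trace
    of that term's block of the influence matrix; an edf near 1 means the
    smooth has shrunk to a straight line.
    """
    y = pd.to_numeric(data[response]).to_numpy(float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    n = len(y)
    if n < 50:
        raise ValueError("GAM requires at least 50 observations")
    bases = [_bspline_basis(data[t].to_numpy(float), n_basis) for t in terms]
    X = np.concatenate([np.ones((n, 1))] + bases, axis=1)
    p = X.shape[1]
    XtX = X.T @ X
    Xty = X.T @ y
    S = []
    for j in range(len(terms)):
        block = np.zeros((p, p))
        sl = slice(1 + j * n_basis, 1 + (j + 1) * n_basis)
        block[sl, sl] = _penalty(n_basis)
        S.append(block)
    if alphas is None:
        alphas = np.logspace(-2, 8, 21)

    def solve(lams):
        A = XtX + sum(l * Sj for l, Sj in zip(lams, S))
        # the centered partition-of-unity basis leaves one exact null
        # direction per term; the pseudoinverse resolves it harmlessly
        Ainv = np.linalg.pinv(A)
        beta = Ainv @ Xty
        fitted = X @ beta
        rss = float(((y - fitted) ** 2).sum())
        Hdiag_blocks = Ainv @ XtX  # influence in coefficient space
        edf_terms = []
        for j in range(len(terms)):
            sl = slice(1 + j * n_basis, 1 + (j + 1) * n_basis)
            edf_terms.append(float(np.trace(Hdiag_blocks[sl, sl])))
        edf_total = float(np.trace(Hdiag_blocks))
        gcv = n * rss / (n - gcv_gamma * edf_total) ** 2
        return beta, rss, edf_terms, edf_total, gcv

    best = None
    for l1 in alphas:
        for l2 in alphas:
            lams = (l1, l2)
            _, rss, edf_terms, edf_total, gcv = solve(lams)
            if best is None or gcv < best[0]:
                best = (gcv, lams, rss, edf_terms, edf_total)
    gcv, lams, rss, edf_terms, edf_total = best
    beta_best, *_ = solve(lams)
    fitted = X @ beta_best
    sigma2 = rss / (n - edf_total)

    # approximate per-term F: deviance change from dropping the term
    rows = []
    for j, term in enumerate(terms):
        keep = [k for k in range(len(terms)) if k != j]
        Xr = np.concatenate([np.ones((n, 1))] + [bases[k] for k in keep], axis=1)
        pr = Xr.shape[1]
        Ar = Xr.T @ Xr
        for idx, k in enumerate(keep):
            sl = slice(1 + idx * n_basis, 1 + (idx + 1) * n_basis)
            Ar[sl, sl] += lams[k] * _penalty(n_basis)
        beta_r = np.linalg.pinv(Ar) @ (Xr.T @ y)
        rss_r = float(((y - Xr @ beta_r) ** 2).sum())
        df1 = max(edf_terms[j], 1e-8)
        F = max(rss_r - rss, 0.0) / df1 / sigma2
        pval = float(stats.f.sf(F, df1, n - edf_total))
        rows.append({"term": term, "edf": edf_terms[j], "F": F, "p": pval})
    terms_df = pd.DataFrame(rows).set_index("term")
    bic = n * np.log(rss / n) + edf_total * np.log(n)
    return GamResult(
        terms=terms_df,
        gcv=float(gcv),
        bic=float(bic),
        deviance=rss,
        edf_total=edf_total,
        alphas={t: float(l) for t, l in zip(terms, lams)},
        fitted=fitted,
    )
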