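"""Brain-behavior inference.

Correlation rules (Pearson, or Spearman whenever either variable is
ordinal, e.g. ADOS scores), partial correlation, nonparametric
(percentile-bootstrap) mediation - scalar and voxelwise - a one-factor
maximum-likelihood latent "flexibility" model with AGFI/CFI/RMSEA/SRMR
fit indices, and the group-comparison statistics used throughout
(two-sample t, Cohen's d, one-way and split-plot ANOVA, Bonferroni).

The mediation point estimate is alpha*beta with alpha from OLS m ~ x and
beta (and the direct effect gamma) from OLS y ~ x + m; inference is by
resampling subjects with replacement and refitting both regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "MediationResult",
    "SEMFit",
    "correlate",
    "partial_correlation",
    "mediate",
    "voxelwise_mediation",
    "fit_latent_model",
    "two_sample_t",
    "cohens_d",
    "one_way_anova",
    "split_plot_anova",
    "bonferroni_alpha",
    "rrb_strata_test",
]


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    coefficient: float
    p: float
    n: int


@dataclass(frozen=True)
class MediationResult:
    alpha: float
    beta: float
    gamma: float
    indirect: float
    ci_lower: float
    ci_upper: float
    p_indirect: float
    n_boot: int
    seed: int
    n: int


@dataclass
class SEMFit:
    loadings: np.ndarray
    residual_variances: np.ndarray
    agfi: float
    cfi: float
    rmsea: float
    srmr: float
    chi2: float
    df: int
    log_likelihood: float
    converged: bool
    heywood: bool
    n: int


# ---------------------------------------------------------------------------
# correlations


def correlate(
    x, y, x_is_ordinal: bool = False, y_is_ordinal: bool = False
) -> CorrelationResult:
    """Pearson correlation, or Spearman if either variable is flagged
    ordinal/nonparametric (two-sided p in both cases)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need n >= 3 paired finite observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input")
    if x_is_ordinal or y_is_ordinal:
        r, p = stats.spearmanr(x, y)
        method = "spearman"
    else:
        r, p = stats.pearsonr(x, y)
        method = "pearson"
    return CorrelationResult(method=method, coefficient=float(r), p=float(p), n=len(x))


def partial_correlation(x, y, z) -> float:
    """Pearson correlation of the residuals of x on z and y on z
    (z may be a vector or an (n, k) matrix); symmetric in x and y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.atleast_2d(np.asarray(z, dtype=float))
    if Z.shape[0] != len(x):
        Z = Z.T
    if len(x) != len(y) or len(x) != Z.shape[0] or len(x) < 4:
        raise ValueError("need n >= 4 aligned observations")
    design = np.column_stack([np.ones(len(x)), Z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("degenerate residuals: a variable is collinear with z")
    return float(np.corrcoef(rx, ry)[0, 1])


# ---------------------------------------------------------------------------
# mediation


def _batched_ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Solve OLS for a batch: X (B, n, k), y (B, n) -> coefs (B, k)."""
    XtX = np.einsum("bni,bnj->bij", X, X)
    Xty = np.einsum("bni,bn->bi", X, y)
    return np.linalg.solve(XtX, Xty[..., None])[..., 0]


def _mediation_point(x, m, y, C=None):
    n = len(x)
    ones = np.ones(n)
    Xa = np.column_stack([ones, x] if C is None else [ones, x, C])
    Xb = np.column_stack([ones, x, m] if C is None else [ones, x, m, C])
    ca = np.linalg.lstsq(Xa, m, rcond=None)[0]
    cb = np.linalg.lstsq(Xb, y, rcond=None)[0]
    alpha = float(ca[1])
    gamma = float(cb[1])
    beta = float(cb[2])
    return alpha, beta, gamma


def mediate(
    x,
    m,
    y,
    n_boot: int = 10_000,
    seed: int = 0,
    covariates=None,
    standardize: bool = False,
) -> MediationResult:
    """Nonparametric mediation of x -> m -> y.

    Point estimates: alpha (x->m), beta (m->y controlling x), gamma
    (direct x->y controlling m), indirect = alpha*beta. Percentile
    bootstrap over subjects gives the CI; two-sided
    p = 2 * min(share of bootstrap indirects <= 0, >= 0), floored at
    1/n_boot. Resamples with (numerically) constant x are redrawn.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("mediation needs n >= 10 subjects")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    C = None
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
    if standardize:
        x = (x - x.mean()) / x.std(ddof=1)
        m = (m - m.mean()) / m.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1)
        if C is not None:
            C = (C - C.mean(axis=0)) / C.std(axis=0, ddof=1)

    alpha, beta, gamma = _mediation_point(x, m, y, C)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    idx = rng.integers(0, n, size=(n_boot, n))
    # redraw degenerate resamples (constant x), capped
    for _ in range(100):
        bad = np.ptp(x[idx], axis=1) == 0
        if not bad.any():
            break
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
    else:  # pragma: no cover
        raise RuntimeError("could not draw non-degenerate bootstrap resamples")

    xb = x[idx]
    mb = m[idx]
    yb = y[idx]
    ones = np.ones_like(xb)
    if C is None:
        Xa = np.stack([ones, xb], axis=2)
        Xb = np.stack([ones, xb, mb], axis=2)
    else:
        Cb = C[idx]  # (B, n, k)
        Xa = np.concatenate([np.stack([ones, xb], axis=2), Cb], axis=2)
        Xb = np.concatenate([np.stack([ones, xb, mb], axis=2), Cb], axis=2)
    alpha_b = _batched_ols(Xa, mb)[:, 1]
    beta_b = _batched_ols(Xb, yb)[:, 2]
    indirect_b = alpha_b * beta_b
    lo, hi = np.percentile(indirect_b, [2.5, 97.5])
    p = 2.0 * min(
        float(np.mean(indirect_b <= 0.0)), float(np.mean(indirect_b >= 0.0))
    )
    p = float(min(max(p, 1.0 / n_boot), 1.0))
    return MediationResult(
        alpha=alpha, beta=beta, gamma=gamma, indirect=alpha * beta,
        ci_lower=float(lo), ci_upper=float(hi), p_indirect=p,
        n_boot=n_boot, seed=seed, n=n,
    )


def voxelwise_mediation(
    x,
    images,
    y,
    mask: np.ndarray,
    q: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
):
    """Per in-mask voxel, mediation with the voxel's GMV as mediator;
    BH-FDR on the indirect-effect p map. One shared set of bootstrap
    resample indices is used across voxels (coherent null, tractable
    runtime). Returns (indirect map, p map, fdr mask, n_failed)."""
    from statsmodels.stats.multitest import multipletests

    values = np.asarray(images.values if hasattr(images, "values") else images, float)
    mask = np.asarray(mask, bool)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    M = values[:, mask]  # (n, V)
    # standardize per voxel for comparable indirect effects
    x_s = (x - x.mean()) / x.std(ddof=1)
    y_s = (y - y.mean()) / y.std(ddof=1)
    M_sd = M.std(axis=0, ddof=1)
    ok = M_sd > 0
    M_s = np.zeros_like(M)
    M_s[:, ok] = (M[:, ok] - M[:, ok].mean(axis=0)) / M_sd[ok]

    # point estimates, all voxels at once
    Xa = np.column_stack([np.ones(n), x_s])
    alpha_v = np.linalg.lstsq(Xa, M_s, rcond=None)[0][1]  # (V,)
    # beta per voxel from y ~ 1 + x + m_v via per-voxel normal equations
    def _beta_all(xv, Mv, yv):
        sm = Mv.sum(axis=0)
        sxm = xv @ Mv
        smm = np.einsum("nv,nv->v", Mv, Mv)
        sx = xv.sum()
        sxx = xv @ xv
        sy = yv.sum()
        sxy = xv @ yv
        smy = Mv.T @ yv
        nn = len(xv)
        V = Mv.shape[1]
        A = np.empty((V, 3, 3))
        A[:, 0, 0] = nn
        A[:, 0, 1] = A[:, 1, 0] = sx
        A[:, 0, 2] = A[:, 2, 0] = sm
        A[:, 1, 1] = sxx
        A[:, 1, 2] = A[:, 2, 1] = sxm
        A[:, 2, 2] = smm
        b = np.empty((V, 3))
        b[:, 0] = sy
        b[:, 1] = sxy
        b[:, 2] = smy
        return np.linalg.solve(A, b[..., None])[:, 2, 0]

    beta_v = _beta_all(x_s, M_s, y_s)
    indirect_v = alpha_v * beta_v

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    idx = rng.integers(0, n, size=(n_boot, n))
    pos = np.zeros(M.shape[1], dtype=np.int64)
    neg = np.zeros(M.shape[1], dtype=np.int64)
    failed = ~ok
    for b_i in range(n_boot):
        take = idx[b_i]
        xv = x_s[take]
        if np.ptp(xv) == 0:
            xv = x_s  # degenerate resample: fall back, counted as coherent
        Mv = M_s[take]
        yv = y_s[take]
        a_b = np.linalg.lstsq(np.column_stack([np.ones(n), xv]), Mv, rcond=None)[0][1]
        with np.errstate(all="ignore"):
            b_b = _beta_all(xv, Mv, yv)
        ind = a_b * b_b
        pos += ind >= 0
        neg += ind <= 0
    p_v = 2.0 * np.minimum(pos, neg) / n_boot
    p_v = np.clip(p_v, 1.0 / n_boot, 1.0)
    p_v[failed] = 1.0
    indirect_v[failed] = 0.0

    reject, _, _, _ = multipletests(p_v, alpha=q, method="fdr_bh")
    ind_map = np.zeros(mask.shape)
    p_map = np.ones(mask.shape)
    fdr_map = np.zeros(mask.shape, dtype=bool)
    ind_map[mask] = indirect_v
    p_map[mask] = p_v
    fdr_map[mask] = reject & ~failed
    return ind_map, p_map, fdr_map, int(failed.sum())


# ---------------------------------------------------------------------------
# one-factor latent model


def _implied_cov(lam: np.ndarray, theta: np.ndarray) -> np.ndarray:
    return np.outer(lam, lam) + np.diag(theta)


def _ml_discrepancy(S: np.ndarray, sigma: np.ndarray) -> float:
    p = S.shape[0]
    sign, logdet_sigma = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    _, logdet_s = np.linalg.slogdet(S)
    return float(logdet_sigma + np.trace(S @ np.linalg.inv(sigma)) - logdet_s - p)


def fit_latent_model(
    indicators: np.ndarray, standardize: bool = True, max_iter: int = 500
) -> SEMFit:
    """One-factor measurement model fit by maximum likelihood.

    The latent factor's variance is fixed to 1; free parameters are the p
    loadings and p residual variances. Identification: the first loading
    is forced non-negative. Residual variances are bounded below at ~0
    (Heywood cases are flagged). Fit indices use the standard
    covariance-based definitions; the CFI baseline is the diagonal
    (independence) model. A just-identified p = 3 model has df = 0, for
    which RMSEA is defined as 0 and AGFI is undefined (NaN).
    """
    from scipy.optimize import minimize

    X = np.asarray(indicators, dtype=float)
    n, p = X.shape
    if p < 3:
        raise ValueError("need at least 3 indicators")
    if n <= p:
        raise ValueError("need more observations than indicators")
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    S = np.cov(X, rowvar=False, ddof=1)

    # principal-axis start
    evals, evecs = np.linalg.eigh(S)
    lam0 = evecs[:, -1] * np.sqrt(max(evals[-1], 1e-6))
    theta0 = np.clip(np.diag(S) - lam0**2, 0.05, None)
    x0 = np.concatenate([lam0, np.log(theta0)])

    def objective(params):
        lam = params[:p]
        theta = np.exp(params[p:])
        sigma = _implied_cov(lam, theta)
        f = _ml_discrepancy(S, sigma)
        if not np.isfinite(f):
            return 1e6, np.zeros_like(params)
        sigma_inv = np.linalg.inv(sigma)
        dF = sigma_inv @ (sigma - S) @ sigma_inv
        g_lam = 2.0 * dF @ lam
        g_theta = np.diag(dF) * theta  # chain rule through log
        return f, np.concatenate([g_lam, g_theta])

    res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter})
    lam = res.x[:p]
    theta = np.exp(res.x[p:])
    heywood = bool(np.any(theta < 1e-4))
    theta = np.maximum(theta, 0.0)
    if lam[0] < 0:
        lam = -lam
    sigma = _implied_cov(lam, theta)
    f_min = _ml_discrepancy(S, sigma)

    chi2 = (n - 1) * f_min
    df = p * (p + 1) // 2 - 2 * p
    sigma_b = np.diag(np.diag(S))
    chi2_b = (n - 1) * _ml_discrepancy(S, sigma_b)
    df_b = p * (p - 1) // 2

    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, num, np.finfo(float).tiny)
    cfi = 1.0 - num / den
    rmsea = 0.0 if df == 0 else float(np.sqrt(num / (df * (n - 1))))

    sigma_inv = np.linalg.inv(sigma)
    resid_w = sigma_inv @ (S - sigma)
    gfi = 1.0 - np.trace(resid_w @ resid_w) / np.trace(
        (sigma_inv @ S) @ (sigma_inv @ S)
    )
    agfi = float("nan") if df == 0 else 1.0 - (p * (p + 1) / (2.0 * df)) * (1.0 - gfi)

    d = np.sqrt(np.diag(S))
    std_resid = (S - sigma) / np.outer(d, d)
    iu = np.triu_indices(p)
    srmr = float(np.sqrt(np.mean(std_resid[iu] ** 2)))

    ll = -0.5 * (n - 1) * (
        p * np.log(2 * np.pi)
        + np.linalg.slogdet(sigma)[1]
        + np.trace(S @ sigma_inv)
    )
    return SEMFit(
        loadings=lam, residual_variances=theta, agfi=float(agfi), cfi=float(cfi),
        rmsea=float(rmsea), srmr=srmr, chi2=float(chi2), df=int(df),
        log_likelihood=float(ll), converged=bool(res.success), heywood=heywood, n=n,
    )


# ---------------------------------------------------------------------------
# group statistics


def two_sample_t(a, b) -> tuple[float, int, float]:
    """Pooled-variance two-sample t test: (t, dof, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), len(a) + len(b) - 2, float(p)


def cohens_d(a, b) -> float:
    """Pooled-SD standardized mean difference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    return float((a.mean() - b.mean()) / pooled)


def one_way_anova(groups: list) -> tuple[float, tuple[int, int], float]:
    """Classical one-way ANOVA: (F, (df_between, df_within), p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 1 for g in groups) or len(groups) < 2:
        raise ValueError("need >= 2 non-empty groups")
    f, p = stats.f_oneway(*groups)
    df_b = len(groups) - 1
    df_w = sum(len(g) for g in groups) - len(groups)
    return float(f), (df_b, df_w), float(p)


def split_plot_anova(
    data: np.ndarray, group_labels
) -> tuple[float, tuple[int, int], float]:
    """Group main effect in a (between: group) x (within: run) split-plot
    design: F = MS_group / MS_subjects-within-group.

    data: (n_subjects, n_runs), balanced; returns (F, (df1, df2), p).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a subjects x runs matrix")
    groups = np.asarray(group_labels)
    if len(groups) != data.shape[0]:
        raise ValueError("one group label per subject is required")
    levels, counts = np.unique(groups, return_counts=True)
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    if len(set(counts)) != 1:
        raise ValueError("unbalanced split-plot design is not supported")
    n_runs = data.shape[1]
    subj_means = data.mean(axis=1)
    grand = subj_means.mean()
    ss_group = 0.0
    ss_subj = 0.0
    for lev in levels:
        sel = groups == lev
        gm = subj_means[sel].mean()
        ss_group += n_runs * sel.sum() * (gm - grand) ** 2
        ss_subj += n_runs * np.sum((subj_means[sel] - gm) ** 2)
    df1 = len(levels) - 1
    df2 = len(groups) - len(levels)
    ms_group = ss_group / df1
    ms_subj = ss_subj / df2
    f = ms_group / ms_subj
    p = float(stats.f.sf(f, df1, df2))
    return float(f), (df1, df2), p


def bonferroni_alpha(alpha: float, k: int) -> float:
    """Bonferroni-adjusted per-test threshold alpha/k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return alpha / k


def rrb_strata_test(roi_means, ados_rrb) -> tuple[float, float]:
    """Two-sample t of ROI GMV between RRB = 0 and RRB >= 1 strata;
    positive t means the RRB = 0 stratum has larger GMV."""
    roi_means = np.asarray(roi_means, dtype=float)
    rrb = np.asarray(ados_rrb, dtype=float)
    zero = roi_means[rrb == 0]
    high = roi_means[rrb >= 1]
    if len(zero) == 0:
        raise ValueError("empty stratum: RRB = 0")
    if len(high) == 0:
        raise ValueError("empty stratum: RRB >= 1")
    t, _, p = two_sample_t(zero, high)
    return t, p
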