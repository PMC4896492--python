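"""Structure-function models: d' versus Talairach electrode coordinates.

Each category/region/hemisphere cell gets a random-intercept linear
mixed-effects model

    d' ~ 1 + c1 + c2 + c1:c2 + (1 | subject)

where (c1, c2) are mean-centered coordinates: (x, y) in ventral temporal
cortex (z is dropped — x and z are nearly collinear along the cortical
sheet) and (z, y) in lateral occipital cortex (x dropped), with a Spearman
collinearity screen reported alongside. Estimation is REML with the single
subject-variance ratio profiled out (closed-form GLS for the fixed effects
at each ratio, bounded scalar search over the ratio); fixed-effect
p-values use t statistics with Satterthwaite-approximated degrees of
freedom. Word-category models are fit in left-hemisphere cells only (the
word task was run only in the left-hemisphere cohort).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["center_coordinates", "collinearity_screen", "fit_lme",
           "topology_report", "LMEFit", "REGION_AXES"]

#: fixed per-region coordinate axes entering the models (the dropped axis
#: is collinear with the retained one along the cortical sheet)
REGION_AXES = {"VTC": ("x", "y"), "LOC": ("z", "y")}

RATIO_BOUNDS = (0.0, 1e3)
CONV_TOL = 1e-10


@dataclass
class LMEFit:
    """One fitted random-intercept model for a category/region/hemisphere."""

    category: str
    region: str
    hemisphere: str
    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    df: np.ndarray
    pvalues: np.ndarray
    sigma2_subject: float
    sigma2_resid: float
    n_obs: int
    n_subjects: int
    converged: bool = True
    boundary: bool = False        # subject variance on the zero boundary
    degenerate: bool = False      # random intercept unidentifiable
    reml_criterion: float = field(default=np.nan)

    def coefficients(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms, "estimate": self.beta, "se": self.se,
            "df": self.df, "p": self.pvalues,
        })


def center_coordinates(geometry: pd.DataFrame) -> pd.DataFrame:
    """Mean-center x/y/z within each hemisphere x region cell.

    Adds ``cx, cy, cz`` columns; within-cell means of the centered
    coordinates are zero by construction.
    """
    out = geometry.copy()
    for ax in ("x", "y", "z"):
        out["c" + ax] = out[ax] - out.groupby(["hemisphere", "region"])[ax].transform("mean")
    return out


def collinearity_screen(geometry: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlations among x, y, z per region x hemisphere.

    Returns one row per cell and axis pair with r_s, the p-value and the
    axis dropped from that region's models (fixed per region, not
    data-driven). Constant coordinates yield NaN correlations.
    """
    rows = []
    for (reg, hemi), grp in geometry.groupby(["region", "hemisphere"]):
        if len(grp) < 3:
            raise ValueError(f"need >= 3 electrodes in {reg}/{hemi}")
        dropped = ({"x", "y", "z"} - set(REGION_AXES.get(reg, ("x", "y")))).pop()
        for a, b in (("x", "y"), ("x", "z"), ("y", "z")):
            va, vb = grp[a].to_numpy(float), grp[b].to_numpy(float)
            if np.all(va == va[0]) or np.all(vb == vb[0]):
                rs, p = np.nan, np.nan
            else:
                rs, p = stats.spearmanr(va, vb)
            rows.append({"region": reg, "hemisphere": hemi, "pair": f"{a}-{b}",
                         "spearman_r": rs, "p": p, "n": len(grp),
                         "dropped_axis": dropped})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# profiled REML machinery


def _group_apply_vinv(arr: np.ndarray, sizes: np.ndarray, lam: float) -> np.ndarray:
    """Apply V^-1 = blockdiag(I - lam/(1+lam*n_i) * J) to rows of arr."""
    out = arr.copy()
    start = 0
    for n_i in sizes:
        block = arr[start:start + n_i]
        shrink = lam / (1.0 + lam * n_i)
        out[start:start + n_i] = block - shrink * block.sum(axis=0, keepdims=True)
        start += n_i
    return out


def _profiled_reml(lam: float, X: np.ndarray, y: np.ndarray,
                   sizes: np.ndarray):
    """REML criterion (-2 log-lik up to a constant) at variance ratio lam."""
    n, p = X.shape
    WX = _group_apply_vinv(X, sizes, lam)
    Wy = _group_apply_vinv(y[:, None], sizes, lam)[:, 0]
    XtWX = X.T @ WX
    XtWy = X.T @ Wy
    beta = np.linalg.solve(XtWX, XtWy)
    r = y - X @ beta
    rWr = float(r @ _group_apply_vinv(r[:, None], sizes, lam)[:, 0])
    sigma2 = rWr / (n - p)
    logdet_v = float(np.sum(np.log1p(lam * sizes)))
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    crit = (n - p) * np.log(sigma2) + logdet_v + logdet_xwx
    return crit, beta, sigma2, XtWX


def _reml_minus2ll(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                   sizes: np.ndarray) -> float:
    """Unprofiled -2 REML log-lik at theta = (sigma2_subject, sigma2_resid)."""
    s2u, s2e = theta
    lam = s2u / s2e
    n, p = X.shape
    WX = _group_apply_vinv(X, sizes, lam)
    Wy = _group_apply_vinv(y[:, None], sizes, lam)[:, 0]
    XtWX = X.T @ WX
    beta = np.linalg.solve(XtWX, X.T @ Wy)
    r = y - X @ beta
    rWr = float(r @ _group_apply_vinv(r[:, None], sizes, lam)[:, 0])
    logdet_sigma = n * np.log(s2e) + float(np.sum(np.log1p(lam * sizes)))
    _, logdet_xsx = np.linalg.slogdet(XtWX / s2e)
    return logdet_sigma + logdet_xsx + rWr / s2e


def _beta_cov(theta: np.ndarray, X: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    s2u, s2e = theta
    lam = s2u / s2e
    WX = _group_apply_vinv(X, sizes, lam)
    return s2e * np.linalg.inv(X.T @ WX)


def _satterthwaite_df(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                      sizes: np.ndarray) -> np.ndarray:
    """Satterthwaite df per coefficient: 2*var_j^2 / (g_j' A g_j).

    g_j is the gradient of Var(beta_j) in the variance components and A the
    asymptotic covariance of the REML variance estimates (inverse Hessian of
    the -2 REML log-likelihood), both by central finite differences.
    """
    p = X.shape[1]
    h = np.maximum(1e-7, 1e-4 * np.abs(theta))

    def var_diag(th):
        return np.diag(_beta_cov(th, X, sizes))

    grads = np.empty((p, 2))
    for k in range(2):
        up, dn = theta.copy(), theta.copy()
        up[k] += h[k]
        dn[k] = max(dn[k] - h[k], 1e-12)
        grads[:, k] = (var_diag(up) - var_diag(dn)) / (up[k] - dn[k])

    H = np.empty((2, 2))
    f0 = _reml_minus2ll(theta, X, y, sizes)
    for k in range(2):
        for m in range(k, 2):
            if k == m:
                up, dn = theta.copy(), theta.copy()
                up[k] += h[k]
                dn[k] = max(dn[k] - h[k], 1e-12)
                fu = _reml_minus2ll(up, X, y, sizes)
                fd = _reml_minus2ll(dn, X, y, sizes)
                H[k, k] = (fu - 2 * f0 + fd) / ((0.5 * (up[k] - dn[k])) ** 2)
            else:
                pp, pm, mp, mm = (theta.copy() for _ in range(4))
                pp[k] += h[k]; pp[m] += h[m]
                pm[k] += h[k]; pm[m] = max(pm[m] - h[m], 1e-12)
                mp[k] = max(mp[k] - h[k], 1e-12); mp[m] += h[m]
                mm[k] = max(mm[k] - h[k], 1e-12); mm[m] = max(mm[m] - h[m], 1e-12)
                num = (_reml_minus2ll(pp, X, y, sizes) - _reml_minus2ll(pm, X, y, sizes)
                       - _reml_minus2ll(mp, X, y, sizes) + _reml_minus2ll(mm, X, y, sizes))
                H[k, m] = H[m, k] = num / ((pp[k] - mp[k]) * (pp[m] - pm[m]))
    n_minus_p = X.shape[0] - p
    try:
        A = 2.0 * np.linalg.inv(H)   # Var(theta_hat); H is of -2*loglik
        v = var_diag(theta)
        denom = np.einsum("jk,kl,jl->j", grads, A, grads)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = 2.0 * v ** 2 / denom
        df = np.where(np.isfinite(df) & (df > 1.0), df, n_minus_p)
        return np.minimum(df, n_minus_p * 10.0)
    except np.linalg.LinAlgError:
        return np.full(p, float(n_minus_p))


def fit_lme(y: np.ndarray, coords: np.ndarray, subjects: np.ndarray,
            terms: list[str] | None = None,
            category: str = "", region: str = "", hemisphere: str = "",
            add_interaction: bool = True) -> LMEFit:
    """Random-intercept LME of d' on two centered coordinates.

    Parameters
    ----------
    y : ndarray (n,)
        Per-electrode d' values.
    coords : ndarray (n, 2)
        Centered coordinate predictors (c1, c2).
    subjects : ndarray (n,)
        Subject identifier per electrode (random-intercept grouping).
    add_interaction : include the c1:c2 product term (default True).

    Notes
    -----
    REML: the subject-to-residual variance ratio is profiled and optimized
    by bounded scalar search on [0, 1e3] (tolerance 1e-10) after a coarse
    grid scan; fixed effects are closed-form GLS at the optimum. A ratio
    estimate on the zero boundary is flagged and the fit then equals OLS
    with residual degrees of freedom. One electrode per subject makes the
    random intercept unidentifiable; such fits are flagged degenerate and
    reported as OLS.
    """
    y = np.asarray(y, float)
    coords = np.asarray(coords, float)
    subjects = np.asarray(subjects)
    n = y.size
    if coords.shape != (n, 2):
        raise ValueError("coords must be (n, 2)")
    cols = [np.ones(n), coords[:, 0], coords[:, 1]]
    if terms is None:
        terms = ["intercept", "c1", "c2"] + (["c1:c2"] if add_interaction else [])
    if add_interaction:
        cols.append(coords[:, 0] * coords[:, 1])
    X = np.column_stack(cols)
    p = X.shape[1]
    if n <= p:
        raise ValueError("more coefficients than observations")
    if np.linalg.matrix_rank(X) < p:
        corr = np.corrcoef(X[:, 1:], rowvar=False)
        bad = [terms[1:][i] for i in range(corr.shape[0])
               if np.any(np.abs(np.delete(corr[i], i)) > 0.999)]
        raise ValueError(f"singular design matrix; collinear columns: {bad or terms}")

    # sort observations into contiguous subject blocks
    order = np.argsort(subjects, kind="stable")
    Xs, ys, subj = X[order], y[order], subjects[order]
    # subj is sorted, so blocks are contiguous in np.unique's sorted order
    uniq, sizes = np.unique(subj, return_counts=True)
    n_subjects = uniq.size
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for a random intercept")

    degenerate = bool(np.all(sizes == 1))

    def crit(lam):
        return _profiled_reml(lam, Xs, ys, sizes)[0]

    if degenerate:
        lam_hat, converged = 0.0, True
    else:
        grid = np.concatenate([[0.0], np.geomspace(1e-4, RATIO_BOUNDS[1], 40)])
        vals = [crit(g) for g in grid]
        i0 = int(np.argmin(vals))
        lo = grid[max(i0 - 1, 0)]
        hi = grid[min(i0 + 1, grid.size - 1)]
        if lo == hi:
            lam_hat, converged = lo, True
        else:
            res = optimize.minimize_scalar(crit, bounds=(lo, hi), method="bounded",
                                           options={"xatol": CONV_TOL})
            lam_hat = float(res.x)
            converged = bool(res.success)
            if crit(0.0) <= res.fun:
                lam_hat = 0.0

    criterion, beta, sigma2, XtWX = _profiled_reml(lam_hat, Xs, ys, sizes)
    boundary = lam_hat <= 1e-8
    s2u = lam_hat * sigma2
    theta = np.array([s2u, sigma2])
    cov = sigma2 * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov))

    if boundary or degenerate:
        df = np.full(p, float(n - p))
    else:
        df = _satterthwaite_df(theta, Xs, ys, sizes)
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    return LMEFit(category=category, region=region, hemisphere=hemisphere,
                  terms=list(terms), beta=beta, se=se, df=df, pvalues=pvals,
                  sigma2_subject=float(s2u), sigma2_resid=float(sigma2),
                  n_obs=n, n_subjects=n_subjects, converged=converged,
                  boundary=bool(boundary or degenerate), degenerate=degenerate,
                  reml_criterion=float(criterion))


def fit_region_models(table: pd.DataFrame, q_flagged: bool = True) -> list[LMEFit]:
    """Fit the per-category models for every region x hemisphere cell.

    ``table`` is a selectivity table (one row per electrode x category with
    d_prime, subject, hemisphere, region, x, y, z). Word models are fit
    only in left-hemisphere cells.
    """
    geo_cols = ["subject", "hemisphere", "region", "x", "y", "z"]
    geometry = (table.drop_duplicates("electrode").set_index("electrode")[geo_cols])
    centered = center_coordinates(geometry)
    fits = []
    for (reg, hemi, cat), grp in table.dropna(subset=["d_prime"]).groupby(
            ["region", "hemisphere", "category"]):
        if cat == "word" and hemi != "L":
            continue
        axes = REGION_AXES.get(reg)
        if axes is None:
            continue
        c = centered.loc[grp["electrode"]]
        coords = c[["c" + axes[0], "c" + axes[1]]].to_numpy(float)
        try:
            fit = fit_lme(grp["d_prime"].to_numpy(float), coords,
                          c["subject"].to_numpy(),
                          terms=["intercept", axes[0], axes[1],
                                 f"{axes[0]}:{axes[1]}"],
                          category=cat, region=reg, hemisphere=hemi)
        except ValueError:
            continue
        fits.append(fit)
    return fits


def topology_report(fits: list[LMEFit], table: pd.DataFrame,
                    boundary_mm: dict | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Coefficient tables plus significant-electrode counts per category.

    Returns ``(coefficients, counts)``. ``coefficients`` mirrors a
    per-category fixed-effects table (term, estimate, SE, p, N_obs);
    ``counts`` gives significant-electrode tallies per
    category/region/hemisphere and, when ``boundary_mm`` supplies a
    user-provided axis boundary per region (e.g. the x position of the
    mid-fusiform sulcus), how many fall on each side of it. Cells with no
    flagged electrodes are absent rather than zero-filled.
    """
    crows = []
    for f in fits:
        for i, term in enumerate(f.terms):
            crows.append({"category": f.category, "region": f.region,
                          "hemisphere": f.hemisphere, "term": term,
                          "estimate": f.beta[i], "se": f.se[i],
                          "p": f.pvalues[i], "n_obs": f.n_obs,
                          "boundary": f.boundary})
    coefficients = pd.DataFrame(crows)

    sig = table[table["fdr_flag"] == True]  # noqa: E712
    rows = []
    for (reg, hemi, cat), grp in sig.groupby(["region", "hemisphere", "category"]):
        row = {"region": reg, "hemisphere": hemi, "category": cat,
               "n_significant": len(grp)}
        if boundary_mm and reg in boundary_mm:
            axis, cut = boundary_mm[reg]
            v = grp[axis].to_numpy(float)
            row["n_below_boundary"] = int((v <= cut).sum())
            row["n_above_boundary"] = int((v > cut).sum())
        rows.append(row)
    counts = pd.DataFrame(rows)
    return coefficients, counts
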