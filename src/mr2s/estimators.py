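"""Causal-effect estimators for summary-level two-sample MR.

All estimators consume the per-SNP quadruple (beta_exp, se_exp, beta_out,
se_out) for J harmonized instruments and return an :class:`MREstimate`
with the causal slope on the outcome's log-odds scale, its standard
error, the odds ratio with a 95% CI, and a two-sided p-value.

Implemented estimators:

``ivw``
    Inverse-variance-weighted: weighted regression of beta_out on beta_exp
    through the origin with weights 1/se_out^2.  The multiplicative
    random-effects variant inflates the fixed-effect SE by
    sqrt(max(1, Q/(J-1))) to absorb heterogeneity, and is the usual
    primary analysis.
``weighted_median``
    The weighted median of the per-SNP Wald ratios; consistent as long as
    at least half the total instrument weight comes from valid
    instruments.  SE by seeded parametric bootstrap.
``mr_egger``
    Weighted regression with a free intercept.  The intercept estimates
    average directional pleiotropy; the slope remains consistent under the
    InSIDE assumption (instrument strength independent of direct effects).
``egger_simex``
    Simulation-extrapolation correction of MR-Egger for regression
    dilution when exposure effects carry non-negligible estimation error
    (NOME violated): noise with variance lambda*se_exp^2 is added at a
    grid of lambda values and a quadratic in lambda is extrapolated back
    to lambda = -1, the zero-total-error limit.

P-value conventions (configurable per call): normal reference for IVW and
the weighted median, Student t with J-2 df for the Egger slope and
intercept.  Odds-ratio CIs always use +/- 1.96 SE on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

Z95 = 1.959963984540054  # two-sided 95% normal quantile

METHOD_LABELS = {
    "ivw_fixed": "IVW (fixed effects)",
    "ivw_mre": "IVW (multiplicative random effects)",
    "weighted_median": "Weighted median",
    "egger": "MR-Egger",
    "egger_simex": "MR-Egger (SIMEX)",
}


@dataclass
class MREstimate:
    """One estimator's causal effect and, for Egger methods, its intercept."""

    method: str
    slope: float
    se: float
    pvalue: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    extras: dict = field(default_factory=dict)

    @property
    def or_point(self) -> float:
        return math.exp(self.slope)

    @property
    def ci_low(self) -> float:
        return math.exp(self.slope - Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.slope + Z95 * self.se)

    def as_row(self) -> dict:
        row = {
            "method": self.method,
            "n_snps": self.n_snps,
            "slope": self.slope,
            "se": self.se,
            "or": self.or_point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
        }
        if self.intercept is not None:
            row.update(intercept=self.intercept, intercept_se=self.intercept_se,
                       intercept_p=self.intercept_p)
        return row


def as_arrays(insts) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Extract (beta_exp, se_exp, beta_out, se_out) from a harmonized frame,
    a mapping of arrays, or a 4-tuple.  Dropped instruments are excluded."""
    if isinstance(insts, pd.DataFrame):
        if "action_taken" in insts.columns:
            insts = insts[~insts["action_taken"].str.startswith("dropped")]
        cols = ("beta_exp", "se_exp", "beta_out", "se_out")
        return tuple(insts[c].to_numpy(dtype=float) for c in cols)
    if isinstance(insts, dict):
        return tuple(np.asarray(insts[c], dtype=float)
                     for c in ("beta_exp", "se_exp", "beta_out", "se_out"))
    bx, sx, by, sy = insts
    return (np.asarray(bx, float), np.asarray(sx, float),
            np.asarray(by, float), np.asarray(sy, float))


def _p_normal(z):
    return 2.0 * stats.norm.sf(np.abs(z))


def _p_t(z, df):
    return 2.0 * stats.t.sf(np.abs(z), df)


# ---------------------------------------------------------------------------
# IVW

def ivw(insts, mode: str = "multiplicative_random_effects",
        p_reference: str = "normal") -> MREstimate:
    """Inverse-variance-weighted estimate.

    ``mode='fixed'`` uses the fixed-effect SE 1/sqrt(sum beta_exp^2/se_out^2);
    ``mode='multiplicative_random_effects'`` multiplies it by
    sqrt(max(1, Q/(J-1))) with Q the Cochran heterogeneity statistic, so
    the random-effects SE is never smaller than the fixed one.
    """
    bx, sx, by, sy = as_arrays(insts)
    j = bx.size
    if j < 2:
        raise ValueError("IVW requires at least 2 instruments")
    w = 1.0 / sy ** 2
    sxx = float(np.sum(w * bx * bx))
    slope = float(np.sum(w * bx * by)) / sxx
    se_fixed = 1.0 / math.sqrt(sxx)
    q = float(np.sum(w * (by - slope * bx) ** 2))
    if mode == "fixed":
        se = se_fixed
    elif mode == "multiplicative_random_effects":
        se = se_fixed * math.sqrt(max(1.0, q / (j - 1)))
    else:
        raise ValueError(f"unknown IVW mode {mode!r}")
    z = slope / se
    p = float(_p_t(z, j - 1)) if p_reference == "t" else float(_p_normal(z))
    return MREstimate(method="ivw_fixed" if mode == "fixed" else "ivw_mre",
                      slope=slope, se=se, pvalue=p, n_snps=j,
                      extras={"q": q, "se_fixed": se_fixed})


# ---------------------------------------------------------------------------
# Weighted median

def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation of the standardized
    cumulative weight: s_j = (cumsum(w)_j - w_j/2) / sum(w), slope at s=0.5."""
    order = np.argsort(ratios, kind="stable")
    r = np.asarray(ratios, float)[order]
    w = np.asarray(weights, float)[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


def weighted_median(insts, n_boot: int = 1000, seed: int = 0,
                    return_se: bool = True) -> MREstimate:
    """Weighted median of Wald ratios with inverse-variance weights.

    Weights are 1/wald_se^2 = beta_exp^2/se_out^2.  The SE is the standard
    deviation of the estimate over ``n_boot`` parametric resamples in
    which beta_exp and beta_out are perturbed by their standard errors;
    the bootstrap is seeded for reproducibility.
    """
    bx, sx, by, sy = as_arrays(insts)
    j = bx.size
    if j < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    ratios = by / bx
    weights = bx ** 2 / sy ** 2
    slope = weighted_median_point(ratios, weights)
    if not return_se:
        return MREstimate(method="weighted_median", slope=slope,
                          se=float("nan"), pvalue=float("nan"), n_snps=j)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = bx + sx * rng.standard_normal(j)
        by_b = by + sy * rng.standard_normal(j)
        ok = bx_b != 0
        boots[b] = weighted_median_point(by_b[ok] / bx_b[ok],
                                         bx_b[ok] ** 2 / sy[ok] ** 2)
    se = float(np.std(boots, ddof=1))
    p = float(_p_normal(slope / se))
    return MREstimate(method="weighted_median", slope=slope, se=se, pvalue=p,
                      n_snps=j, extras={"n_boot": n_boot, "seed": seed})


# ---------------------------------------------------------------------------
# MR-Egger

def _orient(bx, by):
    """Flip instruments so every exposure effect is non-negative.

    The Egger intercept is only identified relative to the
    exposure-increasing allele; orientation happens inside the estimator
    and never touches the harmonized table.
    """
    s = np.where(bx < 0, -1.0, 1.0)
    return bx * s, by * s


def _wls_with_intercept(x, y, w):
    """Closed-form weighted least squares of y on [1, x]; returns
    (intercept, slope, se_intercept, se_slope, rss_weighted)."""
    sw = np.sum(w)
    mx = np.sum(w * x) / sw
    my = np.sum(w * y) / sw
    sxx = np.sum(w * (x - mx) ** 2)
    # relative guard: identical exposure effects leave only rounding residue
    if sxx <= 1e-12 * max(float(np.sum(w * x ** 2)), np.finfo(float).tiny):
        raise ValueError("no spread in instrument strength")
    slope = np.sum(w * (x - mx) * (y - my)) / sxx
    intercept = my - slope * mx
    resid = y - intercept - slope * x
    rss = float(np.sum(w * resid ** 2))
    se_slope = math.sqrt(1.0 / sxx)
    se_intercept = math.sqrt(1.0 / sw + mx ** 2 / sxx)
    return float(intercept), float(slope), se_intercept, se_slope, rss


def mr_egger(insts, p_reference: str = "t") -> MREstimate:
    """MR-Egger regression: weighted fit of beta_out on beta_exp with a
    free intercept, weights 1/se_out^2, instruments oriented to
    beta_exp >= 0.  Both SEs are multiplied by the residual scale
    max(1, sqrt(Q'/(J-2))) (multiplicative random effects); p-values use
    the t distribution with J-2 df by default.
    """
    bx, _, by, sy = as_arrays(insts)
    j = bx.size
    if j < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    bx, by = _orient(bx, by)
    w = 1.0 / sy ** 2
    intercept, slope, se_i, se_s, rss = _wls_with_intercept(bx, by, w)
    scale = max(1.0, math.sqrt(rss / (j - 2)))
    se_i *= scale
    se_s *= scale
    pf = (lambda z: float(_p_t(z, j - 2))) if p_reference == "t" \
        else (lambda z: float(_p_normal(z)))
    return MREstimate(method="egger", slope=slope, se=se_s, pvalue=pf(slope / se_s),
                      n_snps=j, intercept=intercept, intercept_se=se_i,
                      intercept_p=pf(intercept / se_i),
                      extras={"q_prime": rss, "scale": scale})


# ---------------------------------------------------------------------------
# MR-Egger with SIMEX

DEFAULT_LAMBDA_GRID = (0.0, 0.5, 1.0, 1.5, 2.0)


def _egger_point_matrix(BX, BY, w):
    """Vectorised Egger point estimates for a batch of datasets.

    BX, BY: (B, J) arrays; w: (J,) weights.  Rows are oriented to
    non-negative exposure effects.  Returns (intercepts, slopes), (B,).
    """
    s = np.where(BX < 0, -1.0, 1.0)
    X = BX * s
    Y = BY * s
    sw = np.sum(w)
    mx = X @ w / sw
    my = Y @ w / sw
    xc = X - mx[:, None]
    sxx = np.einsum("j,bj,bj->b", w, xc, xc)
    sxy = np.einsum("j,bj,bj->b", w, xc, Y - my[:, None])
    slope = sxy / sxx
    intercept = my - slope * mx
    return intercept, slope


def _quad_extrapolate(lams: np.ndarray, means: np.ndarray, target: float = -1.0):
    """Fit a quadratic in lambda to per-lambda means (columns of a (L, B)
    or (L,) array) and evaluate at ``target``."""
    V = np.vander(lams, 3, increasing=True)  # [1, lam, lam^2]
    coef, *_ = np.linalg.lstsq(V, means, rcond=None)
    t = np.array([1.0, target, target ** 2])
    return t @ coef


def egger_simex(insts, lambda_grid=DEFAULT_LAMBDA_GRID,
                n_sim_per_lambda: int = 1000, seed: int = 0,
                p_reference: str = "t") -> MREstimate:
    """SIMEX-corrected MR-Egger.

    For each lambda in the grid, ``n_sim_per_lambda`` replicates add
    N(0, lambda * se_exp^2) noise to the exposure effects and refit the
    Egger regression; the per-lambda mean slope and intercept are fit with
    a quadratic in lambda and extrapolated to lambda = -1 (total
    measurement-error variance zero).  SEs come from a delete-one
    jackknife over replicates propagated through the extrapolation, added
    in quadrature to the plain Egger sampling SE (the naive SE; the
    jackknife only measures the simulation component).
    """
    lams = np.asarray(lambda_grid, dtype=float)
    if lams[0] != 0.0 or np.any(np.diff(lams) <= 0):
        raise ValueError("lambda_grid must start at 0 and be strictly increasing")
    bx, sx, by, sy = as_arrays(insts)
    j = bx.size
    if j < 3:
        raise ValueError("SIMEX Egger requires at least 3 instruments")
    base = mr_egger((bx, sx, by, sy), p_reference=p_reference)
    if np.all(sx == 0):
        return MREstimate(method="egger_simex", slope=base.slope, se=base.se,
                          pvalue=base.pvalue, n_snps=j, intercept=base.intercept,
                          intercept_se=base.intercept_se, intercept_p=base.intercept_p,
                          extras={"lambda_grid": tuple(lams), "degenerate": True})

    rng = np.random.default_rng(seed)
    B = int(n_sim_per_lambda)
    w = 1.0 / sy ** 2
    # per-lambda replicate estimates, shape (L, B)
    inter = np.empty((lams.size, B))
    slope = np.empty((lams.size, B))
    for li, lam in enumerate(lams):
        if lam == 0.0:
            inter[li] = base.intercept
            slope[li] = base.slope
            continue
        noise = math.sqrt(lam) * sx * rng.standard_normal((B, j))
        inter[li], slope[li] = _egger_point_matrix(bx + noise, np.tile(by, (B, 1)), w)

    mean_slope = slope.mean(axis=1)
    mean_inter = inter.mean(axis=1)
    slope_hat = float(_quad_extrapolate(lams, mean_slope))
    inter_hat = float(_quad_extrapolate(lams, mean_inter))

    # delete-one-replicate jackknife through the extrapolant
    jk_slope = (slope.sum(axis=1, keepdims=True) - slope) / (B - 1)  # (L, B)
    jk_inter = (inter.sum(axis=1, keepdims=True) - inter) / (B - 1)
    jk_s = _quad_extrapolate(lams, jk_slope)  # (B,)
    jk_i = _quad_extrapolate(lams, jk_inter)
    fac = (B - 1) / B
    var_sim_s = fac * float(np.sum((jk_s - jk_s.mean()) ** 2))
    var_sim_i = fac * float(np.sum((jk_i - jk_i.mean()) ** 2))
    se_s = math.sqrt(base.se ** 2 + var_sim_s)
    se_i = math.sqrt(base.intercept_se ** 2 + var_sim_i)

    pf = (lambda z: float(_p_t(z, j - 2))) if p_reference == "t" \
        else (lambda z: float(_p_normal(z)))
    return MREstimate(method="egger_simex", slope=slope_hat, se=se_s,
                      pvalue=pf(slope_hat / se_s), n_snps=j,
                      intercept=inter_hat, intercept_se=se_i,
                      intercept_p=pf(inter_hat / se_i),
                      extras={"lambda_grid": tuple(lams),
                              "n_sim_per_lambda": B, "seed": seed,
                              "mean_slope_per_lambda": mean_slope.tolist(),
                              "mean_intercept_per_lambda": mean_inter.tolist()})
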