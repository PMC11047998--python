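"""Heterogeneity and horizontal-pleiotropy diagnostics.

The validity checks that accompany every two-sample MR analysis:

* Cochran's Q for the IVW fit and Rücker's Q' for the Egger fit — weighted
  residual sums of squares referred to chi-square with J-1 and J-2 df.
* I^2_GX — the proportion of variance in the observed exposure effects not
  attributable to estimation error; low values warn that MR-Egger suffers
  regression dilution (NOME violation) and motivate the SIMEX correction.
* MR-PRESSO — a parametric-simulation global test for horizontal
  pleiotropy based on the leave-one-out IVW residual sum of squares, with
  per-SNP outlier detection and a distortion test comparing the estimate
  before and after outlier removal.
* A method-selection rule turning the diagnostics into a labelled
  recommendation of the primary estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import as_arrays, ivw

logger = logging.getLogger(__name__)


def cochran_q(insts, slope: float) -> tuple[float, float]:
    """Cochran's Q about the IVW slope: sum w_j (beta_out - slope*beta_exp)^2,
    w_j = 1/se_out^2; p from the upper chi-square tail with J-1 df."""
    bx, _, by, sy = as_arrays(insts)
    q = float(np.sum((by - slope * bx) ** 2 / sy ** 2))
    p = float(stats.chi2.sf(q, bx.size - 1))
    return q, p


def rucker_q(insts, intercept: float, slope: float) -> tuple[float, float]:
    """Rücker's Q' about the Egger line (intercept + slope*beta_exp),
    instruments oriented to beta_exp >= 0; chi-square with J-2 df."""
    bx, _, by, sy = as_arrays(insts)
    s = np.where(bx < 0, -1.0, 1.0)
    q = float(np.sum((by * s - intercept - slope * bx * s) ** 2 / sy ** 2))
    p = float(stats.chi2.sf(q, bx.size - 2))
    return q, p


def i2_gx(insts) -> float:
    """Instrument-strength heterogeneity I^2_GX, in percent.

    Q_GX is the 1/se_exp^2-weighted sum of squares of the exposure effects
    about their weighted mean; I^2_GX = max(0, (Q_GX - (J-1))/Q_GX) * 100.
    Values near 100 mean exposure effects are measured essentially without
    error relative to their spread, so plain MR-Egger is trustworthy.
    """
    bx, sx, _, _ = as_arrays(insts)
    w = 1.0 / sx ** 2
    mean_w = float(np.sum(w * bx) / np.sum(w))
    q_gx = float(np.sum(w * (bx - mean_w) ** 2))
    if q_gx <= 0:
        return 0.0
    return max(0.0, (q_gx - (bx.size - 1)) / q_gx) * 100.0


# ---------------------------------------------------------------------------
# MR-PRESSO

@dataclass
class PressoResult:
    global_p: float
    rss_obs: float
    outliers: list
    outlier_p: np.ndarray          # Bonferroni-corrected per-SNP p
    distortion_p: float | None
    slope_all: float
    slope_no_outliers: float | None
    n_sim: int
    seed: int


def _loo_ivw_slopes(BX, BY, w):
    """Leave-one-out IVW slopes for each dataset row and each left-out SNP.

    BX, BY: (B, J); w: (J,).  Returns (B, J) slopes where entry (b, j) is
    the IVW slope of dataset b with SNP j removed.
    """
    sxy = np.sum(w * BX * BY, axis=1, keepdims=True)
    sxx = np.sum(w * BX * BX, axis=1, keepdims=True)
    return (sxy - w * BX * BY) / (sxx - w * BX * BX)


def presso(insts, n_sim: int = 1000, seed: int = 0,
           outlier_alpha: float = 0.05, n_distortion: int = 1000) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests.

    The observed statistic is RSS = sum_j w_j (beta_out_j -
    slope_{-j} beta_exp_j)^2 with slope_{-j} the leave-one-out IVW slope.
    Its null distribution is built from ``n_sim`` parametric replicates
    drawing beta_out_j* ~ N(slope_{-j} beta_exp_j, se_out_j^2) and
    beta_exp_j* ~ N(beta_exp_j, se_exp_j^2); the global p-value is the
    add-one empirical tail (1 + #{RSS* >= RSS}) / (n_sim + 1), hence never
    below 1/(n_sim+1).

    Per-SNP outlier p-values compare each SNP's observed weighted squared
    residual with its simulated distribution, Bonferroni-corrected by J;
    SNPs below ``outlier_alpha`` after correction are flagged.  When
    outliers exist the distortion test compares the change in IVW slope
    after their removal against removal of ``n_distortion`` random subsets
    of the same size.
    """
    if n_sim < 100:
        raise ValueError("n_sim < 100 gives an unstable empirical p-value")
    bx, sx, by, sy = as_arrays(insts)
    j = bx.size
    if j < 4:
        raise ValueError("MR-PRESSO requires at least 4 instruments")
    rng = np.random.default_rng(seed)
    w = 1.0 / sy ** 2

    slope_loo = _loo_ivw_slopes(bx[None, :], by[None, :], w)[0]
    resid_obs = w * (by - slope_loo * bx) ** 2
    rss_obs = float(np.sum(resid_obs))

    BX = bx + sx * rng.standard_normal((n_sim, j))
    BY = slope_loo * bx + sy * rng.standard_normal((n_sim, j))
    slope_loo_sim = _loo_ivw_slopes(BX, BY, w)
    resid_sim = w * (BY - slope_loo_sim * BX) ** 2        # (n_sim, J)
    rss_sim = resid_sim.sum(axis=1)

    global_p = (1.0 + float(np.sum(rss_sim >= rss_obs))) / (n_sim + 1.0)
    p_snp = (1.0 + (resid_sim >= resid_obs).sum(axis=0)) / (n_sim + 1.0)
    p_corr = np.minimum(1.0, p_snp * j)
    flagged = np.flatnonzero(p_corr < outlier_alpha)

    snp_ids = None
    if isinstance(insts, pd.DataFrame) and "snp_id" in insts.columns:
        kept = insts[~insts["action_taken"].str.startswith("dropped")] \
            if "action_taken" in insts.columns else insts
        snp_ids = kept["snp_id"].to_numpy()
    outliers = [snp_ids[i] if snp_ids is not None else int(i) for i in flagged]

    slope_all = ivw((bx, sx, by, sy), mode="fixed").slope
    slope_no = None
    distortion_p = None
    if flagged.size and flagged.size < j - 1:
        keep = np.setdiff1d(np.arange(j), flagged)
        slope_no = ivw((bx[keep], sx[keep], by[keep], sy[keep]), mode="fixed").slope
        d_obs = slope_no - slope_all
        d_ref = np.empty(n_distortion)
        for b in range(n_distortion):
            drop = rng.choice(j, size=flagged.size, replace=False)
            kb = np.setdiff1d(np.arange(j), drop)
            d_ref[b] = ivw((bx[kb], sx[kb], by[kb], sy[kb]), mode="fixed").slope - slope_all
        distortion_p = (1.0 + float(np.sum(np.abs(d_ref) >= abs(d_obs)))) / (n_distortion + 1.0)
        logger.info("MR-PRESSO: %d outlier(s) %s; distortion p = %.3g",
                    flagged.size, outliers, distortion_p)
    return PressoResult(global_p=global_p, rss_obs=rss_obs, outliers=outliers,
                        outlier_p=p_corr, distortion_p=distortion_p,
                        slope_all=slope_all, slope_no_outliers=slope_no,
                        n_sim=n_sim, seed=seed)


# ---------------------------------------------------------------------------
# Report and method selection

@dataclass
class DiagnosticsReport:
    """Heterogeneity / pleiotropy summary for one exposure-outcome pair."""

    n_snps: int
    mean_f: float
    i2_gx: float
    cochran_q: float
    cochran_p: float
    rucker_q: float
    rucker_p: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_p: float
    simex_intercept: float | None = None
    simex_intercept_se: float | None = None
    simex_intercept_p: float | None = None
    presso_global_p: float | None = None
    presso_outliers: list = field(default_factory=list)
    presso_distortion_p: float | None = None

    def as_row(self) -> dict:
        return {
            "n_snps": self.n_snps, "mean_f": self.mean_f, "i2_gx_pct": self.i2_gx,
            "cochran_q": self.cochran_q, "cochran_p": self.cochran_p,
            "rucker_q": self.rucker_q, "rucker_p": self.rucker_p,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_p": self.egger_intercept_p,
            "simex_intercept": self.simex_intercept,
            "simex_intercept_se": self.simex_intercept_se,
            "simex_intercept_p": self.simex_intercept_p,
            "presso_global_p": self.presso_global_p,
            "presso_n_outliers": len(self.presso_outliers),
            "presso_distortion_p": self.presso_distortion_p,
        }


@dataclass
class Verdict:
    """Labelled recommendation; every estimate is always reported."""

    primary: str
    use_random_effects: bool
    notes: list


def pleiotropy_verdict(report: DiagnosticsReport, alpha: float = 0.05) -> Verdict:
    """Turn the diagnostics into a primary-method recommendation.

    Cochran p < alpha selects the multiplicative random-effects IVW over
    the fixed-effect one.  Evidence of directional pleiotropy (Egger
    intercept p < alpha, or PRESSO global p < alpha) promotes MR-Egger
    (and the outlier-corrected IVW when PRESSO found outliers) to primary,
    with IVW retained as supporting.  Otherwise IVW is primary.
    """
    notes = []
    use_re = report.cochran_p < alpha
    if use_re:
        notes.append(f"Cochran Q p = {report.cochran_p:.3g} < {alpha:g}: "
                     "heterogeneity present, random-effects IVW used")
    pleio = (report.egger_intercept_p < alpha
             or (report.presso_global_p is not None and report.presso_global_p < alpha))
    if pleio:
        primary = "egger"
        notes.append("directional pleiotropy indicated "
                     f"(Egger intercept p = {report.egger_intercept_p:.3g}"
                     + (f", PRESSO global p = {report.presso_global_p:.3g}"
                        if report.presso_global_p is not None else "")
                     + "): MR-Egger primary, IVW supporting")
        if report.presso_outliers:
            notes.append(f"PRESSO outliers {report.presso_outliers}: "
                         "outlier-corrected IVW also primary")
        elif report.presso_global_p is not None:
            notes.append("no outliers identified")
    else:
        primary = "ivw_mre" if use_re else "ivw"
    return Verdict(primary=primary, use_random_effects=use_re, notes=notes)


def report_frame(report: DiagnosticsReport) -> pd.DataFrame:
    return pd.DataFrame([report.as_row()])
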