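"""Model/Results interface tying estimators and diagnostics together.

:class:`MRModel` is built from a harmonized instrument table (or directly
from exposure and outcome summary frames via
:meth:`MRModel.from_summary_frames`); its :meth:`~MRModel.fit` runs the
requested causal estimators plus the full diagnostic battery and returns
an :class:`MRResults` holding every estimate with its uncertainty, the
heterogeneity/pleiotropy report, the method recommendation, and tabular /
text summaries.

Example
-------
>>> from mr2s import simulate, MRModel
>>> exp, out, truth = simulate.simulate_pair(simulate.SimulationConfig(seed=7))
>>> res = MRModel.from_summary_frames(exp, out).fit(seed=7)
>>> print(res.summary())              # doctest: +SKIP
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diagnostics as diag
from . import estimators as est
from . import instruments as instr
from . import summary_io

logger = logging.getLogger(__name__)

DEFAULT_METHODS = ("ivw_fixed", "ivw_mre", "weighted_median", "egger", "egger_simex")


class MRModel:
    """Two-sample MR model over a set of harmonized instruments.

    Parameters
    ----------
    harmonized
        Frame with :data:`mr2s.summary_io.HARMONIZED_COLUMNS` (rows with a
        ``dropped_*`` action are excluded automatically) or any mapping /
        tuple accepted by :func:`mr2s.estimators.as_arrays`.
    instrument_set
        Optional :class:`~mr2s.instruments.InstrumentSet` carrying per-SNP
        F statistics for the diagnostics report.
    exposure_unit
        Free-text label for the exposure's measurement unit; carried as
        opaque metadata into reports ("OR per <unit>").
    """

    def __init__(self, harmonized, instrument_set: instr.InstrumentSet | None = None,
                 exposure_unit: str = "unit of the deposited exposure beta"):
        if isinstance(harmonized, pd.DataFrame):
            self.harmonized = summary_io.estimation_subset(harmonized)
        else:
            bx, sx, by, sy = est.as_arrays(harmonized)
            self.harmonized = pd.DataFrame({
                "snp_id": [f"snp{i}" for i in range(bx.size)],
                "beta_exp": bx, "se_exp": sx, "beta_out": by, "se_out": sy,
                "eaf_exp": np.nan, "eaf_out": np.nan,
                "wald_ratio": by / bx, "wald_se": sy / np.abs(bx),
                "action_taken": "aligned",
            })
        if len(self.harmonized) < 2:
            raise ValueError("need at least 2 usable instruments")
        self.instrument_set = instrument_set
        self.exposure_unit = exposure_unit

    @classmethod
    def from_summary_frames(cls, exposure: pd.DataFrame, outcome: pd.DataFrame,
                            p_threshold: float = instr.GWS_THRESHOLD,
                            ld: instr.LdTable | None = None,
                            clump: bool = True, clump_r2: float = 0.001,
                            clump_kb: float = 10_000,
                            palindromic_eaf_limit: float = 0.42,
                            r2_convention: str = "z_based",
                            **kwargs) -> "MRModel":
        """Select, clump and harmonize raw summary frames into a model."""
        selected = instr.select_significant(exposure, p_threshold)
        if clump:
            selected = instr.ld_clump(selected, ld=ld, r2_max=clump_r2,
                                      window_kb=clump_kb)
        iset = instr.build_instrument_set(selected, convention=r2_convention)
        harmonized = summary_io.harmonize(selected, outcome,
                                          palindromic_eaf_limit=palindromic_eaf_limit)
        model = cls(harmonized, instrument_set=iset, **kwargs)
        model._full_harmonized = harmonized
        return model

    def fit(self, methods=DEFAULT_METHODS, seed: int = 0,
            n_boot: int = 1000, simex_lambda=est.DEFAULT_LAMBDA_GRID,
            simex_n_sim: int = 1000, presso_n_sim: int = 1000,
            run_presso: bool = True, alpha: float = 0.05) -> "MRResults":
        """Run the requested estimators and diagnostics.

        All randomness (median bootstrap, SIMEX replicates, PRESSO
        simulations) derives from ``seed``.
        """
        h = self.harmonized
        estimates: dict[str, est.MREstimate] = {}
        for m in methods:
            if m == "ivw_fixed":
                estimates[m] = est.ivw(h, mode="fixed")
            elif m == "ivw_mre":
                estimates[m] = est.ivw(h, mode="multiplicative_random_effects")
            elif m == "weighted_median":
                estimates[m] = est.weighted_median(h, n_boot=n_boot, seed=seed)
            elif m == "egger":
                estimates[m] = est.mr_egger(h)
            elif m == "egger_simex":
                estimates[m] = est.egger_simex(h, lambda_grid=simex_lambda,
                                               n_sim_per_lambda=simex_n_sim,
                                               seed=seed + 1)
            else:
                raise ValueError(f"unknown method {m!r}")

        ivw_ref = estimates.get("ivw_mre") or estimates.get("ivw_fixed") \
            or est.ivw(h, mode="multiplicative_random_effects")
        egger_ref = estimates.get("egger") or est.mr_egger(h)
        cq, cp = diag.cochran_q(h, ivw_ref.slope)
        rq, rp = diag.rucker_q(h, egger_ref.intercept, egger_ref.slope)
        presso_res = None
        if run_presso and len(h) >= 4:
            presso_res = diag.presso(h, n_sim=presso_n_sim, seed=seed + 2)

        simex_ref = estimates.get("egger_simex")
        report = diag.DiagnosticsReport(
            n_snps=len(h),
            mean_f=self.instrument_set.mean_f if self.instrument_set else float("nan"),
            i2_gx=diag.i2_gx(h),
            cochran_q=cq, cochran_p=cp, rucker_q=rq, rucker_p=rp,
            egger_intercept=egger_ref.intercept,
            egger_intercept_se=egger_ref.intercept_se,
            egger_intercept_p=egger_ref.intercept_p,
            simex_intercept=simex_ref.intercept if simex_ref else None,
            simex_intercept_se=simex_ref.intercept_se if simex_ref else None,
            simex_intercept_p=simex_ref.intercept_p if simex_ref else None,
            presso_global_p=presso_res.global_p if presso_res else None,
            presso_outliers=presso_res.outliers if presso_res else [],
            presso_distortion_p=presso_res.distortion_p if presso_res else None,
        )
        verdict = diag.pleiotropy_verdict(report, alpha=alpha)
        return MRResults(model=self, estimates=estimates, diagnostics=report,
                         presso=presso_res, verdict=verdict, seed=seed)


@dataclass
class MRResults:
    """Fitted causal estimates, diagnostics and recommendation."""

    model: MRModel
    estimates: dict
    diagnostics: diag.DiagnosticsReport
    presso: diag.PressoResult | None
    verdict: diag.Verdict
    seed: int

    def forest_frame(self) -> pd.DataFrame:
        """One row per estimator: OR, 95% CI, p — the forest-plot table."""
        return pd.DataFrame([e.as_row() for e in self.estimates.values()])

    def scatter_frame(self) -> pd.DataFrame:
        """Per-SNP (beta_exp, se_exp, beta_out, se_out) behind the scatter plot."""
        return self.model.harmonized[
            ["snp_id", "beta_exp", "se_exp", "beta_out", "se_out"]].copy()

    def diagnostics_frame(self) -> pd.DataFrame:
        return diag.report_frame(self.diagnostics)

    def summary(self) -> str:
        lines = [
            "Two-sample Mendelian randomization",
            "=" * 66,
            f"Instruments used: {self.diagnostics.n_snps}"
            + (f"   mean F: {self.diagnostics.mean_f:.2f}"
               if np.isfinite(self.diagnostics.mean_f) else ""),
            f"ORs are per {self.model.exposure_unit} "
            "(exposure measurement unit not standardized).",
            "",
            f"{'method':<34}{'OR':>7}{'95% CI':>17}{'p':>9}",
            "-" * 66,
        ]
        for e in self.estimates.values():
            label = est.METHOD_LABELS.get(e.method, e.method)
            lines.append(f"{label:<34}{e.or_point:>7.3f}"
                         f"{'[%.3f, %.3f]' % (e.ci_low, e.ci_high):>17}"
                         f"{_fmt_p(e.pvalue):>9}")
        d = self.diagnostics
        lines += [
            "-" * 66,
            f"Cochran Q = {d.cochran_q:.2f} (p = {_fmt_p(d.cochran_p)})   "
            f"Rucker Q' = {d.rucker_q:.2f} (p = {_fmt_p(d.rucker_p)})",
            f"I2_GX = {d.i2_gx:.2f}%",
            f"Egger intercept = {d.egger_intercept:.4g} "
            f"({d.egger_intercept_se:.4g}), p = {_fmt_p(d.egger_intercept_p)}",
        ]
        if d.presso_global_p is not None:
            lines.append(f"MR-PRESSO global p = {_fmt_p(d.presso_global_p)}; "
                         f"outliers: {d.presso_outliers or 'none identified'}")
        lines.append(f"Primary method: {self.verdict.primary}")
        for note in self.verdict.notes:
            lines.append(f"  - {note}")
        return "\n".join(lines)

    def plot_scatter(self, ax=None):
        """Per-SNP effects with the fitted estimator lines (needs matplotlib)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        h = self.model.harmonized
        s = np.where(h["beta_exp"] < 0, -1.0, 1.0)
        x, y = h["beta_exp"] * s, h["beta_out"] * s
        ax.errorbar(x, y, xerr=h["se_exp"], yerr=h["se_out"],
                    fmt="o", ms=3, lw=0.6, alpha=0.7)
        grid = np.linspace(0, float(x.max()) * 1.05, 50)
        for e in self.estimates.values():
            icpt = e.intercept or 0.0
            ax.plot(grid, icpt + e.slope * grid,
                    label=est.METHOD_LABELS.get(e.method, e.method))
        ax.set_xlabel("SNP effect on exposure")
        ax.set_ylabel("SNP effect on outcome")
        ax.legend(fontsize=8)
        return ax

    def plot_forest(self, ax=None):
        """Odds ratios with 95% CIs per estimator (needs matplotlib)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        tab = self.forest_frame()
        ypos = np.arange(len(tab))[::-1]
        ax.errorbar(tab["or"], ypos,
                    xerr=[tab["or"] - tab["ci_low"], tab["ci_high"] - tab["or"]],
                    fmt="s", color="k", capsize=3)
        ax.axvline(1.0, color="grey", lw=0.8, ls="--")
        ax.set_yticks(ypos)
        ax.set_yticklabels([est.METHOD_LABELS.get(m, m) for m in tab["method"]])
        ax.set_xlabel("Odds ratio (95% CI)")
        return ax


def _fmt_p(p: float) -> str:
    if not np.isfinite(p):
        return "nan"
    return f"{p:.3f}" if p >= 0.001 else f"{p:.1e}"
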