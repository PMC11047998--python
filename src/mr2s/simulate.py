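"""Synthetic paired GWAS summary statistics with known causal truth.

The generator draws per-SNP exposure and outcome association summaries
under the standard two-sample MR data model: a true per-allele exposure
effect gamma_j, an outcome effect theta*gamma_j plus an optional
horizontal-pleiotropy term alpha_j, and estimation noise with standard
errors derived from allele frequency and sample size under a
standardized-trait approximation,

    se ~= 1 / sqrt(2 p (1-p) n).

Pleiotropy regimes:

``none``
    All instruments valid; the exclusion-restriction assumption holds.
``balanced``
    A fraction of SNPs receive N(0, alpha_sd^2) direct effects — zero on
    average, so IVW stays consistent but heterogeneity inflates.
``directional``
    Direct effects N(alpha_mean, alpha_sd^2) applied relative to the
    exposure-increasing allele (the sign convention under which "average
    directional pleiotropy", the Egger intercept, is defined).  The InSIDE
    assumption holds because alpha is drawn independently of gamma.
``inside_violating``
    alpha_j = inside_c * gamma_j + N(0, alpha_sd^2): direct effects
    correlated with instrument strength, breaking InSIDE.

The exposure and outcome samples are independent (no overlap), matching
the two-sample design.  With ``ascertain=True`` SNPs are redrawn until
their realized exposure association reaches genome-wide significance
(p < 5e-8), reproducing the winner's-curse inflation real instrument
panels carry; parameter-recovery tests should set it to False.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import summary_io
from .instruments import GWS_THRESHOLD, LdTable

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_NON_PALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
                          ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T")]


@dataclass
class SimulationConfig:
    """Generative parameters for one paired exposure/outcome dataset.

    Defaults mirror the study conditions the pipeline is meant to emulate:
    204 independent instruments, an exposure GWAS of 436,491 and an
    outcome GWAS of 105,248, a true causal effect of 0.12 on the log-odds
    scale (odds ratio ~1.13 per unit of exposure), and per-SNP true
    effects with SD 0.03 — which yields instrument F statistics averaging
    near the low hundreds, as in large CRP GWAS panels.
    """

    n_snps: int = 204
    theta: float = 0.12
    n_exp: float = 436_491
    n_out: float = 105_248
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_sd: float = 0.03
    pleiotropy_mode: str = "none"
    pleio_frac: float = 0.0
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    inside_c: float = 0.5
    n_outliers: int = 0
    outlier_offset: float = 0.5
    ascertain: bool = True
    palindromic_frac: float = 0.2
    seed: int = 0
    max_redraw_rounds: int = 200

    def __post_init__(self):
        if not (0.0 <= self.pleio_frac <= 1.0):
            raise ValueError("pleio_frac must be in [0,1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie inside (0, 0.5]")
        if self.n_snps < self.n_outliers:
            raise ValueError("n_outliers cannot exceed n_snps")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "inside_violating"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")


class AscertainmentError(RuntimeError):
    pass


def simulate_effects(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> dict:
    """Draw the numeric core of a paired dataset as arrays.

    Returns a dict with beta_exp, se_exp, beta_out, se_out, maf, gamma,
    alpha (the direct effect actually added to the outcome mean), and the
    boolean outlier flags.  This is the fast path used by calibration
    studies; :func:`simulate_pair` wraps it with rsIDs, alleles and
    positions into full summary tables.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    j = cfg.n_snps

    def draw_exposure(size):
        maf = rng.uniform(*cfg.maf_range, size=size)
        gamma = rng.normal(0.0, cfg.gamma_sd, size=size)
        se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * cfg.n_exp)
        beta = gamma + se * rng.standard_normal(size)
        return maf, gamma, se, beta

    maf, gamma, se_exp, beta_exp = draw_exposure(j)
    if cfg.ascertain:
        from scipy.stats import norm
        for _ in range(cfg.max_redraw_rounds):
            p = 2.0 * norm.sf(np.abs(beta_exp / se_exp))
            fail = p >= GWS_THRESHOLD
            if not fail.any():
                break
            m, g, s, b = draw_exposure(int(fail.sum()))
            maf[fail], gamma[fail], se_exp[fail], beta_exp[fail] = m, g, s, b
        else:
            raise AscertainmentError(
                "could not realize genome-wide-significant exposure effects; "
                "increase gamma_sd or n_exp")

    alpha = np.zeros(j)
    if cfg.pleiotropy_mode != "none" and cfg.pleio_frac > 0:
        n_pleio = int(round(cfg.pleio_frac * j))
        idx = rng.choice(j, size=n_pleio, replace=False)
        if cfg.pleiotropy_mode == "balanced":
            alpha[idx] = rng.normal(0.0, cfg.alpha_sd, size=n_pleio)
        elif cfg.pleiotropy_mode == "directional":
            draw = rng.normal(cfg.alpha_mean, cfg.alpha_sd, size=n_pleio)
            # direction is defined on the exposure-increasing allele
            alpha[idx] = np.sign(gamma[idx]) * draw
        else:  # inside_violating
            alpha[idx] = cfg.inside_c * gamma[idx] + rng.normal(0.0, cfg.alpha_sd, size=n_pleio)

    outlier = np.zeros(j, dtype=bool)
    if cfg.n_outliers:
        out_idx = rng.choice(j, size=cfg.n_outliers, replace=False)
        outlier[out_idx] = True
        alpha[out_idx] += np.sign(gamma[out_idx]) * cfg.outlier_offset

    se_out = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * cfg.n_out)
    beta_out = cfg.theta * gamma + alpha + se_out * rng.standard_normal(j)
    return {
        "maf": maf, "gamma": gamma, "alpha": alpha, "outlier": outlier,
        "beta_exp": beta_exp, "se_exp": se_exp,
        "beta_out": beta_out, "se_out": se_out,
    }


def simulate_pair(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (exposure, outcome, truth) summary tables.

    rsIDs are ``rs<j>``; SNPs are laid out cyclically over 22 autosomes at
    20 Mb spacing so that default-window LD clumping keeps them all.  A
    configurable fraction of SNPs gets palindromic (A/T or C/G) allele
    pairs so the harmonization path is exercised.  The truth table records
    gamma, the realized direct effect alpha, outlier flags, theta and the
    seed.  Same seed, same config: byte-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    eff = simulate_effects(cfg, rng)
    j = cfg.n_snps

    snp_id = np.array([f"rs{100000 + i}" for i in range(j)])
    chrom = np.array([str((i % 22) + 1) for i in range(j)])
    pos = np.array([1_000_000 + (i // 22) * 20_000_000 for i in range(j)], dtype=np.int64)
    pal = rng.random(j) < cfg.palindromic_frac
    pair_idx_p = rng.integers(0, len(_PALINDROMIC_PAIRS), size=j)
    pair_idx_n = rng.integers(0, len(_NON_PALINDROMIC_PAIRS), size=j)
    ea = np.where(pal,
                  [_PALINDROMIC_PAIRS[i][0] for i in pair_idx_p],
                  [_NON_PALINDROMIC_PAIRS[i][0] for i in pair_idx_n])
    oa = np.where(pal,
                  [_PALINDROMIC_PAIRS[i][1] for i in pair_idx_p],
                  [_NON_PALINDROMIC_PAIRS[i][1] for i in pair_idx_n])

    def table(beta, se, n):
        z = beta / se
        from scipy.stats import norm
        p = np.clip(2.0 * norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
        return pd.DataFrame({
            "snp_id": snp_id, "chrom": chrom, "pos": pos,
            "effect_allele": ea, "other_allele": oa,
            "eaf": eff["maf"], "beta": beta, "se": se,
            "pvalue": p, "n": float(n),
        }, columns=summary_io.GWAS_COLUMNS)

    exposure = table(eff["beta_exp"], eff["se_exp"], cfg.n_exp)
    outcome = table(eff["beta_out"], eff["se_out"], cfg.n_out)
    truth = pd.DataFrame({
        "snp_id": snp_id, "gamma": eff["gamma"], "alpha": eff["alpha"],
        "outlier": eff["outlier"], "theta": cfg.theta, "seed": cfg.seed,
    })
    return exposure, outcome, truth


def write_fixture(records: pd.DataFrame, path) -> None:
    """Write a summary table in the TSV layout ``read_gwas_summary`` expects."""
    summary_io.write_gwas_summary(records, path)


def block_ld_table(records: pd.DataFrame, block_kb: float = 500.0,
                   r2_within: float = 0.8) -> LdTable:
    """Block-constant pairwise r^2: same-chromosome SNPs closer than
    ``block_kb`` kilobases share ``r2_within``; everything else is absent
    (treated as 0).  A minimal stand-in for a reference-panel LD table,
    sufficient to exercise the clumping path."""
    table = LdTable()
    recs = records.reset_index(drop=True)
    for i in range(len(recs)):
        for k in range(i + 1, len(recs)):
            a, b = recs.iloc[i], recs.iloc[k]
            if a["chrom"] == b["chrom"] and abs(a["pos"] - b["pos"]) < block_kb * 1000:
                table.set(a["snp_id"], b["snp_id"], r2_within)
    return table


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["maf_range"] = list(d["maf_range"])
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "maf_range" in d:
        d["maf_range"] = tuple(d["maf_range"])
    return SimulationConfig(**d)
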