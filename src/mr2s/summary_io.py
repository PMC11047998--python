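"""Reading, validating and harmonizing GWAS summary statistics.

Two-sample Mendelian randomization starts from two per-SNP association
tables: one for the exposure (here, C-reactive protein levels) and one for
the outcome (age-related macular degeneration case/control status).  Before
any causal estimation the two tables must be expressed on the same effect
allele for every SNP; this module owns that plumbing.

Collections of SNP records travel as :class:`pandas.DataFrame` objects with
the canonical columns in :data:`GWAS_COLUMNS`; :class:`GwasRecord` is the
row schema and validator.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Canonical column order for a GWAS summary-statistics frame.
GWAS_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]

#: Canonical column order for a harmonized-instrument frame.
HARMONIZED_COLUMNS = [
    "snp_id", "beta_exp", "se_exp", "beta_out", "se_out",
    "eaf_exp", "eaf_out", "wald_ratio", "wald_se", "action_taken",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_NUCLEOTIDES = frozenset(_COMPLEMENT)

#: Actions a harmonized instrument can carry; ``dropped_*`` rows never
#: enter estimation.
ACTIONS = (
    "aligned", "flipped", "strand_flipped",
    "dropped_palindromic", "dropped_mismatch", "dropped_missing_outcome",
)


class SummaryStatsError(ValueError):
    """Malformed or unusable summary-statistics input."""


@dataclass(frozen=True)
class GwasRecord:
    """One SNP's association summary in a single GWAS.

    ``beta`` is the additive per-allele effect of ``effect_allele``
    (log-odds for a binary trait, trait units otherwise) with standard
    error ``se``; ``eaf`` is the effect-allele frequency and ``n`` the
    GWAS sample size.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: float

    def validate(self, p_rtol: float = 0.5) -> None:
        """Raise on structural violations; warn on beta/se vs p mismatch.

        The p-value is cross-checked against the two-sided normal tail of
        ``beta/se``; disagreement beyond ``p_rtol`` (on -log10 scale) is
        logged as a warning only, since published tables are often rounded.
        """
        if self.effect_allele not in _NUCLEOTIDES or self.other_allele not in _NUCLEOTIDES:
            raise SummaryStatsError(
                f"{self.snp_id}: alleles must be A/C/G/T, got "
                f"{self.effect_allele}/{self.other_allele}")
        if self.effect_allele == self.other_allele:
            raise SummaryStatsError(f"{self.snp_id}: effect and other allele identical")
        if not (self.se > 0):
            raise SummaryStatsError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0.0 <= self.eaf <= 1.0):
            raise SummaryStatsError(f"{self.snp_id}: eaf outside [0,1]: {self.eaf}")
        if not (0.0 < self.pvalue <= 1.0):
            raise SummaryStatsError(f"{self.snp_id}: pvalue outside (0,1]: {self.pvalue}")
        if not (self.n > 0):
            raise SummaryStatsError(f"{self.snp_id}: n must be > 0, got {self.n}")
        implied = pvalue_from_z(self.beta / self.se)
        if implied > 0 and self.pvalue > 0:
            la, lb = -math.log10(implied), -math.log10(self.pvalue)
            if abs(la - lb) > p_rtol * max(1.0, la):
                logger.warning(
                    "%s: supplied p=%.3g inconsistent with |beta/se| (implies %.3g)",
                    self.snp_id, self.pvalue, implied)


def pvalue_from_z(z: float | np.ndarray) -> float | np.ndarray:
    """Two-sided normal tail probability of a z score."""
    return 2.0 * stats.norm.sf(np.abs(z))


def records_to_frame(records) -> pd.DataFrame:
    """Stack :class:`GwasRecord` objects into a canonical frame."""
    return pd.DataFrame([vars(r) for r in records], columns=GWAS_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[GwasRecord]:
    return [GwasRecord(**{k: row[k] for k in GWAS_COLUMNS})
            for _, row in frame.iterrows()]


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_gwas_summary(path, column_map: dict[str, str] | None = None,
                      sep: str | None = None) -> pd.DataFrame:
    """Read a tab- or comma-delimited GWAS summary table.

    Parameters
    ----------
    path
        File path; ``.gz`` is handled transparently.
    column_map
        Mapping from canonical names (:data:`GWAS_COLUMNS`) to the file's
        header names.  Canonical names absent from the map are assumed to
        appear verbatim.  A missing ``pvalue`` column is tolerated and the
        p-value recomputed from ``beta/se``; every other column is
        mandatory.
    sep
        Field separator; sniffed from the header line when omitted.

    Returns
    -------
    pandas.DataFrame
        Accepted rows in file order with canonical columns.  Row
        acceptance/rejection counts are logged and stored in
        ``frame.attrs['n_accepted']`` / ``frame.attrs['n_rejected']``.
    """
    column_map = dict(column_map or {})
    with _open_text(path) as fh:
        header_line = fh.readline()
    if sep is None:
        sep = "\t" if header_line.count("\t") >= header_line.count(",") else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)

    missing_p = False
    rename = {}
    for canon in GWAS_COLUMNS:
        source = column_map.get(canon, canon)
        if source not in raw.columns:
            if canon == "pvalue":
                missing_p = True
                continue
            raise SummaryStatsError(f"mandatory column '{source}' (for '{canon}') not found")
        rename[source] = canon
    df = raw.rename(columns=rename)
    if missing_p:
        df["pvalue"] = np.nan
    df = df[GWAS_COLUMNS].copy()

    numeric = ["pos", "eaf", "beta", "se", "pvalue", "n"]
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper().str.strip()
    df["chrom"] = df["chrom"].astype(str).str.strip()
    df["snp_id"] = df["snp_id"].astype(str).str.strip()

    # missing p gets recomputed; a supplied p always takes precedence
    recompute = df["pvalue"].isna() & df["beta"].notna() & (df["se"] > 0)
    df.loc[recompute, "pvalue"] = pvalue_from_z(
        df.loc[recompute, "beta"] / df.loc[recompute, "se"])

    ok = (
        df[["pos", "eaf", "beta", "se", "pvalue", "n"]].notna().all(axis=1)
        & (df["se"] > 0)
        & df["eaf"].between(0.0, 1.0)
        & (df["pvalue"] > 0) & (df["pvalue"] <= 1.0)
        & (df["n"] > 0)
        & df["effect_allele"].isin(_NUCLEOTIDES)
        & df["other_allele"].isin(_NUCLEOTIDES)
        & (df["effect_allele"] != df["other_allele"])
    )
    for idx in df.index[~ok]:
        logger.info("rejected row %d (snp_id=%s): failed validation", idx, df.at[idx, "snp_id"])
    accepted = df[ok].copy()
    accepted["pos"] = accepted["pos"].astype(np.int64)
    accepted = accepted.reset_index(drop=True)
    accepted.attrs["n_accepted"] = int(ok.sum())
    accepted.attrs["n_rejected"] = int((~ok).sum())
    logger.info("read %s: %d accepted, %d rejected",
                path, accepted.attrs["n_accepted"], accepted.attrs["n_rejected"])
    return accepted


def write_gwas_summary(frame: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a canonical summary frame; numeric fields keep 6 significant digits."""
    out = frame[GWAS_COLUMNS].copy()
    for col in ("eaf", "beta", "se", "pvalue", "n"):
        out[col] = out[col].map(lambda v: f"{v:.6g}")
    out.to_csv(path, sep=sep, index=False)


def _complement(allele: str) -> str:
    return _COMPLEMENT[allele]


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T and C/G pairs cannot be strand-resolved from alleles alone."""
    return _COMPLEMENT[a1] == a2


def _ambiguous_eaf(eaf: float, limit: float) -> bool:
    # frequency inside (limit, 1-limit) is too close to 0.5 to orient
    return limit < eaf < 1.0 - limit


def wald_ratio(beta_exp: float, beta_out: float, se_out: float) -> tuple[float, float]:
    """Per-SNP causal estimate beta_out/beta_exp with first-order SE.

    The delta-method SE ``se_out/|beta_exp|`` ignores uncertainty in the
    exposure effect; adequate when the instrument is strong
    (|beta_exp|/se_exp >> 1), which the F > 10 screen enforces.
    """
    if beta_exp == 0:
        raise ZeroDivisionError("wald ratio undefined for beta_exp = 0")
    return beta_out / beta_exp, se_out / abs(beta_exp)


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              palindromic_eaf_limit: float = 0.42) -> pd.DataFrame:
    """Express outcome effects on the exposure's effect allele, SNP by SNP.

    Matching is by rsID.  Four allele configurations are reconciled:
    identical (aligned), swapped (outcome beta and eaf flipped), strand
    complement, and strand complement + swap.  Palindromic SNPs (A/T, C/G)
    are kept only when both frequencies — compared on the exposure's
    effect allele, so the outcome eaf is flipped first when its labels are
    swapped — fall on the same side of 0.5 and both lie outside the
    ambiguity zone ``(limit, 1-limit)``; otherwise they are dropped.  Dropped rows stay in the returned frame with a
    ``dropped_*`` action so the decision is auditable; they carry NaN
    Wald ratios and must be excluded from estimation (see
    :func:`estimation_subset`).

    Returns a frame with :data:`HARMONIZED_COLUMNS`, one row per exposure
    SNP found in the outcome (missing SNPs are logged and rows retained
    with ``action_taken='dropped_missing_outcome'``).
    """
    if not (0.0 < palindromic_eaf_limit < 0.5):
        raise ValueError("palindromic_eaf_limit must be in (0, 0.5)")
    out_by_id = outcome.set_index("snp_id")
    if out_by_id.index.has_duplicates:
        raise SummaryStatsError("duplicate rsIDs in outcome table")
    rows = []
    for exp in exposure.itertuples(index=False):
        if exp.snp_id not in out_by_id.index:
            logger.info("%s absent from outcome; dropped", exp.snp_id)
            rows.append(_harmonized_row(exp, None, np.nan, np.nan,
                                        "dropped_missing_outcome"))
            continue
        out = out_by_id.loc[exp.snp_id]
        ea_x, oa_x = exp.effect_allele, exp.other_allele
        ea_y, oa_y = out["effect_allele"], out["other_allele"]

        if is_palindromic(ea_x, oa_x):
            if not is_palindromic(ea_y, oa_y) or {ea_y, oa_y} != {ea_x, oa_x}:
                logger.info("%s: palindromic exposure with irreconcilable outcome "
                            "alleles %s/%s; dropped", exp.snp_id, ea_y, oa_y)
                rows.append(_harmonized_row(exp, out, np.nan, np.nan, "dropped_mismatch"))
                continue
            # compare frequencies on the exposure's effect allele: flip the
            # outcome eaf first when the labels are swapped
            swapped = (ea_y, oa_y) != (ea_x, oa_x)
            eaf_aligned = 1.0 - out["eaf"] if swapped else out["eaf"]
            same_side = (exp.eaf - 0.5) * (eaf_aligned - 0.5) > 0
            unambiguous = (not _ambiguous_eaf(exp.eaf, palindromic_eaf_limit)
                           and not _ambiguous_eaf(eaf_aligned, palindromic_eaf_limit))
            if same_side and unambiguous:
                if swapped:
                    rows.append(_harmonized_row(exp, out, -out["beta"],
                                                eaf_aligned, "flipped"))
                else:
                    rows.append(_harmonized_row(exp, out, out["beta"], out["eaf"], "aligned"))
            else:
                rows.append(_harmonized_row(exp, out, np.nan, np.nan, "dropped_palindromic"))
            continue

        if (ea_y, oa_y) == (ea_x, oa_x):
            rows.append(_harmonized_row(exp, out, out["beta"], out["eaf"], "aligned"))
        elif (ea_y, oa_y) == (oa_x, ea_x):
            rows.append(_harmonized_row(exp, out, -out["beta"], 1.0 - out["eaf"], "flipped"))
        elif (_complement(ea_y), _complement(oa_y)) == (ea_x, oa_x):
            rows.append(_harmonized_row(exp, out, out["beta"], out["eaf"], "strand_flipped"))
        elif (_complement(ea_y), _complement(oa_y)) == (oa_x, ea_x):
            rows.append(_harmonized_row(exp, out, -out["beta"],
                                        1.0 - out["eaf"], "strand_flipped"))
        else:
            logger.info("%s: alleles %s/%s vs %s/%s irreconcilable; dropped",
                        exp.snp_id, ea_x, oa_x, ea_y, oa_y)
            rows.append(_harmonized_row(exp, out, np.nan, np.nan, "dropped_mismatch"))

    harm = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    n_dropped = int(harm["action_taken"].str.startswith("dropped").sum())
    logger.info("harmonized %d SNPs: %d usable, %d dropped",
                len(harm), len(harm) - n_dropped, n_dropped)
    return harm


def _harmonized_row(exp, out, beta_out, eaf_out, action):
    dropped = action.startswith("dropped")
    if not dropped and exp.beta == 0:
        # a zero exposure effect cannot anchor a Wald ratio
        logger.info("%s: beta_exp = 0; excluded from estimation", exp.snp_id)
        action, dropped = "dropped_mismatch", True
    if dropped:
        ratio = se_ratio = np.nan
    else:
        ratio, se_ratio = wald_ratio(exp.beta, beta_out, out["se"])
    return {
        "snp_id": exp.snp_id,
        "beta_exp": exp.beta,
        "se_exp": exp.se,
        "beta_out": beta_out if not dropped else np.nan,
        "se_out": out["se"] if out is not None else np.nan,
        "eaf_exp": exp.eaf,
        "eaf_out": eaf_out if not dropped else np.nan,
        "wald_ratio": ratio,
        "wald_se": se_ratio,
        "action_taken": action,
    }


def estimation_subset(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Rows eligible for causal estimation (no ``dropped_*`` action)."""
    keep = ~harmonized["action_taken"].str.startswith("dropped")
    return harmonized[keep].reset_index(drop=True)


def write_harmonized(harmonized: pd.DataFrame, path, sep: str = "\t") -> None:
    out = harmonized[HARMONIZED_COLUMNS].copy()
    for col in HARMONIZED_COLUMNS:
        if col in ("snp_id", "action_taken"):
            continue
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6g}")
    out.to_csv(path, sep=sep, index=False)
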