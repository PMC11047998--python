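"""Instrument selection and strength: significance filter, LD clumping, F statistics.

A valid genetic instrument must associate with the exposure at genome-wide
significance (p < 5e-8 by convention) and be independent of the other
instruments, which is enforced by greedy LD clumping against a pairwise
r-squared table.  Instrument strength is summarised by the F statistic

    F = R^2 (n - 2) / (1 - R^2),

where R^2 is the proportion of exposure variance explained by the variant
and n the exposure GWAS sample size; F > 10 is the usual no-weak-instrument
rule of thumb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GWS_THRESHOLD = 5e-8
R2_CONVENTIONS = ("z_based", "variance_explained")


class NoInstrumentsError(ValueError):
    """No SNP survived the significance threshold."""


class LdTable:
    """Symmetric pairwise r-squared lookup.

    Missing pairs are treated as r^2 = 0 (unlinked) and counted, so a
    sparse table — only pairs above some floor — is a valid input.
    """

    def __init__(self, pairs: dict[tuple[str, str], float] | None = None):
        self._r2: dict[frozenset, float] = {}
        self.n_missing_queries = 0
        for (a, b), r2 in (pairs or {}).items():
            self.set(a, b, r2)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 outside [0,1]: {r2}")
        self._r2[frozenset((a, b))] = float(r2)

    def get(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = frozenset((a, b))
        if key not in self._r2:
            self.n_missing_queries += 1
            return 0.0
        return self._r2[key]

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_tsv(cls, path) -> "LdTable":
        """Read a 3-column (snp_a, snp_b, r2) table, header optional."""
        df = pd.read_csv(path, sep=None, engine="python", header=None,
                         names=["snp_a", "snp_b", "r2"], comment="#", dtype=str)
        # tolerate a header row
        if not _is_float(df.iloc[0]["r2"]):
            df = df.iloc[1:]
        table = cls()
        for row in df.itertuples(index=False):
            table.set(str(row.snp_a), str(row.snp_b), float(row.r2))
        return table

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("snp_a\tsnp_b\tr2\n")
            for key, r2 in self._r2.items():
                pair = sorted(key)
                a, b = (pair[0], pair[0]) if len(pair) == 1 else pair
                fh.write(f"{a}\t{b}\t{r2:.6g}\n")


def _is_float(s) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False


def select_significant(records: pd.DataFrame, threshold: float = GWS_THRESHOLD) -> pd.DataFrame:
    """Keep strictly the records with p < threshold, sorted by ascending p."""
    if not (0.0 < threshold < 1.0) and threshold != 1.0:
        raise ValueError(f"threshold must be in (0,1]: {threshold}")
    kept = records[records["pvalue"] < threshold]
    if kept.empty:
        raise NoInstrumentsError(f"no instruments at threshold p < {threshold:g}")
    kept = kept.sort_values("pvalue", kind="mergesort").reset_index(drop=True)
    logger.info("significance filter p < %g: %d of %d SNPs kept",
                threshold, len(kept), len(records))
    return kept


def ld_clump(records: pd.DataFrame, ld: LdTable | None = None,
             r2_max: float = 0.001, window_kb: float = 10_000) -> pd.DataFrame:
    """Greedy LD clumping: keep index SNPs by ascending p, drop linked neighbours.

    Repeatedly takes the remaining SNP with the smallest p-value as an
    index and removes every remaining SNP on the same chromosome within
    ``window_kb`` kilobases whose r^2 with the index exceeds ``r2_max``.
    Ties on p are broken by (chrom, pos) so the output never depends on
    input order.  Without an LD table every same-chromosome SNP inside the
    window is removed (distance-only pruning), with a prominent warning.

    Returns the retained index SNPs sorted by genome position.
    """
    if not (0.0 < r2_max < 1.0):
        raise ValueError("r2_max must be in (0,1)")
    if window_kb <= 0:
        raise ValueError("window_kb must be > 0")
    if ld is None:
        logger.warning("ld_clump: no LD table supplied — removing every SNP within "
                       "%g kb of an index (distance-only pruning)", window_kb)

    df = records.reset_index(drop=True).sort_values(
        ["pvalue", "chrom", "pos"], kind="mergesort")
    window_bp = window_kb * 1000.0
    alive = df.copy()
    kept_idx = []
    while not alive.empty:
        index_row = alive.iloc[0]
        kept_idx.append(alive.index[0])
        same_chrom = alive["chrom"] == index_row["chrom"]
        near = (alive["pos"] - index_row["pos"]).abs() < window_bp
        candidates = alive.index[same_chrom & near]
        if ld is None:
            to_drop = list(candidates)
        else:
            to_drop = [i for i in candidates
                       if i == alive.index[0]
                       or ld.get(index_row["snp_id"], alive.at[i, "snp_id"]) > r2_max]
        alive = alive.drop(index=to_drop)
    kept = df.loc[kept_idx].sort_values(["chrom", "pos"], kind="mergesort")
    logger.info("LD clumping (r2 <= %g, window %g kb): %d of %d SNPs retained",
                r2_max, window_kb, len(kept), len(records))
    if ld is not None and ld.n_missing_queries:
        logger.info("ld_clump: %d SNP pairs absent from the LD table were treated as r2=0",
                    ld.n_missing_queries)
    return kept.reset_index(drop=True)


def f_statistic(r2, n):
    """F = R^2 (n-2) / (1 - R^2); vectorised."""
    r2 = np.asarray(r2, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(r2 < 0) or np.any(r2 >= 1):
        raise ValueError("r2 must satisfy 0 <= r2 < 1")
    if np.any(n <= 2):
        raise ValueError("n must exceed 2")
    out = r2 * (n - 2.0) / (1.0 - r2)
    return float(out) if out.ndim == 0 else out


def snp_r2(beta, se, eaf, n, convention: str = "z_based"):
    """Per-SNP proportion of exposure variance explained.

    ``z_based``: r2 = z^2 / (n - 2 + z^2) with z = beta/se — needs no
    assumption about the trait's measurement scale and makes
    :func:`f_statistic` return exactly z^2.

    ``variance_explained``: r2 = 2 eaf (1-eaf) beta^2 — exact only when the
    trait is standardized to unit variance.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    n = np.asarray(n, dtype=float)
    if convention == "z_based":
        z2 = (beta / se) ** 2
        out = z2 / (n - 2.0 + z2)
    elif convention == "variance_explained":
        out = 2.0 * eaf * (1.0 - eaf) * beta ** 2
    else:
        raise ValueError(f"unknown convention {convention!r}; use one of {R2_CONVENTIONS}")
    return float(out) if out.ndim == 0 else out


@dataclass
class InstrumentSet:
    """Exposure-side instruments with per-SNP strength statistics.

    ``mean_f`` is the unweighted arithmetic mean of the per-SNP F values;
    ``r2_total`` their summed variance explained.  The R^2 convention used
    is recorded so downstream reports can state it.
    """

    records: pd.DataFrame
    f_stats: np.ndarray
    r2_convention: str = "z_based"
    flagged_weak: list = field(default_factory=list)

    @property
    def mean_f(self) -> float:
        return float(np.mean(self.f_stats)) if len(self.f_stats) else float("nan")

    @property
    def r2_total(self) -> float:
        r2 = snp_r2(self.records["beta"], self.records["se"],
                    self.records["eaf"], self.records["n"],
                    convention=self.r2_convention)
        return float(np.sum(r2))

    def __len__(self) -> int:
        return len(self.records)


def build_instrument_set(records: pd.DataFrame,
                         convention: str = "z_based") -> InstrumentSet:
    """Attach per-SNP F statistics to a selected/clumped instrument frame."""
    r2 = snp_r2(records["beta"].to_numpy(), records["se"].to_numpy(),
                records["eaf"].to_numpy(), records["n"].to_numpy(),
                convention=convention)
    f = f_statistic(r2, records["n"].to_numpy())
    return InstrumentSet(records=records.reset_index(drop=True),
                         f_stats=np.atleast_1d(f), r2_convention=convention)


def weak_instrument_screen(iset: InstrumentSet, f_min: float = 10.0,
                           strict: bool = False) -> tuple[InstrumentSet, dict]:
    """Flag (or with ``strict`` drop) instruments with F below ``f_min``.

    ``f_min=10`` is the conventional weak-instrument rule; a higher bar
    (e.g. 100) can be used to pick out only the strongest instruments.
    """
    weak = np.asarray(iset.f_stats) < f_min
    flagged = list(iset.records.loc[weak, "snp_id"])
    report = {
        "f_min": f_min,
        "n_flagged": int(weak.sum()),
        "flagged": flagged,
        "dropped": bool(strict) and bool(weak.any()),
    }
    if strict and weak.any():
        kept = iset.records[~weak].reset_index(drop=True)
        out = InstrumentSet(records=kept, f_stats=np.asarray(iset.f_stats)[~weak],
                            r2_convention=iset.r2_convention, flagged_weak=flagged)
    else:
        out = InstrumentSet(records=iset.records, f_stats=iset.f_stats,
                            r2_convention=iset.r2_convention, flagged_weak=flagged)
    if flagged:
        logger.warning("weak-instrument screen (F < %g): %d flagged%s",
                       f_min, len(flagged), " and dropped" if strict else "")
    return out, report


def instrument_table(iset: InstrumentSet) -> pd.DataFrame:
    """Per-SNP instrument table: rsID, locus, alleles, EAF, beta, SE, p, F."""
    tab = iset.records[["snp_id", "chrom", "pos", "effect_allele", "other_allele",
                        "eaf", "beta", "se", "pvalue", "n"]].copy()
    tab["F"] = np.asarray(iset.f_stats)
    return tab
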