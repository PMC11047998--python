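"""End-to-end run: selection -> clumping -> harmonization -> estimation -> report.

Orchestrates the library modules over files on disk and writes the four
analysis tables (instrument table, harmonized/scatter table, forest table,
diagnostics report), a JSON sidecar with PRESSO outliers and the method
verdict, the fully resolved configuration, and a run log.  Every stage is
the corresponding module function called with the same inputs — the
pipeline adds no hidden state, so any stage can be reproduced
interactively.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import instruments as instr
from . import summary_io
from .model import MRModel

logger = logging.getLogger(__name__)

DEFAULT_METHODS = ("ivw_fixed", "ivw_mre", "weighted_median", "egger", "egger_simex")


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run.

    Defaults are the conventional instrument-selection parameters:
    genome-wide significance 5e-8, LD clumping at r^2 = 0.001 within a
    10,000 kb window.
    """

    exposure_path: str = ""
    outcome_path: str = ""
    ld_path: str | None = None
    output_dir: str = "mr2s_out"
    p_threshold: float = 5e-8
    clump: bool = True
    clump_r2: float = 0.001
    clump_kb: float = 10_000
    palindromic_eaf_limit: float = 0.42
    r2_convention: str = "z_based"
    f_min: float = 10.0
    methods: tuple = DEFAULT_METHODS
    n_boot: int = 1000
    simex_n_sim: int = 1000
    presso_n_sim: int = 1000
    seed: int = 0
    exposure_column_map: dict = field(default_factory=dict)
    outcome_column_map: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "methods" in data:
            data["methods"] = tuple(data["methods"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(d["methods"])
        return d


def _setup_logging(output_dir: Path) -> None:
    root = logging.getLogger("mr2s")
    root.setLevel(logging.INFO)
    have = {getattr(h, "_mr2s_tag", None) for h in root.handlers}
    if "stderr" not in have:
        sh = logging.StreamHandler(sys.stderr)
        sh._mr2s_tag = "stderr"
        sh.setFormatter(logging.Formatter("[%(levelname)s] %(name)s: %(message)s"))
        root.addHandler(sh)
    fh = logging.FileHandler(output_dir / "run.log", mode="w")
    fh._mr2s_tag = "file"
    fh.setFormatter(logging.Formatter("%(asctime)s [%(levelname)s] %(name)s: %(message)s"))
    root.handlers = [h for h in root.handlers if getattr(h, "_mr2s_tag", None) != "file"]
    root.addHandler(fh)


def run(cfg: RunConfig):
    """Execute the full analysis; returns the fitted :class:`MRResults`.

    Writes into ``cfg.output_dir``: ``instrument_table.tsv`` (per-SNP
    instruments with F), ``harmonized.tsv`` (scatter table),
    ``forest.tsv`` (one row per estimator with OR/CI/p),
    ``diagnostics.tsv``, ``diagnostics.json`` (incl. outlier list and
    verdict), ``resolved_config.yaml`` and ``run.log``.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)

    logger.info("stage read: exposure=%s outcome=%s", cfg.exposure_path, cfg.outcome_path)
    exposure = summary_io.read_gwas_summary(cfg.exposure_path, cfg.exposure_column_map)
    outcome = summary_io.read_gwas_summary(cfg.outcome_path, cfg.outcome_column_map)
    ld = instr.LdTable.from_tsv(cfg.ld_path) if cfg.ld_path else None

    logger.info("stage select: %d exposure SNPs in", len(exposure))
    selected = instr.select_significant(exposure, cfg.p_threshold)
    if cfg.clump:
        selected = instr.ld_clump(selected, ld=ld, r2_max=cfg.clump_r2,
                                  window_kb=cfg.clump_kb)
    iset = instr.build_instrument_set(selected, convention=cfg.r2_convention)
    iset, screen = instr.weak_instrument_screen(iset, f_min=cfg.f_min)
    instr.instrument_table(iset).to_csv(outdir / "instrument_table.tsv",
                                        sep="\t", index=False)

    logger.info("stage harmonize: %d instruments in", len(selected))
    harmonized = summary_io.harmonize(iset.records, outcome,
                                      palindromic_eaf_limit=cfg.palindromic_eaf_limit)
    summary_io.write_harmonized(harmonized, outdir / "harmonized.tsv")

    model = MRModel(harmonized, instrument_set=iset)
    usable = len(model.harmonized)
    logger.info("stage estimate: %d usable instruments, methods=%s",
                usable, list(cfg.methods))
    results = model.fit(methods=cfg.methods, seed=cfg.seed, n_boot=cfg.n_boot,
                        simex_n_sim=cfg.simex_n_sim, presso_n_sim=cfg.presso_n_sim)

    results.forest_frame().to_csv(outdir / "forest.tsv", sep="\t", index=False,
                                  float_format="%.6g")
    results.diagnostics_frame().to_csv(outdir / "diagnostics.tsv", sep="\t",
                                       index=False, float_format="%.6g")
    sidecar = {
        "verdict": {"primary": results.verdict.primary,
                    "use_random_effects": results.verdict.use_random_effects,
                    "notes": results.verdict.notes},
        "presso_outliers": [str(s) for s in results.diagnostics.presso_outliers],
        "weak_instrument_screen": screen,
        "seed": cfg.seed,
        "exposure_unit_caveat": "ORs are per unit of the deposited exposure beta; "
                                "the exposure measurement unit is not standardized.",
    }
    with open(outdir / "diagnostics.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=str)
    with open(outdir / "summary.txt", "w") as fh:
        fh.write(results.summary() + "\n")
    logger.info("stage report: wrote outputs to %s", outdir)
    return results
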