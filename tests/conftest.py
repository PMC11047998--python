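import numpy as np
import pandas as pd
import pytest

from mr2s import simulate

# Published per-SNP instrument table for the CRP exposure (12 strongest
# loci with nearby genes); used as a realistic static parsing fixture.
TABLE3_TSV = """\
snp_id\tchrom\tpos\tnearby_gene\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn
rs12972970\t19\t45387596\tNECTIN2\tA\tG\t0.152\t-0.172\t0.0030\t1.00e-200\t436491
rs117310449\t19\t45393516\tTOMM40\tT\tC\t0.012\t-0.267\t0.0111\t2.74e-128\t436491
rs10420434\t19\t45451190\tAPOC4-APOC2\tA\tG\t0.047\t0.059\t0.0057\t1.65e-25\t436491
rs28929474\t14\t94844947\tSERPINA1\tT\tC\t0.020\t-0.103\t0.0085\t2.27e-33\t436491
rs1800961\t20\t43042364\tHNF4A\tT\tC\t0.027\t-0.101\t0.0066\t3.55e-52\t436491
rs1037169\t11\t13361005\tARNTL\tC\tT\t0.688\t0.029\t0.0026\t2.68e-29\t436491
rs17138478\t17\t36073320\tHNF1B\tA\tC\t0.144\t0.032\t0.0030\t2.14e-25\t436491
rs1260326\t2\t27730940\tGCKR\tC\tT\t0.575\t-0.064\t0.0022\t3.85e-187\t436491
rs1811471\t1\t159642599\tAPCS\tA\tG\t0.258\t0.110\t0.0028\t1.00e-200\t436491
rs55709272\t2\t113867288\tIL1F10-IL1RN\tC\tT\t0.364\t0.043\t0.0024\t2.27e-73\t436491
rs4133213\t1\t154395212\tIL6R\tA\tC\t0.442\t-0.076\t0.0022\t1.00e-200\t436491
rs56015600\t1\t247601886\tNLRP3\tG\tA\t0.622\t0.034\t0.0022\t4.09e-52\t436491
"""

# per-SNP F values as printed alongside the table above
TABLE3_PRINTED_F = {
    "rs12972970": 3271.84, "rs117310449": 576.43, "rs10420434": 108.60,
    "rs28929474": 145.98, "rs1800961": 231.87, "rs1037169": 127.00,
    "rs17138478": 112.36, "rs1260326": 835.74, "rs1811471": 1529.37,
    "rs55709272": 319.52, "rs4133213": 1183.99, "rs56015600": 233.26,
}


@pytest.fixture
def table3_path(tmp_path):
    p = tmp_path / "crp_instruments.tsv"
    p.write_text(TABLE3_TSV)
    return p


@pytest.fixture
def table3_frame(table3_path):
    from mr2s import read_gwas_summary
    return read_gwas_summary(table3_path)


def make_instruments(j=20, seed=0, theta=0.12, **cfg_kwargs):
    """Small random instrument quadruple as a dict of arrays."""
    cfg = simulate.SimulationConfig(n_snps=j, theta=theta, seed=seed,
                                    ascertain=False, **cfg_kwargs)
    return simulate.simulate_effects(cfg)


@pytest.fixture
def toy_instruments():
    return make_instruments(j=20, seed=42)


@pytest.fixture
def exposure_outcome_pair():
    cfg = simulate.SimulationConfig(n_snps=60, seed=11)
    return simulate.simulate_pair(cfg)


def gwas_frame(rows):
    """Build a canonical GWAS frame from (snp_id, chrom, pos, ea, oa, eaf,
    beta, se, p, n) tuples."""
    cols = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "pvalue", "n"]
    df = pd.DataFrame(rows, columns=cols)
    df["pos"] = df["pos"].astype(np.int64)
    return df
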