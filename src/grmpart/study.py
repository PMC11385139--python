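"""Parameter-recovery simulation study for the two-component models.

Each replicate draws a fresh genotype panel and a bivariate phenotype
under the two-GRM generative model, then refits:

* the single-GRM univariate model on all variants (the total-heritability
  reference),
* the two-GRM univariate model (subset GRM + complement GRM), from which
  the partitioned heritabilities derive,
* the two-GRM bivariate model, from which the subset genetic correlation
  derives.

The replicate table feeds two checks: calibration (the generating values
lie inside estimate +/- 2 SE in the vast majority of replicates) and the
decomposition identity (subset plus complement heritability from the
two-GRM fit reproduces the single-GRM heritability).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .derived import genetic_correlations, heritabilities
from .grm import Grm, compute_grm
from .reml import ModelSpec, fit_bivariate, fit_univariate
from .simulate import SimConfig, simulate_genotypes, simulate_phenotypes

#: generating values of the study: chip h2, subset h2 and subset r_g
STUDY_CONFIG = dict(
    n_individuals=1000,
    n_variants=5000,
    n_chromosomes=5,
    var_g_chip=0.30,
    var_g_subset=0.10,
    var_e=0.60,
    cov_g_chip=-0.06,
    cov_g_subset=-0.05,  # subset r_g = -0.5
    cov_e=-0.06,
    n_causal_chip=500,
    n_causal_subset=100,
)

TRUE_H2_CHIP = 0.30
TRUE_H2_SET = 0.10
TRUE_RG_SET = -0.50


def replicate_seed(base_seed: int, rep: int) -> int:
    return int((base_seed * 100_003 + 7919 * rep + 1) % (2**31 - 1))


def run_replicate(seed: int, overrides: dict | None = None) -> dict:
    """One simulate-and-refit replicate; returns the derived estimates."""
    cfg = SimConfig(**{**STUDY_CONFIG, **(overrides or {}), "seed": seed})
    geno, subsets = simulate_genotypes(cfg)
    pheno, truth = simulate_phenotypes(geno, subsets, cfg)
    set_ids = subsets[0].variant_ids
    in_set = set(set_ids)
    chip_ids = [v for v in geno.variants["variant_id"] if v not in in_set]
    g_set = compute_grm(geno, set_ids, name="set")
    g_chip = compute_grm(geno, chip_ids, name="chip")
    m_all = (len(set_ids) * g_set.matrix + len(chip_ids) * g_chip.matrix) / geno.n_variants
    g_all = Grm(m_all, geno.individual_ids, geno.n_variants, name="all")

    m1 = fit_univariate(pheno, ModelSpec([g_all]), trait=0)
    m3 = fit_univariate(pheno, ModelSpec([g_set, g_chip]), trait=0)
    m4 = fit_bivariate(pheno, ModelSpec([g_set, g_chip]))

    h1 = heritabilities(m1)["h2_all"]
    h3 = heritabilities(m3)
    rg = genetic_correlations(m4)["r_set"]
    out = {
        "seed": seed,
        "h2_m1": h1.value,
        "h2_m1_se": h1.se,
        "h2_set": h3["h2_set"].value,
        "h2_set_se": h3["h2_set"].se,
        "h2_chip": h3["h2_chip"].value,
        "h2_chip_se": h3["h2_chip"].se,
        "converged_m1": m1.converged,
        "converged_m3": m3.converged,
        "converged_m4": m4.converged,
        "realized_h2_set": truth.realized["h2_set_t1"],
        "realized_h2_chip": truth.realized["h2_50K_t1"],
        "realized_rg_set": truth.realized.get("r_g_subset_12", np.nan),
    }
    from ._util import is_defined

    if is_defined(rg):
        out["rg_set"] = rg.value
        out["rg_set_se"] = rg.se
    else:
        out["rg_set"] = np.nan
        out["rg_set_se"] = np.nan
    return out


def run_recovery_study(
    n_reps: int = 20, base_seed: int = 1, overrides: dict | None = None
) -> pd.DataFrame:
    rows = [
        run_replicate(replicate_seed(base_seed, rep), overrides) for rep in range(n_reps)
    ]
    return pd.DataFrame(rows)


def coverage(df: pd.DataFrame, estimate: str, se: str, truth: float) -> float:
    """Share of replicates whose +/- 2 SE interval covers the truth."""
    est = df[estimate].to_numpy()
    s = df[se].to_numpy()
    ok = np.abs(est - truth) <= 2 * s
    return float(np.mean(ok))
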