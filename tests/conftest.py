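import numpy as np
import pytest

import grmpart as gp


@pytest.fixture(scope="session")
def small_config():
    return gp.SimConfig(
        n_individuals=300,
        n_variants=400,
        n_chromosomes=2,
        block_length_bp=25_000,
        haplotypes_per_block=8,
        maf_floor=0.05,
        n_causal_chip=120,
        n_causal_subset=30,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    geno, subsets = gp.simulate_genotypes(small_config)
    pheno, truth = gp.simulate_phenotypes(geno, subsets, small_config)
    return geno, subsets, pheno, truth


@pytest.fixture(scope="session")
def small_grms(small_sim):
    geno, subsets, _, _ = small_sim
    in_set = set(subsets[0].variant_ids)
    chip_ids = [v for v in geno.variants["variant_id"] if v not in in_set]
    return {
        "all": gp.compute_grm(geno, name="all"),
        "set": gp.compute_grm(geno, subsets[0].variant_ids, name="set"),
        "chip": gp.compute_grm(geno, chip_ids, name="chip"),
    }


def tiny_phenotype(n, seed, grm_matrix=None, h2=0.5, n_traits=1, rg=0.5):
    """Small direct multivariate-normal phenotype draw for oracle fixtures."""
    rng = np.random.default_rng(seed)
    G = grm_matrix if grm_matrix is not None else np.eye(n)
    cov_g = h2 * G
    cov_e = (1 - h2) * np.eye(n)
    ys = []
    L_g = np.linalg.cholesky(cov_g + 1e-8 * np.eye(n))
    L_e = np.linalg.cholesky(cov_e)
    zg = rng.standard_normal((n, n_traits))
    ze = rng.standard_normal((n, n_traits))
    if n_traits == 2:
        mix = np.array([[1.0, 0.0], [rg, np.sqrt(max(1 - rg**2, 0))]])
        zg = zg @ mix.T
    ys = L_g @ zg + L_e @ ze
    ids = np.array([f"i{k}" for k in range(n)], dtype=object)
    return gp.PhenotypeTable(ids, ys), ids


def family_grm(n, fam_size=4, mix=0.5, name="g"):
    """Block-family relationship matrix: clearly separated relatedness
    levels keep small-n variance components well identified."""
    blocks = np.zeros((n, n))
    for s in range(0, n, fam_size):
        blocks[s : s + fam_size, s : s + fam_size] = 1.0
    g = (1 - mix) * np.eye(n) + mix * blocks
    ids = np.array([f"i{k}" for k in range(n)], dtype=object)
    return gp.Grm(g, ids, n_variants_used=100, name=name)


@pytest.fixture(scope="session")
def tiny_grm():
    return family_grm(20, fam_size=4)
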