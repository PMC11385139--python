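import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import grmpart as gp
from grmpart.reml import BiFit, UniFit


def make_unifit(sigma2, se=None, cov=None):
    names = list(sigma2)
    p = len(names)
    cov = cov if cov is not None else np.eye(p) * 1e-4
    se = se or {nm: float(np.sqrt(cov[i, i])) for i, nm in enumerate(names)}
    return UniFit(
        term_names=names, sigma2=dict(sigma2), se=se, sampling_cov=cov,
        loglik_trace=[0.0], converged=True,
        pinned={nm: False for nm in names}, n_records=100,
    )


def make_bifit(blocks, cov=None):
    names = list(blocks)
    p = 3 * len(names)
    cov = cov if cov is not None else np.eye(p) * 1e-4
    bl = {nm: np.array([[v1, c], [c, v2]], dtype=float) for nm, (v1, v2, c) in blocks.items()}
    se = {nm: np.full((2, 2), 1e-2) for nm in names}
    return BiFit(
        term_names=names, blocks=bl, se_blocks=se,
        param_names=[f"{nm}:{ij}" for nm in names for ij in ("11", "22", "12")],
        sampling_cov=cov, loglik_trace=[0.0], converged=True,
        pinned={nm: False for nm in names}, n_records=(100, 90),
    )


class TestHeritabilities:
    def test_symmetric_split(self):
        fit = make_unifit({"set": 1.0, "chip": 1.0, "e": 2.0})
        h = gp.heritabilities(fit)
        assert h["h2_set"].value == pytest.approx(0.25)
        assert h["h2_chip"].value == pytest.approx(0.25)

    def test_vanishing_subset_reduces_to_single_grm_formula(self):
        fit2 = make_unifit({"set": 0.0, "chip": 0.3, "e": 0.7})
        h2 = gp.heritabilities(fit2)
        fit1 = make_unifit({"chip": 0.3, "e": 0.7})
        h1 = gp.heritabilities(fit1)
        assert h2["h2_set"].value == 0.0
        assert h2["h2_chip"].value == pytest.approx(h1["h2_chip"].value)

    def test_fractions_sum_to_one_with_residual_share(self):
        fit = make_unifit({"set": 0.4, "chip": 1.1, "e": 0.9})
        h = gp.heritabilities(fit)
        total = 0.4 + 1.1 + 0.9
        assert h["h2_set"].value + h["h2_chip"].value + 0.9 / total == pytest.approx(1.0)

    def test_zero_total_variance_rejected(self):
        fit = make_unifit({"g": 0.0, "e": 0.0})
        with pytest.raises(ValueError, match="zero"):
            gp.heritabilities(fit)

    def test_delta_se_matches_parametric_bootstrap(self):
        # refit on phenotypes re-drawn from the fitted model and compare the
        # spread of h2 estimates with the delta-method SE; the fixture must
        # be large enough for the asymptotic SE to be meaningful
        from conftest import family_grm

        rng = np.random.default_rng(3)
        tiny_grm = family_grm(150, fam_size=5, mix=0.6)
        n = tiny_grm.n
        G = tiny_grm.matrix
        v_g, v_e = 0.5, 0.5
        L = np.linalg.cholesky(v_g * G + v_e * np.eye(n))
        y0 = L @ rng.standard_normal(n)
        pheno0 = gp.PhenotypeTable(tiny_grm.individual_ids, y0[:, None])
        fit0 = gp.fit_univariate(pheno0, gp.ModelSpec([tiny_grm]))
        h0 = gp.heritabilities(fit0)["h2_g"]
        Lhat = np.linalg.cholesky(
            fit0.sigma2["g"] * G + fit0.sigma2["e"] * np.eye(n) + 1e-10 * np.eye(n)
        )
        boots = []
        for _ in range(500):
            yb = Lhat @ rng.standard_normal(n)
            fb = gp.fit_univariate(
                gp.PhenotypeTable(tiny_grm.individual_ids, yb[:, None]),
                gp.ModelSpec([tiny_grm], tolerance=1e-6),
            )
            boots.append(gp.heritabilities(fb)["h2_g"].value)
        boot_se = float(np.std(boots, ddof=1))
        assert h0.se == pytest.approx(boot_se, rel=0.25)


class TestGeneticCorrelations:
    def test_zero_covariance_gives_zero(self):
        fit = make_bifit({"g": (0.5, 0.4, 0.0), "e": (0.5, 0.6, 0.1)})
        assert gp.genetic_correlations(fit)["r_g"].value == 0.0

    def test_perfect_covariance_gives_one(self):
        c = np.sqrt(0.5 * 0.4)
        fit = make_bifit({"g": (0.5, 0.4, c), "e": (0.5, 0.6, 0.0)})
        assert gp.genetic_correlations(fit)["r_g"].value == pytest.approx(1.0)

    def test_nonpositive_variance_undefined_not_raised(self):
        fit = make_bifit({"g": (0.0, 0.4, 0.1), "e": (0.5, 0.6, 0.0)})
        out = gp.genetic_correlations(fit)["r_g"]
        assert not gp.is_defined(out)
        assert "variance" in out.reason

    def test_out_of_range_estimate_clamped_and_flagged(self):
        fit = make_bifit({"g": (0.5, 0.4, 0.6), "e": (0.5, 0.6, 0.0)})
        out = gp.genetic_correlations(fit)["r_g"]
        assert out.value == 1.0
        assert out.clamped

    def test_simulation_recovery_of_negative_subset_correlation(self):
        # the M4-style generative model with subset r_g = -0.5; the mean
        # of the realized subset correlations over replicates must sit
        # near the target
        vals = []
        for seed in range(20):
            cfg = gp.SimConfig(
                n_individuals=400, n_variants=500, n_chromosomes=2, seed=seed,
                n_causal_chip=100, n_causal_subset=50,
                var_g_subset=0.1, cov_g_subset=-0.05,
            )
            geno, subsets = gp.simulate_genotypes(cfg)
            _, truth = gp.simulate_phenotypes(geno, subsets, cfg)
            vals.append(truth.realized["r_g_subset_12"])
        assert np.mean(vals) == pytest.approx(-0.5, abs=0.1)


class TestRelativeCovariances:
    def test_equal_covariances_split_evenly(self):
        fit = make_bifit({"set": (1, 1, 0.2), "chip": (1, 1, 0.2), "e": (1, 1, 0.2)})
        rc = gp.relative_covariances(fit)
        for key in ("relcov_set", "relcov_chip", "relcov_e"):
            assert rc[key].value == pytest.approx(1 / 3)

    def test_signs_preserved(self):
        fit = make_bifit({"chip": (1, 1, -1.0), "set": (1, 1, 1.0), "e": (2, 2, 2.0)})
        rc = gp.relative_covariances(fit)
        assert rc["relcov_chip"].value == pytest.approx(-0.25)
        assert rc["relcov_set"].value == pytest.approx(0.25)
        assert rc["relcov_e"].value == pytest.approx(0.5)

    def test_all_zero_covariances_undefined(self):
        fit = make_bifit({"set": (1, 1, 0.0), "chip": (1, 1, 0.0), "e": (1, 1, 0.0)})
        out = gp.relative_covariances(fit)
        assert not gp.is_defined(out)

    @given(
        st.tuples(
            st.floats(-5, 5, allow_nan=False),
            st.floats(-5, 5, allow_nan=False),
            st.floats(-5, 5, allow_nan=False),
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_absolute_values_sum_to_one(self, covs):
        c1, c2, c3 = covs
        if abs(c1) + abs(c2) + abs(c3) == 0:
            return
        fit = make_bifit({"set": (1, 1, c1), "chip": (1, 1, c2), "e": (1, 1, c3)})
        rc = gp.relative_covariances(fit)
        total = sum(abs(rc[k].value) for k in ("relcov_set", "relcov_chip", "relcov_e"))
        assert total == pytest.approx(1.0, abs=1e-12)


class TestSignificance:
    @pytest.mark.parametrize(
        "estimate,se,expected",
        [(-0.4558, 0.1070, True), (-0.0111, 0.0387, False), (0.2, 0.1, True)],
    )
    def test_two_se_rule_inclusive(self, estimate, se, expected):
        assert gp.significance_flag(estimate, se) is expected

    def test_nonpositive_se_undefined(self):
        out = gp.significance_flag(0.5, 0.0)
        assert not gp.is_defined(out)


class TestPerVariant:
    def test_chip_across_trait_value_from_printed_heritabilities(self):
        h2 = [0.4358, 0.1530, 0.0980, 0.1530, 0.1747, 0.1326, 0.0558, 0.0738, 0.0771]
        val = gp.across_trait_per_variant_h2(h2, n_variants=44_126, n_traits=9)
        assert val == pytest.approx(3.409e-6, rel=5e-4)

    def test_chip_trait_specific_rg_magnitude(self):
        val = gp.per_variant(-0.0111, 44_126)
        assert abs(val) == pytest.approx(2.516e-7, rel=5e-4)

    def test_small_subset_trait_specific_rg(self):
        val = gp.per_variant(0.6662, 3_189)
        assert val == pytest.approx(2.089e-4, rel=5e-4)

    def test_linearity_in_estimates(self):
        h2 = [0.1, 0.2, 0.3]
        v1 = gp.across_trait_per_variant_h2(h2, 100)
        v2 = gp.across_trait_per_variant_h2([2 * h for h in h2], 100)
        assert v2 == pytest.approx(2 * v1)

    def test_missing_trait_estimate_undefined(self):
        out = gp.across_trait_per_variant_h2([0.1, 0.2], n_variants=10, n_traits=3)
        assert not gp.is_defined(out)

    def test_summary_table_layout(self):
        est = pd.DataFrame(
            [
                {"subset": "s", "trait": "t1", "statistic": "h2_set", "estimate": 0.10},
                {"subset": "s", "trait": "t2", "statistic": "h2_set", "estimate": 0.30},
                {"subset": "s", "trait": "t1-t2", "statistic": "r_g_set", "estimate": -0.5},
            ]
        )
        out = gp.per_variant_summary_table(est, {"s": 100}, n_traits=2)
        across = out[out["statistic"] == "across_trait_per_variant_h2"]["value"].iloc[0]
        assert across == pytest.approx(0.4 / (2 * 100))
        rg = out[out["statistic"] == "trait_specific_per_variant_rg"]
        assert rg["value"].iloc[0] == pytest.approx(-0.005)
        assert rg["abs_value"].iloc[0] == pytest.approx(0.005)
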