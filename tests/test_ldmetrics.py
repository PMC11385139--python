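import numpy as np
import pandas as pd
import pytest

import grmpart as gp


def _geno(dosages, positions, chrom="1"):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    table = gp.make_variant_table(
        [f"v{j}" for j in range(m)], [chrom] * m, positions,
        maf=np.minimum(dosages.mean(0) / 2, 1 - dosages.mean(0) / 2),
    )
    return gp.GenotypeMatrix(
        np.array([f"i{k}" for k in range(n)], dtype=object), dosages, table
    )


@pytest.fixture(scope="module")
def chrom50():
    """One simulated 50-variant chromosome spanning ~1 Mbp."""
    cfg = gp.SimConfig(
        n_individuals=150, n_variants=50, n_chromosomes=1,
        block_length_bp=100_000, variant_spacing_bp=20_000,
        haplotypes_per_block=4, seed=17, n_causal_chip=5, n_causal_subset=2,
    )
    geno, _ = gp.simulate_genotypes(cfg)
    return geno


def brute_force_pairs(geno, subset_ids, window_bp):
    """All-pairs enumeration with explicit loops."""
    member = set(subset_ids)
    tab = geno.variants
    r = np.corrcoef(geno.dosages, rowvar=False)
    out = []
    m = len(tab)
    for a in range(m):
        if tab.variant_id[a] not in member:
            continue
        for b in range(m):
            if b == a or tab.chromosome[a] != tab.chromosome[b]:
                continue
            d = abs(int(tab.position[a]) - int(tab.position[b]))
            if d > window_bp:
                continue
            if tab.variant_id[b] in member:
                if b > a:
                    out.append((tab.variant_id[a], tab.variant_id[b], d, r[a, b] ** 2, "intern"))
            else:
                out.append((tab.variant_id[a], tab.variant_id[b], d, r[a, b] ** 2, "extern"))
    return out


class TestEnumeratePairs:
    def test_full_subset_has_no_extern_pairs_and_distribution_one(self, chrom50):
        subset = gp.SubsetDefinition("all", chrom50.variants["variant_id"].tolist())
        pairs = gp.enumerate_pairs(chrom50, subset, window_bp=500_000)
        assert (pairs["class"] == "intern").all()
        m = gp.subset_metrics(pairs, chrom50, subset)
        assert m.distribution == 1.0

    def test_singleton_subset_yields_only_extern_pairs(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, (60, 4)).astype(float)
        d[0] = 1
        geno = _geno(d, [10_000, 20_000, 30_000, 900_000])
        subset = gp.SubsetDefinition("one", ["v1"])
        pairs = gp.enumerate_pairs(geno, subset, window_bp=500_000)
        assert len(pairs) == 2  # v0 and v2; v3 is out of the window
        assert (pairs["class"] == "extern").all()

    def test_matches_brute_force_enumeration(self, chrom50):
        rng = np.random.default_rng(5)
        ids = chrom50.variants["variant_id"].to_numpy()
        subset_ids = sorted(rng.choice(ids, size=10, replace=False))
        subset = gp.SubsetDefinition("rand", list(subset_ids))
        pairs = gp.enumerate_pairs(chrom50, subset, window_bp=500_000)
        ref = brute_force_pairs(chrom50, subset_ids, 500_000)
        key = lambda t: (t[0], t[1])
        got = sorted(
            zip(pairs["variant_a"], pairs["variant_b"], pairs["distance"],
                pairs["r2"], pairs["class"]),
            key=key,
        )
        ref = sorted(ref, key=key)
        assert len(got) == len(ref)
        for g, r in zip(got, ref):
            assert g[0] == r[0] and g[1] == r[1] and g[2] == r[2] and g[4] == r[4]
            assert g[3] == pytest.approx(r[3], abs=1e-12)


def _pairframe(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos_a", "variant_a", "pos_b", "variant_b",
                       "distance", "r2", "class"]
    )


class TestSubsetMetrics:
    def test_flat_ld_gives_decay_one(self, chrom50):
        rows = [
            ("1", 0, "a", 0, f"x{k}", d, 0.4, "extern")
            for k, d in enumerate([1_000, 20_000, 130_000, 400_000])
        ]
        subset = gp.SubsetDefinition("s", [chrom50.variants.variant_id[0]])
        m = gp.subset_metrics(_pairframe(rows), chrom50, subset)
        assert m.mean_ld_extern == pytest.approx(0.4)
        assert m.decay_extern == pytest.approx(1.0)

    def test_two_stratum_decay_ratio(self, chrom50):
        rows = [("1", 0, "a", 0, "x1", 10_000, 0.8, "extern"),
                ("1", 0, "a", 0, "x2", 300_000, 0.2, "extern")]
        subset = gp.SubsetDefinition("s", [chrom50.variants.variant_id[0]])
        m = gp.subset_metrics(_pairframe(rows), chrom50, subset)
        assert m.decay_extern == pytest.approx(0.25)

    def test_middle_stratum_excluded_from_decay(self, chrom50):
        rows = [("1", 0, "a", 0, "x1", 10_000, 0.8, "extern"),
                ("1", 0, "a", 0, "x2", 60_000, 0.9, "extern"),  # neither stratum
                ("1", 0, "a", 0, "x3", 300_000, 0.4, "extern")]
        subset = gp.SubsetDefinition("s", [chrom50.variants.variant_id[0]])
        m = gp.subset_metrics(_pairframe(rows), chrom50, subset)
        assert m.decay_extern == pytest.approx(0.5)
        assert m.mean_ld_extern == pytest.approx((0.8 + 0.9 + 0.4) / 3)

    def test_empty_stratum_undefined_with_reason(self, chrom50):
        rows = [("1", 0, "a", 0, "x1", 10_000, 0.8, "extern")]
        subset = gp.SubsetDefinition("s", [chrom50.variants.variant_id[0]])
        m = gp.subset_metrics(_pairframe(rows), chrom50, subset)
        assert not gp.is_defined(m.decay_extern)
        assert "far" in m.decay_extern.reason
        assert not gp.is_defined(m.mean_ld_intern)

    def test_no_pairs_all_metrics_undefined_but_maf_defined(self, chrom50):
        subset = gp.SubsetDefinition("s", [chrom50.variants.variant_id[0]])
        m = gp.subset_metrics(_pairframe([]), chrom50, subset)
        assert not gp.is_defined(m.mean_ld_extern)
        assert np.isfinite(m.mean_maf)

    def test_clustered_subset_has_smaller_distribution_than_uniform(self, chrom50):
        ids = chrom50.variants["variant_id"].tolist()
        clustered = gp.SubsetDefinition("clu", ids[10:20])
        uniform = gp.SubsetDefinition("uni", ids[::5])
        window = 500_000
        m_clu = gp.subset_metrics(
            gp.enumerate_pairs(chrom50, clustered, window), chrom50, clustered
        )
        m_uni = gp.subset_metrics(
            gp.enumerate_pairs(chrom50, uniform, window), chrom50, uniform
        )
        assert m_uni.distribution < m_clu.distribution
        # brute-force recount of the distribution ratio
        for sub, m in ((clustered, m_clu), (uniform, m_uni)):
            ref = brute_force_pairs(chrom50, sub.variant_ids, window)
            n_int = sum(1 for r in ref if r[4] == "intern")
            assert m.distribution == pytest.approx(n_int / len(ref))

    def test_mean_maf_is_subset_mean(self, chrom50):
        ids = chrom50.variants["variant_id"].tolist()[:7]
        subset = gp.SubsetDefinition("s", ids)
        pairs = gp.enumerate_pairs(chrom50, subset, 500_000)
        m = gp.subset_metrics(pairs, chrom50, subset)
        assert m.mean_maf == pytest.approx(float(chrom50.sample_maf()[:7].mean()))


class TestCorrelateMetrics:
    def _metrics(self, **kw):
        base = dict(mean_ld_extern=0.2, mean_ld_intern=0.3, decay_extern=0.4,
                    decay_intern=0.5, distribution=0.9, mean_maf=0.25)
        base.update(kw)
        return gp.LdMetrics(**base)

    def test_perfect_linear_relation_gives_unit_correlation(self):
        metrics = {f"s{k}": self._metrics(mean_maf=0.1 + 0.05 * k) for k in range(5)}
        h2 = {f"s{k}": 1e-6 * (0.1 + 0.05 * k) for k in range(5)}
        out = gp.correlate_metrics(metrics, h2)
        row = out[out["parameter"] == "mean_maf"].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["n"] == 5

    def test_constant_parameter_undefined(self):
        metrics = {f"s{k}": self._metrics() for k in range(4)}
        h2 = {f"s{k}": 1e-6 * k for k in range(4)}
        out = gp.correlate_metrics(metrics, h2)
        row = out[out["parameter"] == "distribution"].iloc[0]
        assert np.isnan(row["r"])
        assert "variance" in row["reason"]

    def test_matches_direct_covariance_formula(self):
        rng = np.random.default_rng(8)
        names = [f"s{k}" for k in range(27)]
        vals = {nm: self._metrics(mean_ld_extern=float(rng.random())) for nm in names}
        h2 = {nm: float(rng.random() * 1e-6) for nm in names}
        out = gp.correlate_metrics(vals, h2)
        x = np.array([vals[nm].mean_ld_extern for nm in names])
        y = np.array([h2[nm] for nm in names])
        ref = float(((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        row = out[out["parameter"] == "mean_ld_extern"].iloc[0]
        assert row["r"] == pytest.approx(ref, abs=1e-12)

    def test_fewer_than_three_subsets_undefined(self):
        metrics = {"a": self._metrics(), "b": self._metrics()}
        out = gp.correlate_metrics(metrics, {"a": 1e-6, "b": 2e-6})
        assert out["reason"].str.contains("fewer").all()
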