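import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gwescan import introgression as intro
from gwescan import synthetic
from gwescan.genotypes import GenotypeMatrix, Variant


def line_table(values: dict) -> pd.DataFrame:
    lines = sorted(values)
    cols = {t: [values[l][t] for l in lines] for t in values[lines[0]]}
    return pd.DataFrame({"line": lines, **cols})


class TestTailSelection:
    def test_single_trait_exact_percentile(self):
        rng = np.random.default_rng(0)
        y = rng.permutation(100).astype(float)
        df = pd.DataFrame({"line": [f"L{i:03d}" for i in range(100)], "y": y})
        sel = intro.select_tail_lines(df, ["y"], percentile=5, min_traits=1)
        order = df.sort_values("y")["line"]
        assert sorted(sel.lower) == sorted(order.iloc[:5])
        assert sorted(sel.upper) == sorted(order.iloc[-5:])

    def test_anticorrelated_traits_empty_tails(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(200)
        df = pd.DataFrame(
            {"line": [f"L{i:03d}" for i in range(200)], "t1": a, "t2": -a}
        )
        sel = intro.select_tail_lines(df, ["t1", "t2"], min_traits=2)
        assert len(sel.lower) == 0 and len(sel.upper) == 0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "line": [f"L{i:02d}" for i in range(20)],
                "a": rng.standard_normal(20),
                "b": rng.standard_normal(20),
            }
        )
        sel = intro.select_tail_lines(df, ["a", "b"], percentile=20, min_traits=2)
        k = int(np.floor(20 * 0.2))
        lower, upper = [], []
        for line in df["line"]:
            lo = hi = 0
            for t in ("a", "b"):
                ranked = df.sort_values([t, "line"], kind="stable")["line"].tolist()
                if line in ranked[:k]:
                    lo += 1
                if line in ranked[-k:]:
                    hi += 1
            if lo >= 2:
                lower.append(line)
            if hi >= 2:
                upper.append(line)
        assert sel.lower == sorted(set(lower) - set(upper))
        assert sel.upper == sorted(set(upper) - set(lower))

    def test_min_traits_bound(self):
        df = pd.DataFrame({"line": list("abcdefghijklmnopqrst"), "y": range(20)})
        with pytest.raises(ValueError):
            intro.select_tail_lines(df, ["y"], min_traits=2)

    def test_constant_trait_rejected(self):
        df = pd.DataFrame({"line": [f"L{i}" for i in range(25)], "y": 1.0})
        with pytest.raises(ValueError, match="variance"):
            intro.select_tail_lines(df, ["y"], min_traits=1)


def ks_two_sample_oracle(x, y):
    """Hand-rolled two-sample KS statistic plus Smirnov's asymptotic p.

    D is computed from first principles; the p-value applies the one-sample
    KS distribution at the effective sample size m*n/(m+n) (Smirnov's
    approximation for the two-sample test).
    """
    x, y = np.sort(x), np.sort(y)
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / len(x)
    cdf_y = np.searchsorted(y, grid, side="right") / len(y)
    d = np.max(np.abs(cdf_x - cdf_y))
    en = len(x) * len(y) / (len(x) + len(y))
    return d, stats.kstwo.sf(d, np.round(en))


class TestFrequencySpectrum:
    def test_identical_vectors(self, rng):
        f = rng.uniform(0.05, 0.95, 100)
        spec = intro.frequency_spectrum(f, f.copy())
        assert spec.ks_d == 0.0 and spec.ks_p == 1.0
        np.testing.assert_allclose(spec.wp_proportions.sum(), 1.0)
        np.testing.assert_allclose(spec.tail_proportions.sum(), 1.0)

    def test_disjoint_supports(self, rng):
        wp = rng.uniform(0.01, 0.09, 50)
        tail = rng.uniform(0.91, 0.99, 50)
        spec = intro.frequency_spectrum(wp, tail)
        assert spec.ks_d == pytest.approx(1.0)

    def test_matches_independent_ks_oracle(self, rng):
        wp = rng.uniform(0.02, 0.98, 150)
        tail = np.clip(wp + rng.normal(0, 0.1, 150), 0.01, 0.99)
        spec = intro.frequency_spectrum(wp, tail)
        d, p = ks_two_sample_oracle(tail, wp)
        assert spec.ks_d == pytest.approx(d, abs=1e-10)
        assert spec.ks_p == pytest.approx(p, abs=1e-8)

    def test_zero_frequencies_excluded_from_bins(self):
        # zeros carry no allele: both spectra collapse to the surviving
        # values (0.5 sits in the right-closed lower bin (0, 0.5])
        wp = np.array([0.0, 0.0, 0.5, 0.5])
        tail = np.array([0.7, 0.7, 0.7, 0.7])
        spec = intro.frequency_spectrum(wp, tail, n_bins=2)
        np.testing.assert_allclose(spec.wp_proportions, [1.0, 0.0])
        np.testing.assert_allclose(spec.tail_proportions, [0.0, 1.0])

    def test_empty_tail_rejected(self):
        with pytest.raises(ValueError):
            intro.frequency_spectrum(np.array([0.5]), np.array([np.nan]))


class TestTailSpectrumTest:
    def test_random_subset_is_not_significant(self, rng):
        dosage = (rng.random((200, 300)) < 0.15) * 2.0
        ps = [
            intro.tail_spectrum_test(
                dosage, rng.choice(200, 20, replace=False), n_perm=99, rng=rng
            )[1]
            for _ in range(10)
        ]
        assert np.median(ps) > 0.1

    def test_enriched_subset_is_significant(self, rng):
        dosage = (rng.random((200, 300)) < 0.15) * 2.0
        burden = dosage.sum(axis=1)
        top = np.argsort(burden)[-20:]
        _, p = intro.tail_spectrum_test(dosage, top, n_perm=99, rng=rng)
        assert p <= 0.05

    def test_empty_tail_rejected(self, rng):
        with pytest.raises(ValueError):
            intro.tail_spectrum_test(np.zeros((10, 5)), [])


class TestFcDifferentiation:
    def test_simple_fold_change(self):
        out = intro.fc_differentiation(
            np.array([0.5]), np.array([0.2]), pseudo=1e-12
        )
        assert out["fc"].iloc[0] == pytest.approx(2.5, abs=1e-6)
        assert out["differentiated"].iloc[0]

    def test_equal_vectors_fall_back_to_adjusted_threshold(self, rng):
        f = rng.uniform(0.1, 0.9, 200)
        out = intro.fc_differentiation(f, f.copy(), n_lines=100)
        # FC == 1 everywhere; adjusted threshold keeps the top 5%
        assert out["differentiated"].sum() == pytest.approx(200, abs=11)

    def test_pseudo_count_arithmetic(self):
        out = intro.fc_differentiation(
            np.array([0.3]), np.array([0.0]), n_lines=100
        )
        assert out["fc"].iloc[0] == pytest.approx((0.3 + 0.005) / 0.005)
        assert out["differentiated"].iloc[0]

    def test_negative_frequencies_rejected(self):
        with pytest.raises(ValueError):
            intro.fc_differentiation(np.array([-0.1]), np.array([0.2]))

    def test_invariant_to_snp_order(self, rng):
        ft = rng.uniform(0, 0.5, 50)
        fw = rng.uniform(0, 0.5, 50)
        out = intro.fc_differentiation(ft, fw, n_lines=50)
        perm = rng.permutation(50)
        out_p = intro.fc_differentiation(ft[perm], fw[perm], n_lines=50)
        assert set(out[out["differentiated"]]["snp"]) == set(
            perm[out_p[out_p["differentiated"]]["snp"].to_numpy()]
        ) or np.array_equal(
            out["fc"].to_numpy()[perm], out_p["fc"].to_numpy()
        )


CHROM_TABLE = pd.DataFrame(
    [{"chrom": "1D", "length": 1_000_000, "centromere_pos": 400_000}]
)


class TestArmBinCounts:
    def snp_table(self, positions):
        return pd.DataFrame(
            {
                "snp": [f"v{i}" for i in range(len(positions))],
                "chrom": "1D",
                "pos": positions,
            }
        )

    def test_just_distal_of_centromere_is_proximal_bin(self):
        res = intro.arm_bin_counts(self.snp_table([400_001]), CHROM_TABLE, dedup_r2=None)
        assert res.totals.tolist() == [1, 0, 0]

    def test_chromosome_end_is_distal_bin(self):
        res = intro.arm_bin_counts(self.snp_table([1_000_000]), CHROM_TABLE, dedup_r2=None)
        assert res.totals.tolist() == [0, 0, 1]

    def test_matches_brute_force_interval_assignment(self, rng):
        pos = rng.integers(1, 1_000_001, size=50).tolist()
        res = intro.arm_bin_counts(self.snp_table(pos), CHROM_TABLE, dedup_r2=None)
        expected = np.zeros(3, dtype=int)
        cent, length = 400_000, 1_000_000
        for p in pos:
            if p <= cent:
                frac = (cent - p) / cent
            else:
                frac = (p - cent) / (length - cent)
            expected[min(int(frac * 3), 2)] += 1
        assert res.totals.tolist() == expected.tolist()
        assert res.totals.sum() == 50

    def test_position_beyond_end_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            intro.arm_bin_counts(self.snp_table([1_000_001]), CHROM_TABLE, dedup_r2=None)


def small_population(seed=8, n_snps=300, n_lines=200):
    cfg = synthetic.LandscapeConfig(n_snps=n_snps, seed=seed)
    _, _, G, _ = synthetic.simulate_panel(cfg)
    gmap = synthetic.uniform_genetic_map(G)
    return synthetic.simulate_introgression_population(
        G.samples[:10], ["c1"], n_lines, gmap, G=G, seed=seed
    )


class TestCaaTraitGwas:
    def test_planted_ct_qtl_recovered(self):
        pop = small_population(seed=8)
        dos = pop.marker_genotypes.dosage
        freq = dos.mean(axis=0) / 2
        j = int(np.argmax(freq))
        snp = pop.genotypes.variant_ids[j]
        synthetic.simulate_phenotypes(
            pop, qtl=[(snp, "ct", 2.0)], h2_target=0.8, n_trials=2, seed=8
        )
        res = intro.caa_trait_gwas(pop, "ct", pop.genotypes.variant_ids)
        row = res[res["snp"] == snp].iloc[0]
        assert row["q_value"] < 0.05

    def test_permuted_trait_mostly_null(self):
        pop = small_population(seed=9)
        synthetic.simulate_phenotypes(pop, qtl=[], h2_target=0.5, n_trials=2, seed=9)
        rng = np.random.default_rng(9)
        hits = 0
        n_perm = 20
        base = pop.traits.copy()
        for _ in range(n_perm):
            perm = base.copy()
            perm["ct"] = rng.permutation(perm["ct"].to_numpy())
            pop.traits = perm
            res = intro.caa_trait_gwas(pop, "ct", pop.genotypes.variant_ids)
            hits += int((res["q_value"] <= 0.05).any())
        assert hits <= max(1, int(0.05 * n_perm) + 1)

    def test_constant_trait_rejected(self):
        pop = small_population(seed=10)
        synthetic.simulate_phenotypes(pop, qtl=[], h2_target=0.5, n_trials=1, seed=10)
        pop.traits["ct"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            intro.caa_trait_gwas(pop, "ct", pop.genotypes.variant_ids)

    def test_missing_caa_rejected(self):
        pop = small_population(seed=11)
        synthetic.simulate_phenotypes(pop, qtl=[], h2_target=0.5, n_trials=1, seed=11)
        with pytest.raises(ValueError, match="absent"):
            intro.caa_trait_gwas(pop, "ct", ["not_a_snp"])


class TestCtYieldRegression:
    def test_exact_linear_relation(self):
        ct = np.linspace(20, 30, 10)
        slope, intercept, r, r2 = intro.regress_trait_on_ct(-2.0 * ct, ct)
        assert slope == pytest.approx(-2.0)
        assert r == pytest.approx(-1.0)
        assert r2 == pytest.approx(1.0)

    def test_independent_traits_uncorrelated(self):
        rng = np.random.default_rng(9)
        y = rng.standard_normal(300)
        ct = rng.standard_normal(300)
        _, _, r, _ = intro.regress_trait_on_ct(y, ct)
        assert abs(r) < 0.15

    def test_negative_genetic_correlation_recovered(self):
        pop = small_population(seed=12, n_lines=300)
        synthetic.simulate_phenotypes(
            pop, qtl=[], h2_target=0.95, n_trials=3, seed=5,
            ct_yield_genetic_corr=-0.5,
        )
        lm = pop.traits.groupby("line")[["yield", "ct"]].mean()
        _, _, r, _ = intro.regress_trait_on_ct(
            lm["yield"].to_numpy(), lm["ct"].to_numpy()
        )
        assert r == pytest.approx(-0.5, abs=0.1)

    def test_zero_ct_variance_rejected(self):
        with pytest.raises(ValueError):
            intro.regress_trait_on_ct(np.arange(5.0), np.ones(5))
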