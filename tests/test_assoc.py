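"""Association fits, FDR, direction tests, power, PRS, clumping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mtcnkit import InputError, assoc, simulate
from mtcnkit.assoc import (ReplicationPowerInput, bh_fdr, bonferroni_threshold,
                           clump_hits, effect_correlation, fit_assoc,
                           h2_explained, prs_score, replication_power,
                           run_phewas, sign_consistency_test)


class TestFitAssoc:
    def test_linear_recovery(self, rng):
        x = rng.normal(size=10000)
        y = 2.0 * x + rng.normal(size=10000)
        r = fit_assoc(y, x)
        assert abs(r.beta - 2.0) < 2 * r.se

    def test_null_p_uniform(self):
        rng = np.random.default_rng(7)
        ps = [fit_assoc(rng.normal(size=200), rng.normal(size=200)).p
              for _ in range(400)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_logistic_recovery(self, rng):
        x = rng.normal(size=8000)
        p = 1 / (1 + np.exp(-(-1.5 + 0.7 * x)))
        y = (rng.uniform(size=8000) < p).astype(float)
        r = fit_assoc(y, x, model="logistic")
        assert r.model == "logistic"
        assert abs(r.beta - 0.7) < 2.5 * r.se

    def test_constant_covariate_rank_error(self, rng):
        x = rng.normal(size=100)
        with pytest.raises(InputError, match="rank"):
            fit_assoc(rng.normal(size=100), x, covariates=np.ones((100, 1)))

    def test_min_cases_refusal(self, rng):
        y = np.zeros(100)
        y[:5] = 1
        with pytest.raises(InputError, match="cases"):
            fit_assoc(y, rng.normal(size=100), model="logistic")

    def test_separation_flagged(self):
        x = np.linspace(-2, 2, 100)
        y = (x > 0).astype(float)
        r = fit_assoc(y, x, model="logistic", min_cases=0)
        assert r.flagged and np.isnan(r.p)

    def test_missing_rows_dropped(self, rng):
        x = rng.normal(size=100)
        y = 2 * x + rng.normal(size=100)
        y[:10] = np.nan
        assert fit_assoc(y, x).n == 90


class TestBH:
    def test_step_up_enumeration(self):
        flags = bh_fdr(np.array([0.001, 0.2, 0.9]), 0.05)
        np.testing.assert_array_equal(flags, [True, False, False])

    def test_all_ones_no_discoveries(self):
        assert not bh_fdr(np.ones(5), 0.05).any()

    def test_nested_levels(self, rng):
        p = rng.uniform(size=200) ** 2
        strict = bh_fdr(p, 0.005)
        loose = bh_fdr(p, 0.05)
        assert (loose | ~strict).all()  # 0.005 discoveries subset of 0.05

    def test_empty_input(self):
        assert bh_fdr(np.array([]), 0.05).size == 0


class TestSignConsistency:
    @pytest.mark.parametrize("k,n,expected,rel", [
        (14, 14, 1.2e-4, 0.05),
        (8, 8, 0.008, 0.05),
        (713, 1158, 3.25e-15, 0.02),
    ])
    def test_printed_values(self, k, n, expected, rel):
        assert sign_consistency_test(k, n) == pytest.approx(expected, rel=rel)

    def test_matches_brute_force_enumeration(self):
        """Exact two-sided p equals direct summation of the binomial pmf over
        outcomes no more likely than the observed one (n <= 25)."""
        for n in (5, 12, 25):
            for k in range(n + 1):
                pk = stats.binom.pmf(np.arange(n + 1), n, 0.5)
                brute = pk[pk <= pk[k] * (1 + 1e-10)].sum()
                assert sign_consistency_test(k, n) == pytest.approx(brute, rel=1e-9)


class TestReplicationPower:
    def test_zero_beta_gives_alpha(self):
        inp = ReplicationPowerInput(0.0, 0.3, 1000, alpha=0.01)
        assert replication_power(inp) == pytest.approx(0.01, rel=1e-6)

    def test_monotone_in_n_and_beta(self):
        base = dict(f=0.3, sigma=0.8, alpha=1e-3)
        pw_n = [replication_power(ReplicationPowerInput(0.05, n=n, **base))
                for n in (1000, 5000, 20000)]
        assert np.all(np.diff(pw_n) > 0)
        pw_b = [replication_power(ReplicationPowerInput(b, n=5000, **base))
                for b in (0.01, 0.05, 0.1)]
        assert np.all(np.diff(pw_b) > 0)

    def test_against_monte_carlo_regression(self):
        """Analytic power within 2% of simulating the replication study:
        draw HW genotypes, y = beta*g + N(0, sigma), test at alpha."""
        rng = np.random.default_rng(11)
        beta, f, n, sigma, alpha = 0.05, 0.5, 10000, 0.8, 4.5e-4
        reps = 4000
        rej = 0
        for _ in range(reps):
            g = rng.binomial(2, f, size=n).astype(float)
            y = beta * g + rng.normal(0, sigma, size=n)
            gc = g - g.mean()
            bhat = (gc @ y) / (gc @ gc)
            resid = y - y.mean() - bhat * gc
            se = np.sqrt(resid @ resid / (n - 2) / (gc @ gc))
            if 2 * stats.t.sf(abs(bhat / se), n - 2) < alpha:
                rej += 1
        mc = rej / reps
        an = replication_power(ReplicationPowerInput(beta, f, n, sigma, alpha))
        assert abs(an - mc) < 0.02

    def test_degenerate_frequency_rejected(self):
        with pytest.raises(InputError):
            replication_power(ReplicationPowerInput(0.1, 0.0, 100))


class TestThresholdArithmetic:
    def test_printed_thresholds(self):
        assert bonferroni_threshold(110, sig_digits=2) == pytest.approx(4.5e-4)
        assert bonferroni_threshold(17821, sig_digits=3) == pytest.approx(2.81e-6)
        assert bonferroni_threshold(1) == 0.05

    def test_h2_explained_arithmetic(self):
        assert h2_explained([0.1], [0.5]) == pytest.approx(0.005)
        assert h2_explained([0.0, 0.0], [0.3, 0.4]) == 0.0

    def test_h2_explained_matches_realized_variance(self, rng):
        """On a simulated additive trait the formula tracks the realized
        genetic variance fraction."""
        m, n = 50, 20000
        f = rng.uniform(0.2, 0.8, m)
        G = rng.binomial(2, f, size=(n, m)).astype(float)
        beta = rng.normal(0, 0.05, m)
        gval = G @ beta
        y = gval + rng.normal(0, 1.0, n)
        y_sd = y.std()
        betas_scaled = beta / y_sd
        expected = gval.var() / y.var()
        assert h2_explained(betas_scaled, f) == pytest.approx(expected, rel=0.05)


class TestPRS:
    def make_geno(self, dosages):
        var = pd.DataFrame({"variant_id": ["v1"], "chrom": [1], "pos": [100],
                            "ref": ["A"], "alt": ["G"], "effect_allele": ["G"],
                            "freq": [0.5]})
        ids = np.array([f"i{k}" for k in range(len(dosages))])
        return simulate.GenotypeMatrix(ids, var, np.array(dosages, float)[:, None])

    def test_single_variant(self):
        g = self.make_geno([0, 1, 2])
        w = pd.DataFrame({"variant_id": ["v1"], "effect_allele": ["G"], "weight": [1.0]})
        np.testing.assert_allclose(prs_score(g, w), [0, 1, 2])

    def test_allele_flip_invariance(self):
        g = self.make_geno([0, 1, 2])
        w_alt = pd.DataFrame({"variant_id": ["v1"], "effect_allele": ["G"], "weight": [0.5]})
        w_ref = pd.DataFrame({"variant_id": ["v1"], "effect_allele": ["A"], "weight": [-0.5]})
        s1 = prs_score(g, w_alt)
        s2 = prs_score(g, w_ref)
        np.testing.assert_allclose(s1 - s1.mean(), s2 - s2.mean())

    def test_no_match_errors(self):
        g = self.make_geno([0, 1])
        w = pd.DataFrame({"variant_id": ["nope"], "effect_allele": ["G"], "weight": [1.0]})
        with pytest.raises(InputError, match="match"):
            prs_score(g, w)

    def test_score_correlates_with_trait_built_from_weights(self, rng):
        m, n = 40, 10000
        g = simulate.simulate_genotypes_hw(n, rng.uniform(0.1, 0.9, m), seed=8)
        wts = rng.normal(size=m)
        w = pd.DataFrame({"variant_id": g.variants["variant_id"],
                          "effect_allele": g.variants["effect_allele"],
                          "weight": wts})
        trait = g.dosages @ wts + rng.normal(0, 1, n)
        s = prs_score(g, w)
        assert np.corrcoef(s, trait)[0, 1] > 0.5


class TestClump:
    def recs(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "p"])

    def test_nearby_hits_merge(self):
        out = clump_hits(self.recs([(1, 1_000_000, 1e-6), (1, 1_500_000, 1e-4)]))
        assert len(out) == 1 and out.loc[0, "p"] == 1e-6

    def test_cross_chromosome_kept(self):
        out = clump_hits(self.recs([(1, 100, 1e-6), (2, 100, 1e-4)]))
        assert len(out) == 2

    def test_no_hits_empty(self):
        assert clump_hits(self.recs([(1, 100, 0.5)])).empty


class TestEffectCorrelation:
    def recs(self, betas, allele="G"):
        return pd.DataFrame({"predictor_id": [f"v{i}" for i in range(len(betas))],
                             "beta": betas, "effect_allele": allele})

    def test_self_correlation_one(self, rng):
        a = self.recs(rng.normal(size=10))
        r, slope = effect_correlation(a, a)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)

    def test_attenuation_with_noise(self, rng):
        b0 = rng.normal(size=4000)
        a = self.recs(b0)
        b = self.recs(b0 + rng.normal(size=4000))
        r, _ = effect_correlation(a, b)
        assert r == pytest.approx(1 / np.sqrt(2), abs=0.03)

    def test_allele_harmonization(self, rng):
        b0 = rng.normal(size=20)
        a = self.recs(b0)
        b = self.recs(-b0, allele="A")
        r, _ = effect_correlation(a, b)
        assert r == pytest.approx(1.0)

    def test_too_few_matches(self):
        with pytest.raises(InputError):
            effect_correlation(self.recs([1.0]), self.recs([1.0]))


class TestPhewas:
    def test_planted_effect_ranks_first(self, cohort):
        rng = np.random.default_rng(13)
        rl = rng.normal(size=len(cohort))
        specs = [simulate.TraitSpec(f"t{i}", "binary", prevalence=0.3)
                 for i in range(8)]
        specs[3].beta_rlrmtcn = 1.2
        counts, _ = simulate.simulate_phenotypes(cohort, rl, specs, seed=14)
        from mtcnkit import pheno
        status = pheno.assign_case_control(counts)
        out = run_phewas(rl, status, min_cases=10)
        assert out.sort_values("p").iloc[0]["trait_id"] == "t3"

    def test_deterministic(self, cohort, rng):
        rl = rng.normal(size=len(cohort))
        labs = pd.DataFrame({"l1": rng.normal(size=len(cohort)),
                             "l2": rng.normal(size=len(cohort))})
        a = run_phewas(rl, labs=labs)
        b = run_phewas(rl, labs=labs)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_phenome_rejected(self, rng):
        with pytest.raises(Exception, match="empty"):
            run_phewas(rng.normal(size=10))
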