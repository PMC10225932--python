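"""Generator properties: determinism, configured frequencies, tract structure,
effect recovery."""

import numpy as np
import pandas as pd
import pytest

from mtcnkit import ConfigError, simulate
from mtcnkit.simulate import (CopyNumberEffects, CoverageConfig, SimulationConfig,
                              TraitSpec)


def test_same_seed_identical_cohorts():
    cfg = SimulationConfig(n_individuals=200, seed=5)
    a = simulate.simulate_cohort(cfg)
    b = simulate.simulate_cohort(cfg)
    pd.testing.assert_frame_equal(a, b)


def test_different_seed_differs():
    a = simulate.simulate_cohort(SimulationConfig(n_individuals=200, seed=5))
    b = simulate.simulate_cohort(SimulationConfig(n_individuals=200, seed=6))
    assert not a["age"].equals(b["age"])


def test_haplogroup_lineage_frequency():
    """African-lineage fraction matches the configured 0.8 within 3 SE."""
    n = 10_000
    cfg = SimulationConfig(n_individuals=n, seed=2, other_haplogroup_fraction=0.0)
    c = simulate.simulate_cohort(cfg)
    frac = (c["mt_origin"] == "African").mean()
    se = np.sqrt(0.8 * 0.2 / n)
    assert abs(frac - 0.8) < 3 * se


def test_duffy_fixed_allele():
    cfg = SimulationConfig(n_individuals=300, seed=3,
                           ancestry_distribution=(0.999, 0.005),
                           duffy_freq_by_ancestry=(1.0, 0.0))
    c = simulate.simulate_cohort(cfg)
    # ancestry is essentially 1 for everyone -> all genotypes homozygous null
    assert (c["duffy_genotype"] == 2).mean() > 0.99


def test_invalid_config_names_field():
    with pytest.raises(ConfigError, match="haplogroup_freq_african"):
        simulate.simulate_cohort(SimulationConfig(haplogroup_freq_african=1.5))
    with pytest.raises(ConfigError, match="n_individuals"):
        simulate.simulate_cohort(SimulationConfig(n_individuals=1))


class TestLocalAncestry:
    def test_no_recombination_constant_tracts(self, cohort, marker_map):
        cfg = SimulationConfig(n_individuals=len(cohort), seed=1,
                               generations_since_admixture=0.0)
        la = simulate.simulate_local_ancestry(cohort, marker_map, cfg, seed=9)
        for hap in (la.hap0, la.hap1):
            for _, grp in la.markers.groupby("chrom"):
                block = hap[:, grp.index]
                assert (block == block[:, [0]]).all()

    def test_all_african_ancestry_counts_two(self, marker_map):
        cfg = SimulationConfig(n_individuals=50, seed=4,
                               ancestry_distribution=(0.999, 0.005))
        c = simulate.simulate_cohort(cfg)
        c["african_ancestry"] = 1.0
        la = simulate.simulate_local_ancestry(c, marker_map, cfg, seed=10)
        assert (la.counts == 2).all()

    def test_haplotypes_sum_to_count(self, local_ancestry):
        assert set(np.unique(local_ancestry.hap0)) <= {0, 1}
        np.testing.assert_array_equal(local_ancestry.counts,
                                      local_ancestry.hap0 + local_ancestry.hap1)

    def test_mean_local_ancestry_tracks_global(self):
        """Mean local ancestry converges on the ancestry fraction at the
        closed-form tract-sampling rate.

        For a stationary two-state chain with autocovariance
        a(1-a)exp(-g*s), the variance of the mean over L Morgans is about
        2a(1-a)/(gL) per haplotype; the diploid 3-Morgan genome at g=8
        averages 6 chromosome-haplotypes, and mean |error| is sd*sqrt(2/pi).
        """
        cfg = SimulationConfig(n_individuals=300, seed=8,
                               generations_since_admixture=8.0)
        c = simulate.simulate_cohort(cfg)
        mm = simulate.uniform_marker_map(3, 400, morgans_per_chromosome=1.0)
        la = simulate.simulate_local_ancestry(c, mm, cfg, seed=12)
        mean_local = la.counts.mean(axis=1) / 2.0
        a = c["african_ancestry"].to_numpy()
        err = np.abs(mean_local - a)
        var_pred = np.mean(2 * a * (1 - a) / 8.0) / 6.0
        expected_abs = np.sqrt(var_pred * 2 / np.pi)
        assert abs(err.mean() - expected_abs) < 0.3 * expected_abs
        # population-level: no systematic bias
        assert abs((mean_local - a).mean()) < 0.01

    def test_unsorted_map_rejected(self, cohort):
        bad = pd.DataFrame({"chrom": [1, 1], "pos": [10, 20], "gpos": [0.5, 0.1]})
        with pytest.raises(Exception, match="decrease"):
            simulate.simulate_local_ancestry(cohort, bad,
                                             SimulationConfig(seed=1), seed=1)


class TestGenotypes:
    def test_fixed_differentiated_allele(self, local_ancestry):
        freqs = np.column_stack([np.ones(local_ancestry.n_markers),
                                 np.zeros(local_ancestry.n_markers)])
        g = simulate.simulate_genotypes(local_ancestry, freqs, seed=3)
        np.testing.assert_array_equal(g.dosages, local_ancestry.counts.astype(float))

    def test_equal_freqs_independent_of_ancestry(self, local_ancestry):
        """With equal allele frequencies on both backgrounds, dosage carries
        no ancestry information (chi-square independence)."""
        from scipy.stats import chi2_contingency
        m = local_ancestry.n_markers
        freqs = np.full((m, 2), 0.5)
        g = simulate.simulate_genotypes(local_ancestry, freqs, seed=7)
        pvals = []
        for j in range(0, m, 8):
            tab = pd.crosstab(local_ancestry.counts[:, j], g.dosages[:, j])
            if tab.shape[0] > 1 and tab.shape[1] > 1:
                pvals.append(chi2_contingency(tab)[1])
        # null p-values: roughly uniform, not enriched near 0
        assert np.mean(np.array(pvals) < 0.05) < 0.25

    def test_realized_frequency_weighted_mean(self):
        """f_realized ~ mean_ancestry * f_afr + (1 - mean_ancestry) * f_eur."""
        cfg = SimulationConfig(n_individuals=8000, seed=6)
        c = simulate.simulate_cohort(cfg)
        mm = simulate.uniform_marker_map(1, 30)
        la = simulate.simulate_local_ancestry(c, mm, cfg, seed=13)
        freqs = np.column_stack([np.full(30, 0.9), np.full(30, 0.1)])
        g = simulate.simulate_genotypes(la, freqs, seed=14)
        abar = la.counts.mean() / 2.0
        expected = abar * 0.9 + (1 - abar) * 0.1
        realized = g.dosages.mean() / 2.0
        se = np.sqrt(expected * (1 - expected) / (2 * 8000))
        assert abs(realized - expected) < 3 * se + 0.01

    def test_shape_mismatch_rejected(self, local_ancestry):
        with pytest.raises(Exception, match="shape"):
            simulate.simulate_genotypes(local_ancestry, np.full((3, 2), 0.5))


class TestCopyNumber:
    def test_zero_effects_noise_sd(self, cohort):
        eff = CopyNumberEffects(sex=0, age=0, age2=0,
                                blood={c: (0.0, 0.0) for c in
                                       simulate.BLOOD_COUNT_COLUMNS},
                                noise_sd=1.0)
        lr = simulate.simulate_copy_number(cohort, eff, seed=5)
        se = 1.0 / np.sqrt(2 * (len(cohort) - 1))
        assert abs(lr.std() - 1.0) < 3 * se

    def test_neutrophil_negative_by_default(self):
        c = simulate.simulate_cohort(SimulationConfig(n_individuals=5000, seed=9))
        lr = simulate.simulate_copy_number(c, seed=10)
        assert np.corrcoef(lr, c["neutrophils"])[0, 1] < 0
        assert np.corrcoef(lr, c["platelets"])[0, 1] > 0

    def test_h2_target_validation(self, cohort):
        with pytest.raises(ConfigError, match="h2_target"):
            simulate.simulate_copy_number(cohort, h2_target=1.2)

    def test_variance_decomposition(self, cohort):
        g = simulate.simulate_genotypes_hw(len(cohort),
                                           np.random.default_rng(0).uniform(0.1, 0.9, 500),
                                           seed=15)
        lr, comp = simulate.simulate_copy_number(cohort, h2_target=0.4, genotypes=g,
                                                 seed=16, return_components=True)
        frac = comp["genetic"].var() / (comp["genetic"].var() + comp["noise"].var())
        assert abs(frac - 0.4) < 0.05


class TestDepth:
    def test_depth_means_match(self):
        profiles = simulate.simulate_depth(
            np.zeros(20), CoverageConfig(spike_multiplier=1.0, n_sites=4000), seed=1)
        mt = np.mean([p.mt_depths.mean() for p in profiles])
        auto = np.mean([p.auto_depths.mean() for p in profiles])
        se = np.sqrt(2.8 / (20 * 4000))
        assert abs(mt - auto) < 3 * np.sqrt(2) * se

    def test_doubled_copy_number_doubles_depth(self):
        profiles = simulate.simulate_depth(
            np.full(30, np.log(2)), CoverageConfig(spike_multiplier=1.0), seed=2)
        mt = np.mean([p.mt_depths.mean() for p in profiles])
        assert abs(mt - 5.6) < 0.05

    def test_spike_inflates_unmasked_mean(self):
        from mtcnkit import copynumber
        profiles = simulate.simulate_depth(
            np.zeros(30), CoverageConfig(spike_multiplier=10.0), seed=3)
        masked = np.mean([copynumber.estimate_rmtcn(
            copynumber.mask_spike(p)).rmtcn for p in profiles])
        unmasked = np.mean([copynumber.estimate_rmtcn(p).rmtcn for p in profiles])
        assert unmasked > masked
        assert abs(masked - 1.0) < 0.02  # unbiased after masking
        expected_bias = (501 * 9) / 16569
        assert abs(unmasked - 1.0 - expected_bias) < 0.02

    def test_nonpositive_coverage_rejected(self):
        with pytest.raises(ConfigError):
            simulate.simulate_depth(np.zeros(2),
                                    CoverageConfig(autosomal_mean_depth=0.0))


class TestPhenotypes:
    def test_null_prevalence(self, cohort):
        specs = [TraitSpec("t0", "binary", prevalence=0.1, singleton_rate=0.0)]
        big = simulate.simulate_cohort(SimulationConfig(n_individuals=20000, seed=17))
        counts, _ = simulate.simulate_phenotypes(big, np.zeros(len(big)), specs, seed=18)
        frac = (counts["t0"] >= 2).mean()
        se = np.sqrt(0.1 * 0.9 / len(big))
        assert abs(frac - 0.1) < 3 * se

    def test_copy_number_effect_recovered(self):
        """A log(2) per-SD copy-number effect is recovered by logistic
        regression within 2 SE."""
        import statsmodels.api as sm
        c = simulate.simulate_cohort(SimulationConfig(n_individuals=12000, seed=19))
        rl = np.random.default_rng(20).normal(size=len(c))
        specs = [TraitSpec("t", "binary", prevalence=0.2,
                           beta_rlrmtcn=np.log(2), singleton_rate=0.0)]
        counts, _ = simulate.simulate_phenotypes(c, rl, specs, seed=21)
        y = (counts["t"] >= 2).to_numpy(dtype=float)
        x = (rl - rl.mean()) / rl.std()
        res = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert abs(res.params[1] - np.log(2)) < 2 * res.bse[1]

    def test_singleton_fraction(self, cohort):
        specs = [TraitSpec("t", "binary", prevalence=0.05, singleton_rate=0.10)]
        counts, _ = simulate.simulate_phenotypes(cohort, np.zeros(len(cohort)),
                                                 specs, seed=22)
        singles = (counts["t"] == 1).mean()
        assert 0.04 < singles < 0.18

    def test_unknown_kind_rejected(self, cohort):
        with pytest.raises(ConfigError, match="kind"):
            simulate.simulate_phenotypes(cohort, np.zeros(len(cohort)),
                                         [TraitSpec("t", "ordinal")], seed=1)
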