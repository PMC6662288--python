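"""Simulator contracts: spectrum shape, HWE draws, read model, caller, channels."""

import numpy as np
import pandas as pd
import pytest

import lowpass_eval as le
from lowpass_eval.cohort import PileupSummary

from conftest import make_gm


class TestAlleleFrequencySpectrum:
    def test_deterministic_under_seed(self):
        cfg = le.CohortConfig(n_samples=100, n_sites=500, seed=3)
        assert np.array_equal(
            le.sample_allele_frequencies(cfg), le.sample_allele_frequencies(cfg)
        )

    def test_rare_skewed_spectrum(self):
        cfg = le.CohortConfig(n_samples=1000, n_sites=100_000, seed=5)
        afs = le.sample_allele_frequencies(cfg)
        assert afs.min() > 0 and afs.max() <= 0.5
        frac_rare = (afs < 0.01).mean()
        frac_common = (afs > 0.05).mean()
        assert frac_rare > frac_common

    def test_point_mass_spectrum(self):
        cfg = le.CohortConfig(n_samples=10, n_sites=50, point_mass=0.25, seed=0)
        assert np.all(le.sample_allele_frequencies(cfg) == 0.25)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_samples": 1, "n_sites": 10},
            {"n_samples": 10, "n_sites": 0},
            {"n_samples": 10, "n_sites": 10, "afs_shape": (0.0, 4.0)},
            {"n_samples": 10, "n_sites": 10, "family_blocks": [(2, 0.7)]},
            {"n_samples": 10, "n_sites": 10, "family_blocks": [(20, 0.5)]},
        ],
    )
    def test_invalid_configs_raise(self, kwargs):
        with pytest.raises(ValueError):
            le.CohortConfig(**kwargs)


class TestGenotypeSimulation:
    def test_het_fraction_at_half_frequency(self):
        # at f = 0.5 under HWE the heterozygote fraction is 2f(1-f) = 0.5
        cfg = le.CohortConfig(n_samples=10_000, n_sites=5, point_mass=0.5, seed=2)
        gm = le.simulate_genotypes(le.sample_allele_frequencies(cfg), cfg)
        het = (gm.dosages == 1).mean()
        sd = np.sqrt(0.25 / gm.dosages.size)
        assert abs(het - 0.5) < 3 * sd

    def test_vanishing_frequency_gives_all_ref(self):
        cfg = le.CohortConfig(n_samples=100, n_sites=20, seed=1)
        gm = le.simulate_genotypes(np.full(20, 1e-9), cfg)
        assert np.all(gm.dosages == 0)

    def test_truth_has_no_missingness(self, small_study):
        assert (small_study.truth.dosages >= 0).all()

    def test_family_block_genotype_correlation(self):
        # relatedness 0.5 block of two -> dosage correlation ~ 0.5 across sites
        # flat spectrum so the pooled correlation is not inflated by
        # between-site mean-dosage variance
        cfg = le.CohortConfig(
            n_samples=200, n_sites=50_000, seed=8, family_blocks=[(2, 0.5)],
            point_mass=0.25,
        )
        gm = le.simulate_genotypes(le.sample_allele_frequencies(cfg), cfg)
        a, b = gm.dosages[0].astype(float), gm.dosages[1].astype(float)
        r = np.corrcoef(a, b)[0, 1]
        assert abs(r - 0.5) < 0.05
        # unrelated pair stays uncorrelated
        c, d = gm.dosages[100].astype(float), gm.dosages[101].astype(float)
        assert abs(np.corrcoef(c, d)[0, 1]) < 0.05

    def test_duplicate_pair_exceeds_close_relative_threshold(self):
        # the pi-hat > 0.1 rule used for close-relative detection
        cfg = le.CohortConfig(
            n_samples=100, n_sites=5000, seed=13, family_blocks=[(2, 0.5)]
        )
        gm = le.simulate_genotypes(le.sample_allele_frequencies(cfg), cfg)
        K = le.centered_grm(gm, le.select_grm_variants(gm, prune_r2=1.0))
        assert K.pi_hat()[0, 1] > 0.1
        assert K.close_relative_counts()[0] >= 1


class TestReadSimulation:
    def test_zero_depth_zero_reads(self, small_study):
        params = le.SequencingParams(mean_depth=0.0, seed=0)
        pile = le.simulate_reads(small_study.truth, params)
        assert (pile.ref_reads == 0).all() and (pile.alt_reads == 0).all()

    def test_poisson_zero_fraction_and_moments(self):
        cfg = le.CohortConfig(n_samples=1000, n_sites=1000, point_mass=0.25, seed=4)
        truth = le.simulate_genotypes(le.sample_allele_frequencies(cfg), cfg)
        pile = le.simulate_reads(truth, le.SequencingParams(mean_depth=1.0, seed=1))
        total = pile.ref_reads + pile.alt_reads
        frac0 = (total == 0).mean()
        sd = np.sqrt(np.exp(-1) * (1 - np.exp(-1)) / total.size)
        assert abs(frac0 - np.exp(-1)) < 4 * sd
        assert abs(total.mean() - 1.0) < 0.01
        assert abs(total.var() - 1.0) < 0.02

    def test_homref_error_free_has_no_alt_reads(self):
        gm = make_gm(np.zeros((50, 20)))
        pile = le.simulate_reads(gm, le.SequencingParams(mean_depth=30, error_rate=0.0))
        assert (pile.alt_reads == 0).all()

    def test_negative_counts_rejected(self, toy_sites):
        with pytest.raises(ValueError):
            PileupSummary(
                ref_reads=np.array([[-1]]), alt_reads=np.array([[0]]),
                sites=toy_sites.iloc[:1], samples=["S0"],
            )


class TestGenotypeCaller:
    def test_zero_reads_is_missing_and_single_alt_read_calls_homalt(self):
        # likelihoods at (ref=0, alt=1), eps=0.01: (0.01, 0.5, 0.99) -> dosage 2
        sites = pd.DataFrame(
            {"chrom": ["1", "1"], "pos": [100, 200], "ref": ["A", "A"], "alt": ["G", "G"]}
        )
        pile = PileupSummary(
            ref_reads=np.array([[0, 0], [5, 0]], np.int32),
            alt_reads=np.array([[1, 0], [5, 0]], np.int32),
            sites=sites,
            samples=["S0", "S1"],
        )
        params = le.SequencingParams(mean_depth=1, error_rate=0.01)
        gm = le.call_from_pileup(pile, params)
        # site 2 had no reads anywhere -> no alt evidence -> dropped
        assert gm.n_sites == 1
        assert gm.dosages[0, 0] == 2
        assert gm.dosages[1, 0] == 1  # 5/5 split -> het

    def test_balanced_reads_call_het_and_hom_likelihoods_tie(self):
        # ref=1/alt=1 reads: L(0) = L(2) = eps(1-eps) < L(1) = 1/4 -> het call;
        # the hom-ref/hom-alt tie sits below the max and cannot flip the call
        ll = le.cohort.genotype_log_likelihoods(
            np.array([[1]]), np.array([[1]]), 0.01
        )[0, 0]
        assert ll[0] == pytest.approx(ll[2])
        assert ll[1] > ll[0]

    def test_high_depth_calls_are_accurate(self):
        cfg = le.CohortConfig(n_samples=100, n_sites=100, point_mass=0.3, seed=6)
        truth = le.simulate_genotypes(le.sample_allele_frequencies(cfg), cfg)
        params = le.SequencingParams(mean_depth=30, error_rate=0.01, seed=2)
        calls = le.call_from_pileup(le.simulate_reads(truth, params), params)
        m = le.match_sites(calls.sites, truth.sites)
        tr = truth.take_sites(m.matched["idx_b"].to_numpy())
        called = calls.dosages >= 0
        err = (calls.dosages != tr.dosages)[called].mean()
        assert err < 0.01

    def test_monomorphic_ref_sites_dropped(self):
        gm = make_gm(np.zeros((20, 5)))
        params = le.SequencingParams(mean_depth=20, error_rate=0.0, seed=3)
        calls = le.call_from_pileup(le.simulate_reads(gm, params), params)
        assert calls.n_sites == 0


class TestImputationChannel:
    def test_perfect_accuracy_reproduces_truth(self, small_study):
        chan = le.ImputationChannel(accuracy=(1.0, 1.0, 1.0), fill_rate=(1, 1, 1))
        calls = small_study.raw_calls.restrict_to(small_study.truth.sites)
        out = le.apply_imputation_channel(calls, small_study.truth, chan, seed=1)
        assert out.n_sites == small_study.truth.n_sites
        assert np.array_equal(out.dosages, small_study.truth.dosages)

    def test_zero_accuracy_never_matches_truth(self, small_study):
        chan = le.ImputationChannel(accuracy=(0.0, 0.0, 0.0), fill_rate=(1, 1, 1))
        calls = small_study.raw_calls.restrict_to(small_study.truth.sites)
        out = le.apply_imputation_channel(calls, small_study.truth, chan, seed=1)
        assert not (out.dosages == small_study.truth.dosages).any()

    def test_false_positive_sites_not_imputable(self, small_study):
        chan = le.ImputationChannel()
        with pytest.raises(ValueError, match="outside the truth universe"):
            le.apply_imputation_channel(
                small_study.raw_calls, small_study.truth, chan, seed=1
            )

    def test_accuracy_calibration(self):
        # bin accuracy 0.97 -> measured cell-level concordance ~ 0.97
        cfg = le.CohortConfig(n_samples=500, n_sites=400, point_mass=0.2, seed=9)
        truth = le.simulate_genotypes(le.sample_allele_frequencies(cfg), cfg)
        chan = le.ImputationChannel(accuracy=(0.97, 0.97, 0.97), fill_rate=(1, 1, 1))
        out = le.apply_imputation_channel(truth, truth, chan, seed=5)
        conc = (out.dosages == truth.dosages).mean()
        sd = np.sqrt(0.97 * 0.03 / truth.dosages.size)
        assert abs(conc - 0.97) < 3 * sd

    def test_output_call_rate_is_complete(self, small_study):
        assert (small_study.imputed.dosages >= 0).all()

    def test_bad_channel_configs(self):
        with pytest.raises(ValueError):
            le.ImputationChannel(accuracy=(0.9,), fill_rate=(1, 1, 1))
        with pytest.raises(ValueError):
            le.ImputationChannel(bin_edges=(0.0, 0.05), accuracy=(1.1,), fill_rate=(1,))


class TestChipSubset:
    def test_insufficient_common_sites_raise(self):
        gm = make_gm(np.vstack([np.ones((1, 10)), np.zeros((99, 10))]))  # all rare
        with pytest.raises(ValueError):
            le.make_chip_subset(gm, 5, maf_floor=0.05)

    def test_error_free_chip_matches_truth(self, small_study):
        chip, truth = small_study.chip, small_study.truth
        m = le.match_sites(chip.sites, truth.sites)
        assert m.n_matched == chip.n_sites
        tr = truth.take_sites(m.matched["idx_b"].to_numpy())
        assert np.array_equal(chip.dosages, tr.dosages)

    def test_selected_sites_respect_maf_floor(self, small_study):
        assert (small_study.chip.mafs() >= 0.05).all()


class TestPhenotypeSimulation:
    def test_deterministic_under_seed(self, small_study):
        t = le.TraitConfig(causal_sites=[0], effect_sizes=[0.3], seed=7)
        y1 = le.simulate_phenotypes(small_study.truth, t)
        y2 = le.simulate_phenotypes(small_study.truth, t)
        assert np.array_equal(y1, y2)

    def test_unit_variance_in_expectation(self, small_study):
        t = le.TraitConfig(causal_sites=[0], effect_sizes=[0.4], seed=2)
        y = le.simulate_phenotypes(small_study.truth, t)
        assert abs(y.var() - 1.0) < 0.2

    def test_variance_budget_enforced(self):
        with pytest.raises(ValueError):
            le.TraitConfig(causal_sites=[0], effect_sizes=[1.5])

    def test_strong_effect_is_detectable(self):
        # 20% variance at n=1000 -> P < 5e-7 in the majority of replicates
        cfg = le.CohortConfig(n_samples=1000, n_sites=200, point_mass=0.3, seed=21)
        truth = le.simulate_genotypes(le.sample_allele_frequencies(cfg), cfg)
        hits = 0
        for rep in range(5):
            t = le.TraitConfig(causal_sites=[10], effect_sizes=[np.sqrt(0.2)],
                               seed=100 + rep)
            y = le.simulate_phenotypes(truth, t)
            fit = le.MixedModel(y, np.eye(1000)).fit()
            p = fit.score_test(truth.dosages[:, 10])["p_score"].iloc[0]
            hits += p < 5e-7
        assert hits >= 3


def test_study_reproducible_end_to_end():
    cfg = le.CohortConfig(n_samples=60, n_sites=300, seed=17)
    a = le.simulate_study(cfg)
    b = le.simulate_study(cfg)
    for x, y in [(a.truth, b.truth), (a.raw_calls, b.raw_calls),
                 (a.imputed, b.imputed), (a.chip, b.chip)]:
        assert np.array_equal(x.dosages, y.dosages)
        assert x.sites[["chrom", "pos"]].equals(y.sites[["chrom", "pos"]])


def test_low_depth_capture_monotone_in_maf(small_study):
    """At 1x, raw calls miss far more singletons than common sites."""
    m = le.match_sites(small_study.raw_calls.sites, small_study.truth.sites)
    sens = le.capture_rate(m, small_study.truth).set_index("bin")["sensitivity"]
    assert sens[le.compare.SINGLETON_DOUBLETON] < sens[le.compare.COMMON]
    vals = sens.reindex(list(le.compare.DEFAULT_BINS)).dropna().to_numpy()
    assert np.all(np.diff(vals) >= -0.02)  # monotone capture up to noise
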