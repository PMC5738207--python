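"""Parentage likelihoods and the pedigree Gibbs sampler."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from scipy.stats import kstest

from helpers import brute_force_posterior
from wolfped.error_model import ErrorRates, observation_distribution
from wolfped.genodata import AlleleFrequencyTable
from wolfped.pedigree_core import UNSAMPLED, Pedigree, is_legal
from wolfped.pedigree_mcmc import (
    MCMCSettings,
    PosteriorPedigree,
    Priors,
    build_candidates,
    exclusion_filter,
    mendelian_transmission,
    modal_pedigree,
    parent_pair_likelihood,
    sample_error_rates,
    sample_pedigree,
)


class TestMendelianTransmission:
    def test_fixed_homozygote_cross(self, small_freqs):
        assert mendelian_transmission(("A", "A"), ("A", "A"), ("A", "A"), "l1", small_freqs) == 1.0

    def test_het_cross_punnett(self, small_freqs):
        expected = {("A", "A"): 0.25, ("A", "B"): 0.5, ("B", "B"): 0.25}
        for off, p in expected.items():
            assert mendelian_transmission(off, ("A", "B"), ("A", "B"), "l1", small_freqs) == pytest.approx(p)

    def test_unsampled_sire_draws_from_frequencies(self, small_freqs):
        # dam AA, sire unsampled, p_B = 0.3 at l2
        assert mendelian_transmission(("A", "B"), ("A", "A"), None, "l2", small_freqs) == pytest.approx(0.3)

    def test_both_unsampled_is_hardy_weinberg(self, small_freqs):
        assert mendelian_transmission(("A", "B"), None, None, "l1", small_freqs) == pytest.approx(
            2 * 0.4 * 0.6
        )


class TestParentPairLikelihood:
    def test_zero_error_equals_mendelian_product(self, small_freqs, zero_rates):
        off = {"l1": ("A", "B"), "l2": ("A", "C"), "l3": ("B", "D")}
        dam = {"l1": ("A", "A"), "l2": ("A", "B"), "l3": ("B", "C")}
        sire = {"l1": ("B", "B"), "l2": ("C", "C"), "l3": ("A", "D")}
        ll = parent_pair_likelihood(off, dam, sire, small_freqs, zero_rates)
        expected = sum(
            math.log(mendelian_transmission(off[l], dam[l], sire[l], l, small_freqs))
            for l in off
        )
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_zero_error_mendelian_exclusion(self, small_freqs, zero_rates):
        off = {"l1": ("A", "A")}
        dam = {"l1": ("B", "B")}
        sire = {"l1": ("A", "B")}
        assert parent_pair_likelihood(off, dam, sire, small_freqs, zero_rates) == -math.inf

    def test_missing_offspring_locus_contributes_one(self, small_freqs, zero_rates):
        off = {"l1": ("A", "B"), "l2": None}
        dam = {"l1": ("A", "A"), "l2": ("A", "A")}
        sire = {"l1": ("B", "B"), "l2": ("B", "B")}
        ll = parent_pair_likelihood(off, dam, sire, small_freqs, zero_rates)
        assert ll == pytest.approx(0.0, abs=1e-9)  # log(1 * 1)

    def test_dropout_likelihood_matches_exhaustive_enumeration(self, two_allele_freqs):
        # independent oracle: enumerate all 3x3x3 true-genotype
        # combinations with the observation model applied to each member
        rates = ErrorRates(0.1, 0.0)
        genos = [("A", "A"), ("A", "B"), ("B", "B")]
        p = {"A": 0.5, "B": 0.5}

        def hw(g):
            return p[g[0]] ** 2 if g[0] == g[1] else 2 * p[g[0]] * p[g[1]]

        def obs_p(observed, true):
            return observation_distribution(true, "loc", two_allele_freqs, rates).get(observed, 0.0)

        def mend(off, d, s):
            return mendelian_transmission(off, d, s, "loc", two_allele_freqs)

        off_obs, dam_obs, sire_obs = ("A", "B"), ("A", "A"), ("A", "B")
        num = 0.0
        for dt, st_, ot in itertools.product(genos, repeat=3):
            num += hw(dt) * obs_p(dam_obs, dt) * hw(st_) * obs_p(sire_obs, st_) * mend(ot, dt, st_) * obs_p(off_obs, ot)
        denom = sum(hw(g) * obs_p(dam_obs, g) for g in genos) * sum(
            hw(g) * obs_p(sire_obs, g) for g in genos
        )
        expected = math.log(num / denom)
        got = parent_pair_likelihood(
            {"loc": off_obs}, {"loc": dam_obs}, {"loc": sire_obs}, two_allele_freqs, rates
        )
        assert got == pytest.approx(expected, abs=1e-12)


class TestExclusionFilter:
    def _geno(self, allele, n=10):
        return {f"L{i}": (allele, allele) for i in range(n)}

    def test_allele_sharing_candidate_retained(self):
        off = self._geno("A")
        cand = {f"L{i}": ("A", "B") for i in range(10)}
        assert exclusion_filter(off, cand)

    def test_five_opposing_loci_excluded(self):
        off = self._geno("A")
        cand = dict(self._geno("A"), **{f"L{i}": ("B", "B") for i in range(5)})
        assert not exclusion_filter(off, cand)
        cand4 = dict(self._geno("A"), **{f"L{i}": ("B", "B") for i in range(4)})
        assert exclusion_filter(off, cand4)

    def test_dead_yearling_excluded(self):
        assert not exclusion_filter(self._geno("A"), self._geno("A"), candidate_dead_young=True)

    def test_too_young_candidate_excluded(self):
        assert not exclusion_filter(
            self._geno("A"), self._geno("A"), offspring_birth=2014, candidate_birth=2013
        )
        assert exclusion_filter(
            self._geno("A"), self._geno("A"), offspring_birth=2015, candidate_birth=2013
        )

    def test_dead_candidate_excluded(self):
        assert not exclusion_filter(
            self._geno("A"), self._geno("A"), offspring_birth=2015, candidate_death=2014
        )


def _toy_family(zero=True):
    """Two parents + cub, fully informative at three loci."""
    freqs = AlleleFrequencyTable(
        {
            "l1": {"A": 0.25, "B": 0.25, "C": 0.25, "D": 0.25},
            "l2": {"A": 0.25, "B": 0.25, "C": 0.25, "D": 0.25},
            "l3": {"A": 0.25, "B": 0.25, "C": 0.25, "D": 0.25},
        }
    )
    genos = {
        "mum": {"l1": ("A", "A"), "l2": ("A", "B"), "l3": ("A", "A")},
        "dad": {"l1": ("C", "C"), "l2": ("C", "D"), "l3": ("C", "C")},
        "cub": {"l1": ("A", "C"), "l2": ("A", "C"), "l3": ("A", "C")},
    }
    sexes = {"mum": "F", "dad": "M", "cub": "F"}
    return genos, sexes, freqs


class TestSamplePedigree:
    def test_unique_compatible_pair_certain_at_zero_unsampled(self, zero_rates):
        genos, sexes, freqs = _toy_family()
        sett = MCMCSettings(iterations=3000, burn_in=500, seed=1,
                            update_unsampled_sizes=False,
                            init_unsampled_male=1e-9, init_unsampled_female=1e-9)
        post = sample_pedigree(genos, sexes, freqs, zero_rates, settings=sett,
                               detection_dates={"mum": 0, "dad": 0, "cub": 1})
        assert post.pair_probabilities("cub")[("mum", "dad")] == pytest.approx(1.0)

    def test_seed_reproducibility(self, small_freqs):
        genos, sexes, _ = _toy_family()
        rates = ErrorRates(0.05, 0.02)
        _, _, freqs = _toy_family()
        sett = MCMCSettings(iterations=2000, burn_in=200, seed=42)
        a = sample_pedigree(genos, sexes, freqs, rates, settings=sett)
        b = sample_pedigree(genos, sexes, freqs, rates, settings=sett)
        assert a.pair_counts == b.pair_counts
        np.testing.assert_array_equal(a.unsampled_male, b.unsampled_male)
        np.testing.assert_array_equal(a.loglik, b.loglik)

    def test_posterior_matches_brute_force_enumeration(self):
        # 2 offspring-ish individuals, several candidates, fixed N
        freqs = AlleleFrequencyTable(
            {"l1": {"A": 0.4, "B": 0.6}, "l2": {"A": 0.3, "B": 0.3, "C": 0.4}}
        )
        rates = ErrorRates(0.05, 0.02)
        genos = {
            "o1": {"l1": ("A", "B"), "l2": ("A", "C")},
            "o2": {"l1": ("A", "A"), "l2": ("B", "C")},
            "d": {"l1": ("A", "A"), "l2": ("A", "B")},
            "s": {"l1": ("A", "B"), "l2": ("B", "C")},
        }
        sexes = {"o1": "F", "o2": "M", "d": "F", "s": "M"}
        sett = MCMCSettings(iterations=42000, burn_in=2000, thinning=2, seed=7,
                            update_unsampled_sizes=False,
                            init_unsampled_male=1.0, init_unsampled_female=1.0)
        post = sample_pedigree(genos, sexes, freqs, rates, settings=sett)
        bf = brute_force_posterior(genos, sexes, freqs, rates)
        for o in genos:
            mc = post.pair_probabilities(o)
            for pair in set(bf[o]) | set(mc):
                p = bf[o].get(pair, 0.0)
                se = math.sqrt(max(p * (1 - p), 1e-6) / post.n_samples)
                assert abs(mc.get(pair, 0.0) - p) < max(3 * se, 0.02)

    def test_unsampled_size_chain_recovers_prior(self):
        # no individuals: the N chains sample the lognormal prior
        sett = MCMCSettings(iterations=220000, burn_in=20000, thinning=2, seed=3)
        post = sample_pedigree({}, {}, AlleleFrequencyTable({"l": {"A": 0.5, "B": 0.5}}),
                               ErrorRates(), settings=sett)
        priors = Priors()
        for chain, mu, sig in (
            (post.unsampled_male, priors.unsampled_male_mu, priors.unsampled_male_sigma),
            (post.unsampled_female, priors.unsampled_female_mu, priors.unsampled_female_sigma),
        ):
            # subsample to decorrelate the random walk
            sub = chain[:: len(chain) // 10000][:10000]
            stat = kstest(np.log(sub), "norm", args=(mu, sig))
            assert stat.pvalue > 0.01

    def test_acceptance_tuned_into_window(self):
        genos, sexes, freqs = _toy_family()
        rates = ErrorRates(0.05, 0.02)
        sett = MCMCSettings(iterations=4000, burn_in=1500, seed=9)
        post = sample_pedigree(genos, sexes, freqs, rates, settings=sett)
        for name, rate in post.acceptance.items():
            assert 0.15 < rate < 0.65, (name, rate, post.warnings)


class TestModalPedigree:
    def _posterior(self, counts):
        return PosteriorPedigree(
            offspring=sorted(counts),
            pair_counts={o: dict(c) for o, c in counts.items()},
            n_samples=sum(next(iter(counts.values())).values()),
            unsampled_male=np.array([]),
            unsampled_female=np.array([]),
            loglik=np.array([]),
        )

    def test_most_frequent_pair_wins(self):
        post = self._posterior({"o": {("d1", "s1"): 60, ("d1", "s2"): 40}})
        ped = modal_pedigree(post)
        assert ped.parents["o"] == ("d1", "s1")
        assert ped.link_prob["o"][0] == pytest.approx(1.0)  # dam marginal
        assert ped.link_prob["o"][1] == pytest.approx(0.6)

    def test_exact_tie_breaks_toward_unsampled(self):
        post = self._posterior(
            {"o": {("d1", "s1"): 50, (UNSAMPLED, UNSAMPLED): 50}}
        )
        ped = modal_pedigree(post)
        assert ped.parents["o"] == (UNSAMPLED, UNSAMPLED)
        assert "TIE" in ped.flags

    def test_cyclic_modal_pairs_get_repaired(self):
        # modal pairs make a and b each other's sires
        post = self._posterior(
            {
                "a": {(UNSAMPLED, "b"): 60, (UNSAMPLED, UNSAMPLED): 40},
                "b": {(UNSAMPLED, "a"): 55, (UNSAMPLED, UNSAMPLED): 45},
            }
        )
        ped = modal_pedigree(post)
        ok, why = is_legal(ped)
        assert ok, why
        assert "REPAIRED" in ped.flags
        # the higher-supported link is kept
        assert ped.parents["a"] == (UNSAMPLED, "b")
        assert ped.parents["b"] == (UNSAMPLED, UNSAMPLED)


class TestErrorRateSampler:
    def test_prior_only_locus_returns_beta_mean(self):
        freqs = AlleleFrequencyTable({"l": {"A": 0.5, "B": 0.5}})
        rates, summ = sample_error_rates({}, freqs, iterations=10, burn_in=5, seed=1)
        assert summ["l"]["E1"][0] == pytest.approx(4 / 104)  # Beta(4,100) mean
        assert summ["l"]["E2"][0] == pytest.approx(2 / 102)  # Beta(2,100) mean
        assert "prior_only" in summ["l"]

    def test_zero_discordance_shrinks_toward_zero(self):
        freqs = AlleleFrequencyTable({"l": {"A": 0.5, "B": 0.5}})
        # many perfectly concordant heterozygous triplicates
        states = {
            f"s{i}": {"l": [("A", "B")] * 3} for i in range(120)
        }
        rates, summ = sample_error_rates(states, freqs, iterations=1500, burn_in=300, seed=2)
        mean_e1 = summ["l"]["E1"][0]
        assert mean_e1 < 4 / 104  # below the prior mean
        assert mean_e1 < 0.02

    def test_dropout_signal_detected(self):
        # truths from Hardy-Weinberg (homozygotes identify the miscall
        # rate, so het->hom discordance is attributed to dropout)
        from wolfped.error_model import simulate_observation

        rng = np.random.default_rng(12)
        freqs = AlleleFrequencyTable({"l": {"A": 0.3, "B": 0.3, "C": 0.4}})
        e1_true, e2_true = 0.12, 0.02
        rates = ErrorRates(e1_true, e2_true)
        alleles = ["A", "B", "C"]
        p = [0.3, 0.3, 0.4]
        states = {}
        for i in range(200):
            true = tuple(sorted(rng.choice(alleles, size=2, p=p)))
            states[f"s{i}"] = {
                "l": [simulate_observation(true, "l", freqs, rates, rng) for _ in range(3)]
            }
        _, summ = sample_error_rates(states, freqs, iterations=1500, burn_in=300, seed=3)
        mean, lo, hi = summ["l"]["E1"]
        assert lo < e1_true < hi
        assert summ["l"]["E2"][1] < e2_true < summ["l"]["E2"][2]
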