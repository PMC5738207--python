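"""Consensus calling, genotype matching, clustering and frequency stats."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wolfped.genodata import (
    AlleleFrequencyTable,
    ConsensusRules,
    ConsensusStatus,
    MatchRule,
    ReplicateObservation,
    allele_frequency_inbreeding,
    augment_frequencies,
    call_consensus,
    cluster_samples,
    expected_heterozygosity,
    match_genotypes,
)


def reps(pairs, sample="s", locus="l"):
    return [
        ReplicateObservation(sample, locus, i + 1, p) for i, p in enumerate(pairs)
    ]


class TestConsensus:
    @pytest.mark.parametrize(
        "pairs, status, genotype",
        [
            # het pair seen together in two of three replicates
            ([("A", "B"), ("A", "B"), ("A", "A")], ConsensusStatus.RELIABLE_HET, ("A", "B")),
            # homozygote must be identical in all three
            ([("A", "A")] * 3, ConsensusStatus.RELIABLE_HOM, ("A", "A")),
            # a failed replicate blocks the all-three homozygote rule
            ([("A", "A"), ("A", "A"), None], ConsensusStatus.UNRESOLVED, None),
            # conflicting dropout pattern resolves in neither triplicate
            (
                [("A", "A"), ("A", "B"), ("B", "B"), ("A", "A"), ("A", "B"), ("B", "B")],
                ConsensusStatus.MISSING,
                None,
            ),
            # second triplicate evaluated on its own succeeds
            (
                [("A", "A"), ("A", "B"), None, ("A", "B"), ("A", "B"), ("C", "C")],
                ConsensusStatus.RELIABLE_HET,
                ("A", "B"),
            ),
        ],
    )
    def test_reliability_rules(self, pairs, status, genotype):
        cg = call_consensus(reps(pairs))
        assert cg.status is status
        assert cg.genotype == genotype

    def test_mixed_ids_rejected(self):
        bad = reps([("A", "A")] * 2) + [ReplicateObservation("other", "l", 3, ("A", "A"))]
        with pytest.raises(ValueError, match="mixed"):
            call_consensus(bad)

    def test_too_many_replicates_rejected(self):
        with pytest.raises(ValueError):
            call_consensus(reps([("A", "A")] * 7))

    @given(
        st.permutations(list(range(3))),
        st.lists(
            st.one_of(
                st.none(),
                st.tuples(st.sampled_from("AB"), st.sampled_from("AB")).map(
                    lambda t: tuple(sorted(t))
                ),
            ),
            min_size=3,
            max_size=3,
        ),
    )
    @settings(derandomize=True, max_examples=60)
    def test_permutation_invariant(self, perm, pairs):
        base = call_consensus(reps(pairs))
        shuffled = [
            ReplicateObservation("s", "l", i + 1, pairs[perm[i]]) for i in range(3)
        ]
        assert call_consensus(shuffled).status is base.status

    def test_pooled_mode_combines_triplicates(self):
        # het seen once per triplicate: pooled evaluation accepts it
        pairs = [("A", "B"), ("A", "A"), None, ("A", "B"), ("C", "C"), None]
        seq = call_consensus(reps(pairs))
        pooled = call_consensus(reps(pairs), ConsensusRules(pooled=True))
        assert seq.status is ConsensusStatus.MISSING
        assert pooled.status is ConsensusStatus.RELIABLE_HET


def _multilocus(pairs_by_locus):
    return dict(pairs_by_locus)


class TestMatching:
    def _identical(self, n=17):
        return {f"L{i}": ("A", "B") for i in range(n)}

    def test_identical_genotypes_match(self):
        g = self._identical()
        res = match_genotypes(g, g)
        assert (res.is_match, res.mismatching_alleles, res.loci_compared) == (True, 0, 17)

    def test_one_allele_at_each_of_two_loci_matches(self):
        g1 = self._identical()
        g2 = dict(g1, L0=("A", "C"), L1=("B", "C"))
        res = match_genotypes(g1, g2)
        assert res.is_match and res.mismatching_alleles == 2

    def test_two_mismatches_at_one_locus_do_not_match(self):
        g1 = self._identical()
        g2 = dict(g1, L0=("C", "D"))
        res = match_genotypes(g1, g2)
        assert not res.is_match and res.mismatching_alleles == 2
        # the plain <=2 rule accepts it
        assert match_genotypes(g1, g2, MatchRule(one_per_locus=False)).is_match

    def test_three_single_mismatches_exceed_limit(self):
        g1 = self._identical()
        g2 = dict(g1, L0=("A", "C"), L1=("A", "C"), L2=("A", "C"))
        res = match_genotypes(g1, g2)
        assert not res.is_match and res.mismatching_alleles == 3

    def test_insufficient_overlap_is_no_call(self):
        g1 = {f"L{i}": ("A", "A") for i in range(5)}
        res = match_genotypes(g1, g1)
        assert res.no_call and not res.is_match

    @given(
        st.dictionaries(
            st.sampled_from([f"L{i}" for i in range(10)]),
            st.one_of(
                st.none(),
                st.tuples(st.sampled_from("ABC"), st.sampled_from("ABC")).map(
                    lambda t: tuple(sorted(t))
                ),
            ),
            min_size=8,
            max_size=10,
        ),
        st.dictionaries(
            st.sampled_from([f"L{i}" for i in range(10)]),
            st.one_of(
                st.none(),
                st.tuples(st.sampled_from("ABC"), st.sampled_from("ABC")).map(
                    lambda t: tuple(sorted(t))
                ),
            ),
            min_size=8,
            max_size=10,
        ),
    )
    @settings(derandomize=True, max_examples=60)
    def test_symmetry(self, g1, g2):
        assert match_genotypes(g1, g2) == match_genotypes(g2, g1)


class TestClustering:
    def test_all_pairwise_matches_form_one_individual(self):
        g = {f"L{i}": ("A", "B") for i in range(12)}
        inds, rejected = cluster_samples({"s1": g, "s2": dict(g), "s3": dict(g)})
        assert len(inds) == 1 and not rejected
        assert inds[0].sample_ids == ["s1", "s2", "s3"]

    def test_transitive_conflict_flagged_ambiguous(self):
        base = {f"L{i}": ("A", "B") for i in range(12)}
        s1 = dict(base)
        s2 = dict(base, L0=("A", "C"))  # matches both neighbours
        s3 = dict(base, L0=("A", "C"), L1=("A", "C"), L2=("A", "C"))  # 3 mismatches to s1
        assert match_genotypes(s1, s2).is_match
        assert match_genotypes(s2, s3).is_match
        assert not match_genotypes(s1, s3).is_match
        inds, _ = cluster_samples({"s1": s1, "s2": s2, "s3": s3})
        assert len(inds) == 1
        assert "AMBIGUOUS" in inds[0].flags

    def test_zero_error_round_trip_recovers_all_individuals(self, rng):
        # 81 distinct individuals sampled without error cluster exactly
        from wolfped.synthetic_data import make_frequency_table

        freqs = make_frequency_table(17, 0.58, seed=9)
        genos = {}
        for i in range(81):
            g = {}
            for loc in freqs.loci:
                alleles = freqs.alleles(loc)
                p = [freqs.freq(loc, a) for a in alleles]
                g[loc] = tuple(sorted(rng.choice(alleles, size=2, p=p)))
            genos[f"s{i:03d}"] = g
        inds, rejected = cluster_samples(genos)
        assert len(inds) == 81 and not rejected


class TestFrequencyStats:
    def test_expected_heterozygosity_values(self):
        freqs = AlleleFrequencyTable(
            {
                "even": {"A": 0.5, "B": 0.5},
                "skew": {"A": 0.2, "B": 0.3, "C": 0.5},
                "mono": {"A": 1.0},
            }
        )
        per_locus, mean, se = expected_heterozygosity(freqs)
        assert per_locus["even"] == pytest.approx(0.5)
        assert per_locus["skew"] == pytest.approx(0.62)
        assert per_locus["mono"] == pytest.approx(0.0)
        assert mean == pytest.approx(per_locus.mean())
        # H_E bounded by 1 - 1/k
        for loc, k in (("even", 2), ("skew", 3), ("mono", 1)):
            assert 0 <= per_locus[loc] <= 1 - 1 / k + 1e-12

    def test_augment_renormalises(self):
        base = AlleleFrequencyTable({"l": {"A": 0.6, "B": 0.4}})
        out = augment_frequencies(base, {"l": ["C"]}, epsilon=0.005)
        assert out.freq("l", "A") == pytest.approx(0.6 / 1.005)
        assert out.freq("l", "C") == pytest.approx(0.005 / 1.005)
        assert sum(out.locus_freqs("l").values()) == pytest.approx(1.0, abs=1e-9)

    def test_augment_no_novel_is_identity(self):
        base = AlleleFrequencyTable({"l": {"A": 0.6, "B": 0.4}})
        assert augment_frequencies(base, {"l": ["A", "B"]}) == base

    def test_augment_two_novel_alleles(self):
        base = AlleleFrequencyTable({"l": {"A": 1.0}})
        out = augment_frequencies(base, {"l": ["B", "C"]}, epsilon=0.01)
        assert out.freq("l", "B") == pytest.approx(0.01 / 1.02)
        assert out.freq("l", "C") == pytest.approx(0.01 / 1.02)

    def test_fhat_all_heterozygous_is_zero(self, small_freqs):
        geno = {"l1": ("A", "B"), "l2": ("A", "C"), "l3": ("C", "D")}
        fhat, _, _ = allele_frequency_inbreeding({"i": geno}, small_freqs)
        assert fhat["i"] == pytest.approx(0.0, abs=1e-5)

    def test_fhat_single_homozygote_is_one(self, two_allele_freqs):
        fhat, _, _ = allele_frequency_inbreeding(
            {"i": {"loc": ("A", "A")}}, two_allele_freqs
        )
        assert fhat["i"] == pytest.approx(1.0, abs=1e-5)

    def test_fhat_simulation_recovery(self, rng):
        # genotypes drawn from the inbreeding model at F = 0.2
        f_true = 0.2
        k, n_loci, n_ind = 4, 30, 200
        p = np.array([0.1, 0.2, 0.3, 0.4])
        alleles = ["a", "b", "c", "d"]
        freqs = AlleleFrequencyTable(
            {f"L{j}": dict(zip(alleles, p)) for j in range(n_loci)}
        )
        inds = {}
        for i in range(n_ind):
            g = {}
            for j in range(n_loci):
                if rng.random() < f_true:  # identical by descent
                    a = rng.choice(alleles, p=p)
                    g[f"L{j}"] = (a, a)
                else:
                    g[f"L{j}"] = tuple(sorted(rng.choice(alleles, size=2, p=p)))
            inds[f"i{i}"] = g
        _, mean, _ = allele_frequency_inbreeding(inds, freqs)
        assert abs(mean - f_true) < 0.05

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            AlleleFrequencyTable({})

    def test_unnormalised_locus_rejected(self):
        with pytest.raises(ValueError):
            AlleleFrequencyTable({"l": {"A": 0.5, "B": 0.6}})
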