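"""Nucleotide diversity, Hudson F_ST, and AMOVA Phi_ST."""

import itertools
import math

import numpy as np
import pytest

from pooltag.haplotypes import HaplotypeSet
from pooltag.popgen import (
    amova_phist,
    estimate_all,
    fst_matrix,
    nucleotide_diversity,
    pairwise_fst_hudson,
)


def hapset(pool_id, haps, sites=None):
    return HaplotypeSet(
        pool_id=pool_id,
        N=sum(m for _, m in haps),
        haplotypes=tuple(sorted(haps, key=lambda kv: (-kv[1], kv[0]))),
        sites=sites,
    )


def enumerate_pairs(hapsA, hapsB=None):
    """Oracle: explicit expansion to individuals and pair enumeration."""
    ea = [h for h, m in hapsA for _ in range(m)]
    if hapsB is None:
        pairs = list(itertools.combinations(ea, 2))
    else:
        eb = [h for h, m in hapsB for _ in range(m)]
        pairs = [(a, b) for a in ea for b in eb]
    diffs = [sum(x != y for x, y in zip(a, b)) for a, b in pairs]
    return sum(diffs), len(pairs)


class TestNucleotideDiversity:
    def test_monomorphic_pool_is_zero(self):
        assert nucleotide_diversity(hapset("p", [("AAA", 5)]), L=420) == 0.0

    def test_two_sequences_one_difference(self):
        hs = hapset("p", [("A", 1), ("T", 1)])
        assert nucleotide_diversity(hs, L=420) == pytest.approx(1 / 420)

    def test_five_two_split_matches_pair_enumeration(self):
        haps = [("C", 5), ("T", 2)]
        hs = hapset("p", haps)
        total, n_pairs = enumerate_pairs(haps)
        assert n_pairs == 21 and total == 10
        assert nucleotide_diversity(hs, L=420) == pytest.approx(10 / 21 / 420)

    def test_scales_inversely_with_length(self):
        hs = hapset("p", [("CA", 3), ("TA", 4)])
        assert nucleotide_diversity(hs, L=100) == pytest.approx(
            2 * nucleotide_diversity(hs, L=200)
        )

    def test_relabelling_invariance(self):
        a = nucleotide_diversity(hapset("p", [("AC", 3), ("GT", 2)]), L=50)
        b = nucleotide_diversity(hapset("p", [("GT", 2), ("AC", 3)]), L=50)
        assert a == b

    def test_undefined_below_two(self):
        # construction forbids N < 2 at the type level; estimator reports NaN
        hs = HaplotypeSet.__new__(HaplotypeSet)
        object.__setattr__(hs, "N", 1)
        object.__setattr__(hs, "haplotypes", (("A", 1),))
        assert math.isnan(nucleotide_diversity(hs, L=10))


class TestHudsonFst:
    def test_identical_monomorphic_pools(self):
        a = hapset("a", [("AAA", 4)])
        b = hapset("b", [("AAA", 6)])
        assert pairwise_fst_hudson(a, b) == 0.0

    def test_fixed_difference_complete_differentiation(self):
        a = hapset("a", [("A", 4)])
        b = hapset("b", [("T", 5)])
        assert pairwise_fst_hudson(a, b) == pytest.approx(1.0)

    def test_matches_pair_enumeration_oracle(self):
        hapsA = [("C", 5), ("T", 2)]
        hapsB = [("C", 1), ("T", 6)]
        wa, pa = enumerate_pairs(hapsA)
        wb, pb = enumerate_pairs(hapsB)
        between, nb = enumerate_pairs(hapsA, hapsB)
        assert (wa, wb, between, nb) == (10, 6, 5 * 6 + 2 * 1, 49)
        hw_pooled = (wa + wb) / (pa + pb)
        hw_mean = (wa / pa + wb / pb) / 2
        hb = between / nb
        a, b = hapset("a", hapsA), hapset("b", hapsB)
        assert pairwise_fst_hudson(a, b, "pooled") == pytest.approx(1 - hw_pooled / hb)
        assert pairwise_fst_hudson(a, b) == pytest.approx(1 - hw_mean / hb)
        # equal pool sizes: the two weightings coincide
        assert pairwise_fst_hudson(a, b, "pooled") == pytest.approx(
            pairwise_fst_hudson(a, b, "mean_of_pops")
        )

    def test_symmetry(self):
        a = hapset("a", [("CA", 5), ("TA", 2)])
        b = hapset("b", [("CA", 1), ("TT", 6)])
        assert pairwise_fst_hudson(a, b) == pytest.approx(pairwise_fst_hudson(b, a))

    def test_identical_polymorphic_multisets_non_positive(self):
        # the finite-sample estimator is slightly negative for identical
        # polymorphic pools (within-pool means use n-1 pair denominators);
        # negatives are classified as "no differentiation" downstream
        a = hapset("a", [("CA", 3), ("TT", 3)])
        b = hapset("b", [("CA", 3), ("TT", 3)])
        assert pairwise_fst_hudson(a, b) <= 0.0

    def test_mismatched_site_sets_rejected(self):
        with pytest.raises(ValueError):
            pairwise_fst_hudson(
                hapset("a", [("AA", 2)]), hapset("b", [("A", 2)])
            )


class TestAmova:
    def test_all_pools_fixed_distinct_gives_one(self):
        pools = [
            hapset("a", [("AAAA", 3)]),
            hapset("b", [("TTTT", 3)]),
            hapset("c", [("GGGG", 3)]),
        ]
        phi, p = amova_phist(pools, n_perm=50, seed=0)
        assert phi == pytest.approx(1.0)
        assert p <= 1 / 51 + 1e-12

    def test_identical_sequences_undefined(self):
        pools = [hapset("a", [("AA", 3)]), hapset("b", [("AA", 3)])]
        phi, p = amova_phist(pools, n_perm=10, seed=0)
        assert math.isnan(phi) and math.isnan(p)

    def test_two_pool_direction_agrees_with_hudson_fst(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            width = 6
            mk = lambda: "".join(
                "ACGT"[i] for i in rng.integers(0, 4, size=width)
            )
            base_a, base_b = mk(), mk()
            a = hapset("a", [(base_a, 4), (mk(), 2)])
            b = hapset("b", [(base_b, 4), (mk(), 2)])
            fst = pairwise_fst_hudson(a, b)
            phi, _ = amova_phist([a, b], n_perm=0, seed=0)
            if math.isnan(phi):
                continue
            assert (fst > 1e-9) == (phi > 1e-9) or (
                abs(fst) < 0.05 and abs(phi) < 0.05
            )

    def test_seeded_p_value_reproducible(self):
        pools = [
            hapset("a", [("AATA", 2), ("AAAA", 2)]),
            hapset("b", [("TTAT", 3), ("TTTT", 1)]),
        ]
        r1 = amova_phist(pools, n_perm=200, seed=11)
        r2 = amova_phist(pools, n_perm=200, seed=11)
        assert r1 == r2


def test_estimate_all_bundle():
    pools = [
        hapset("a", [("AA", 3), ("AT", 1)]),
        hapset("b", [("TT", 4)]),
        hapset("c", [("TA", 2), ("AA", 2)]),
    ]
    est = estimate_all(pools, L=100, n_perm=50, seed=0)
    assert est.pool_ids == ("a", "b", "c")
    assert est.fst.shape == (3, 3)
    assert np.all(np.isnan(np.diag(est.fst)))
    assert est.fst[0, 1] == pytest.approx(est.fst[1, 0])
    assert 0 < est.phi_p <= 1
    d = est.to_dict()
    assert set(d) >= {"pi", "fst", "phi_st", "phi_p"}
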