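"""Frequency-to-count allocation and haplotype phasing."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from conftest import make_mapped
from pooltag.haplotypes import (
    AlleleCountTable,
    HaplotypeSet,
    allocate_counts,
    expand_to_sites,
    haplotypes_from_individual_sequences,
    phase_from_spanning_reads,
)


class TestAllocateCounts:
    def test_pool_of_seven_at_seventy_thirty(self):
        assert allocate_counts({"C": 0.7, "T": 0.3}, 7) == {"C": 5, "T": 2}

    def test_monomorphic(self):
        assert allocate_counts({"A": 1.0}, 4) == {"A": 4}

    def test_even_split_tie_breaks_lexicographically(self):
        assert allocate_counts({"A": 0.5, "G": 0.5}, 5) == {"A": 3, "G": 2}

    def test_all_zero_frequencies_error(self):
        with pytest.raises(ValueError):
            allocate_counts({"A": 0.0}, 3)

    def test_matches_exhaustive_l1_search(self):
        """Largest-remainder allocation attains the minimum L1 distance
        to freq*N over every integer split, for N <= 10 and a 0.05
        frequency grid."""
        for n in range(1, 11):
            for pct in range(0, 105, 5):
                freqs = {"A": pct / 100, "C": 1 - pct / 100}
                freqs = {a: f for a, f in freqs.items() if f > 0}
                got = allocate_counts(freqs, n)
                best = min(
                    sum(abs(k - freqs.get(a, 0) * n)
                        for a, k in zip(freqs, combo))
                    for combo in itertools.product(range(n + 1), repeat=len(freqs))
                    if sum(combo) == n
                )
                l1 = sum(abs(got[a] - freqs[a] * n) for a in freqs)
                assert math.isclose(l1, best, abs_tol=1e-12)
                assert sum(got.values()) == n


def table(pool_id, N, counts):
    return AlleleCountTable(pool_id=pool_id, N=N, counts=counts)


def reads_from_haplotypes(haps, sites, per_copy=5):
    """Deterministic full-spanning reads: per_copy reads per individual."""
    reads = []
    i = 0
    for alleles, mult in haps:
        for _ in range(mult * per_copy):
            bases = "".join(alleles)
            # contiguous representation over the called sites only
            read = make_mapped("", read_id=f"r{i}")
            read.ref_positions = np.asarray(sites, dtype=np.int32)
            read.bases = np.asarray(list(bases), dtype="<U1")
            read.quals = np.full(len(sites), 30, dtype=np.int16)
            reads.append(read)
            i += 1
    return reads


class TestPhasing:
    def test_single_site_needs_no_phasing(self):
        t = table("p", 7, {10: {"C": 5, "T": 2}})
        hs = phase_from_spanning_reads(t, [])
        assert hs.haplotypes == (("C", 5), ("T", 2))

    def test_perfect_linkage_two_sites(self):
        t = table("p", 7, {3: {"A": 4, "T": 3}, 9: {"G": 4, "C": 3}})
        reads = reads_from_haplotypes([("AG", 4), ("TC", 3)], [3, 9])
        hs = phase_from_spanning_reads(t, reads)
        assert hs.haplotypes == (("AG", 4), ("TC", 3))
        assert hs.ambiguous_pairs == ()

    def test_no_spanning_reads_falls_back_to_rank_matching(self):
        t = table("p", 7, {3: {"A": 5, "T": 2}, 9: {"G": 4, "C": 3}})
        hs = phase_from_spanning_reads(t, [], min_span_reads=3)
        assert hs.ambiguous_pairs == ((3, 9),)
        # largest-with-largest: A(5) takes G(4) then C(1); T(2) takes C(2)
        assert dict(hs.haplotypes) == {"AG": 4, "AC": 1, "TC": 2}

    def test_marginals_always_conserved(self):
        rng = np.random.default_rng(4)
        for trial in range(25):
            n_sites = int(rng.integers(1, 5))
            sites = sorted(rng.choice(100, size=n_sites, replace=False))
            N = int(rng.integers(2, 9))
            counts = {}
            truth = [["?"] * n_sites for _ in range(N)]
            for k, pos in enumerate(sites):
                alleles = rng.permutation(list("ACGT"))[: int(rng.integers(1, 4))]
                assignment = rng.choice(len(alleles), size=N)
                for ind in range(N):
                    truth[ind][k] = alleles[assignment[ind]]
                c = Counter(alleles[a] for a in assignment)
                counts[int(pos)] = dict(c)
            t = table("p", N, counts)
            hap_counts = Counter("".join(row) for row in truth)
            reads = reads_from_haplotypes(
                sorted(hap_counts.items()), [int(s) for s in sites], per_copy=3
            )
            hs = phase_from_spanning_reads(t, reads)
            assert hs.site_marginals() == counts

    def test_recovers_truth_against_exhaustive_oracle(self):
        """On <= 3 sites, N <= 6, with deterministic full-spanning reads,
        phasing equals the marginal-consistent haplotype multiset that
        maximises read agreement (which is the generating truth)."""
        rng = np.random.default_rng(9)
        for trial in range(15):
            n_sites = int(rng.integers(2, 4))
            sites = sorted(int(s) for s in rng.choice(50, n_sites, replace=False))
            N = int(rng.integers(3, 7))
            alleles_per_site = [
                [str(a) for a in rng.permutation(list("ACGT"))[:2]]
                for _ in range(n_sites)
            ]
            truth_rows = [
                "".join(alleles_per_site[k][int(rng.integers(0, 2))]
                        for k in range(n_sites))
                for _ in range(N)
            ]
            truth = Counter(truth_rows)
            marginals = {
                pos: dict(Counter(row[k] for row in truth_rows))
                for k, pos in enumerate(sites)
            }
            reads = reads_from_haplotypes(sorted(truth.items()), sites)
            hs = phase_from_spanning_reads(table("p", N, marginals), reads)

            # oracle: enumerate all assignments consistent with marginals,
            # keep those maximising the number of reads consistent with
            # some positive-multiplicity haplotype
            vectors = ["".join(v) for v in itertools.product(*alleles_per_site)]
            best_score, best_sets = -1, []
            for combo in itertools.product(range(N + 1), repeat=len(vectors)):
                if sum(combo) != N:
                    continue
                cand = {v: c for v, c in zip(vectors, combo) if c > 0}
                ok = all(
                    sum(c for v, c in cand.items() if v[k] == a) == cnt
                    for k, pos in enumerate(sites)
                    for a, cnt in marginals[pos].items()
                )
                if not ok:
                    continue
                score = sum(
                    mult for v, mult in truth.items() if v in cand
                )
                if score > best_score:
                    best_score, best_sets = score, [cand]
                elif score == best_score:
                    best_sets.append(cand)
            assert dict(hs.haplotypes) == dict(truth)
            assert dict(truth) in best_sets

    def test_inconsistent_table_rejected(self):
        with pytest.raises(ValueError):
            table("p", 7, {3: {"A": 5, "T": 1}})


class TestIndividualHaplotypes:
    def test_direct_read_off(self):
        seqs = ["ACGT"] * 5 + ["ACTT"] * 2
        hs = haplotypes_from_individual_sequences(seqs, [2], pool_id="p")
        assert hs.haplotypes == (("G", 5), ("T", 2))

    def test_all_identical_single_haplotype(self):
        hs = haplotypes_from_individual_sequences(["ACGT"] * 4, [1, 3])
        assert hs.haplotypes == (("CT", 4),)

    def test_ambiguity_site_dropped_pool_wide(self):
        seqs = ["ACGT", "ACRT", "TCGT"]
        hs = haplotypes_from_individual_sequences(seqs, [0, 2])
        assert hs.sites == (0,)
        assert dict(hs.haplotypes) == {"A": 2, "T": 1}


def test_expand_to_sites_fills_reference_alleles():
    hs = HaplotypeSet("p", 3, (("C", 2), ("T", 1)), sites=(5,))
    ref = "A" * 10
    out = expand_to_sites(hs, [2, 5, 8], ref)
    assert out.sites == (2, 5, 8)
    assert dict(out.haplotypes) == {"ACA": 2, "ATA": 1}


def test_haplotype_set_invariants():
    with pytest.raises(ValueError):
        HaplotypeSet("p", 3, (("C", 1), ("T", 1)), sites=(5,))
    with pytest.raises(ValueError):
        HaplotypeSet("p", 2, (("CT", 2),), sites=(5,))
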