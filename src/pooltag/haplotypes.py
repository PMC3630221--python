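"""Population haplotype reconstruction from pooled SNP frequencies.

In an equimolar pool of N haploid individuals, a variant at read
frequency f is carried by about ``f * N`` individuals: frequencies are
converted to integer per-site allele counts by largest-remainder
allocation (minimising the L1 distance to ``f * N`` subject to the
counts summing to N). Multi-site haplotypes are then assembled by
linking alleles at consecutive called sites using reads that span both
sites — automating what was historically resolved by eye from longer
reads — with site-pairs lacking spanning-read evidence linked by
frequency rank (largest with largest) and flagged ambiguous so that
downstream diversity statistics can be recomputed under alternative
phasings.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .mapping import MappedRead
from .variants import SnpCall

_NUC = set("ACGT")


@dataclass(frozen=True)
class AlleleCountTable:
    """Integer allele counts per called site for one pool; each site's
    counts sum exactly to the pool size N."""

    pool_id: str
    N: int
    counts: dict[int, dict[str, int]]  # position -> allele -> count

    def __post_init__(self) -> None:
        for pos, alleles in self.counts.items():
            total = sum(alleles.values())
            if total != self.N or any(c < 0 for c in alleles.values()):
                raise ValueError(
                    f"counts at site {pos} must be non-negative and sum to N={self.N}"
                )

    @property
    def sites(self) -> tuple[int, ...]:
        return tuple(sorted(self.counts))


@dataclass(frozen=True)
class HaplotypeSet:
    """Reconstructed haplotypes for one pool.

    ``haplotypes`` holds ``(allele string, multiplicity)`` pairs; the
    string runs over ``sites`` (ascending reference positions) or over
    the full reference when ``sites`` is None. ``ambiguous_pairs``
    lists consecutive site-pairs whose linkage had no qualifying
    spanning-read support.
    """

    pool_id: str
    N: int
    haplotypes: tuple[tuple[str, int], ...]
    sites: Optional[tuple[int, ...]] = None
    ambiguous_pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if sum(m for _, m in self.haplotypes) != self.N:
            raise ValueError("multiplicities must sum to N")
        if self.sites is not None:
            for h, _ in self.haplotypes:
                if len(h) != len(self.sites):
                    raise ValueError("haplotype length must match number of sites")

    def site_marginals(self) -> dict[int, dict[str, int]]:
        """Per-site allele counts implied by the haplotypes."""
        if self.sites is None:
            raise ValueError("marginals require explicit sites")
        out: dict[int, dict[str, int]] = {}
        for k, pos in enumerate(self.sites):
            counts: Counter = Counter()
            for hap, mult in self.haplotypes:
                counts[hap[k]] += mult
            out[pos] = dict(counts)
        return out


def allocate_counts(freqs: Mapping[str, float], N: int) -> dict[str, int]:
    """Integer counts closest (L1) to ``freq * N`` summing exactly to N.

    Largest-remainder allocation: frequencies are renormalised, each
    allele receives ``floor(f * N)``, and leftover units go to the
    largest fractional remainders, ties broken by lexicographic allele
    order. E.g. frequencies C/T of 0.7/0.3 in a pool of seven give
    counts 5 and 2.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    total = float(sum(freqs.values()))
    if total <= 0:
        raise ValueError("all frequencies are zero")
    # totals slightly off 1 (filtered low-frequency alleles) are renormalised
    quotas = {a: freqs[a] / total * N for a in freqs}
    counts = {a: int(np.floor(q)) for a, q in quotas.items()}
    remaining = N - sum(counts.values())
    order = sorted(quotas, key=lambda a: (-(quotas[a] - counts[a]), a))
    for a in order[:remaining]:
        counts[a] += 1
    return counts


def count_table_from_calls(
    calls: Sequence[SnpCall], pool_id: str, N: int, freq_floor: float = 0.05
) -> AlleleCountTable:
    """Build the per-site integer count table from passing pooled calls.

    At each called site the candidate alleles are the passing variant
    alleles plus the reference allele when its own frequency clears the
    floor; frequencies are renormalised over candidates before
    allocation, and alleles allocated zero copies are dropped.
    """
    table: dict[int, dict[str, int]] = {}
    for call in calls:
        if not call.passes or call.mode != "pooled":
            continue
        alleles = {a: call.alleles[a] for a in call.variant_alleles}
        ref_freq = call.alleles.get(call.ref, 0.0)
        if ref_freq >= freq_floor:
            alleles[call.ref] = ref_freq
        if not alleles:
            continue
        counts = allocate_counts(alleles, N)
        counts = {a: c for a, c in counts.items() if c > 0}
        table[call.position] = counts
    return AlleleCountTable(pool_id=pool_id, N=N, counts=table)


# ---------------------------------------------------------------------------
# phasing

def _read_site_alleles(
    mappings: Sequence[MappedRead], sites: Sequence[int]
) -> list[dict[int, str]]:
    """Per read, the base observed at each queried site it covers."""
    site_arr = np.asarray(sites, dtype=np.int64)
    out = []
    for m in mappings:
        if m.ref_positions.size == 0:
            continue
        idx = np.searchsorted(m.ref_positions, site_arr)
        hit = (idx < m.ref_positions.size) & (
            m.ref_positions[np.minimum(idx, m.ref_positions.size - 1)] == site_arr
        )
        if not hit.any():
            continue
        out.append(
            {
                int(site_arr[k]): str(m.bases[idx[k]])
                for k in np.nonzero(hit)[0]
            }
        )
    return out


def phase_from_spanning_reads(
    count_table: AlleleCountTable,
    mappings: Sequence[MappedRead],
    min_span_reads: int = 3,
) -> HaplotypeSet:
    """Assemble haplotypes by greedy, prefix-aware linkage of called sites.

    Sites are processed in reference order, maintaining a set of
    partial haplotypes (prefixes) with integer multiplicities. To link
    the next site, every read covering it and at least one processed
    site votes for the (prefix, allele) combinations it is consistent
    with — a read supports a prefix only if it matches the prefix at
    *all* processed sites the read covers, so reads spanning several
    sites resolve combinations that single site-pair counts cannot.
    Each prefix's multiplicity is then split across next-site alleles
    by largest-remainder allocation of its support proportions, and
    the split is repaired (moving single units by smallest support
    loss) until the site's marginal counts from the table are met
    exactly.

    A consecutive site-pair with fewer than ``min_span_reads`` reads
    covering both sites is flagged ambiguous and linked by
    frequency-rank matching instead (largest multiplicity with largest
    count, ties lexicographic). Site marginals of the result always
    equal the count table.
    """
    sites = count_table.sites
    N = count_table.N
    if not sites:
        return HaplotypeSet(pool_id=count_table.pool_id, N=N,
                            haplotypes=(("", N),), sites=())

    read_alleles = _read_site_alleles(mappings, sites)

    first = count_table.counts[sites[0]]
    partials: list[tuple[tuple[str, ...], int]] = [
        ((a,), m) for a, m in sorted(first.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    ambiguous: list[tuple[int, int]] = []

    for k in range(1, len(sites)):
        prev_pos, pos = sites[k - 1], sites[k]
        processed = sites[:k]
        next_counts = dict(count_table.counts[pos])
        n_span = sum(
            1 for ra in read_alleles if prev_pos in ra and pos in ra
        )
        if n_span >= min_span_reads:
            alloc = _link_by_support(
                partials, processed, next_counts, read_alleles, pos
            )
        else:
            ambiguous.append((prev_pos, pos))
            alloc = _link_by_rank(partials, next_counts)

        merged: Counter = Counter()
        for (prefix, b), m in alloc.items():
            if m > 0:
                merged[prefix + (b,)] += m
        partials = sorted(merged.items(), key=lambda kv: (-kv[1], kv[0]))

    haps = tuple(
        sorted(
            (("".join(alleles), mult) for alleles, mult in partials),
            key=lambda kv: (-kv[1], kv[0]),
        )
    )
    return HaplotypeSet(
        pool_id=count_table.pool_id,
        N=N,
        haplotypes=haps,
        sites=sites,
        ambiguous_pairs=tuple(ambiguous),
    )


def _link_by_support(
    partials: Sequence[tuple[tuple[str, ...], int]],
    processed: Sequence[int],
    next_counts: dict[str, int],
    read_alleles: Sequence[dict[int, str]],
    pos: int,
) -> dict[tuple[tuple[str, ...], str], int]:
    """Split each prefix's multiplicity over next-site alleles by read support."""
    site_index = {p: i for i, p in enumerate(processed)}
    support: dict[int, Counter] = {i: Counter() for i in range(len(partials))}
    for ra in read_alleles:
        b = ra.get(pos)
        if b not in next_counts:
            continue
        covered = [(s, a) for s, a in ra.items() if s in site_index]
        if not covered:
            continue
        for i, (prefix, _) in enumerate(partials):
            if all(prefix[site_index[s]] == a for s, a in covered):
                support[i][b] += 1

    alloc: dict[tuple[tuple[str, ...], str], int] = {}
    unplaced: list[tuple[int, int]] = []  # (partial index, multiplicity)
    for i, (prefix, mult) in enumerate(partials):
        row = support[i]
        total = sum(row.values())
        if total == 0:
            unplaced.append((i, mult))
            continue
        quotas = {b: mult * row.get(b, 0) / total for b in next_counts}
        floors = {b: int(np.floor(q)) for b, q in quotas.items()}
        left = mult - sum(floors.values())
        order = sorted(quotas, key=lambda b: (-(quotas[b] - floors[b]), b))
        for b in order[:left]:
            floors[b] += 1
        for b, m in floors.items():
            if m > 0:
                alloc[(prefix, b)] = m

    # place support-less prefixes into the largest remaining deficits
    def deficits() -> dict[str, int]:
        placed = Counter()
        for (_, b), m in alloc.items():
            placed[b] += m
        return {b: next_counts[b] - placed.get(b, 0) for b in next_counts}

    for i, mult in unplaced:
        prefix = partials[i][0]
        while mult > 0:
            d = deficits()
            b = max(d, key=lambda x: (d[x], x))
            take = min(mult, d[b]) if d[b] > 0 else mult
            alloc[(prefix, b)] = alloc.get((prefix, b), 0) + take
            mult -= take

    # repair: move single units until the marginals match exactly
    prefix_index = {prefix: i for i, (prefix, _) in enumerate(partials)}
    while True:
        d = deficits()
        under = sorted((b for b in d if d[b] > 0), key=lambda b: (-d[b], b))
        over = set(b for b in d if d[b] < 0)
        if not under:
            break
        moves = []
        for (prefix, b_over), m in alloc.items():
            if b_over not in over or m <= 0:
                continue
            row = support.get(prefix_index.get(prefix, -1), Counter())
            for b_under in under:
                moves.append(
                    (row.get(b_under, 0) - row.get(b_over, 0),
                     "".join(prefix), b_over, b_under, prefix)
                )
        moves.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
        _, _, b_over, b_under, prefix = moves[0]
        alloc[(prefix, b_over)] -= 1
        if alloc[(prefix, b_over)] == 0:
            del alloc[(prefix, b_over)]
        alloc[(prefix, b_under)] = alloc.get((prefix, b_under), 0) + 1
    return alloc


def _link_by_rank(
    partials: Sequence[tuple[tuple[str, ...], int]],
    next_counts: dict[str, int],
) -> dict[tuple[tuple[str, ...], str], int]:
    """Frequency-rank matching: largest multiplicities with largest counts."""
    alloc: dict[tuple[tuple[str, ...], str], int] = {}
    remaining = [
        [prefix, mult]
        for prefix, mult in sorted(partials, key=lambda kv: (-kv[1], kv[0]))
    ]
    nexts = [
        [b, c]
        for b, c in sorted(next_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    while True:
        remaining.sort(key=lambda p: (-p[1], "".join(p[0])))
        nexts.sort(key=lambda n: (-n[1], n[0]))
        live_p = [p for p in remaining if p[1] > 0]
        live_n = [n for n in nexts if n[1] > 0]
        if not live_p or not live_n:
            break
        p, n = live_p[0], live_n[0]
        take = min(p[1], n[1])
        key = (tuple(p[0]), n[0])
        alloc[key] = alloc.get(key, 0) + take
        p[1] -= take
        n[1] -= take
    return alloc


def haplotypes_from_individual_sequences(
    sequences: Sequence[str], snp_sites: Sequence[int], pool_id: str = "pool"
) -> HaplotypeSet:
    """Read haplotypes directly off per-individual sequences.

    Sites where any sequence carries a non-ACGT character are dropped
    pool-wide, mirroring the individual-mode caller.
    """
    kept = [
        pos
        for pos in sorted(snp_sites)
        if all(s[pos] in _NUC for s in sequences)
    ]
    counts: Counter = Counter("".join(s[p] for p in kept) for s in sequences)
    haps = tuple(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    return HaplotypeSet(
        pool_id=pool_id, N=len(sequences), haplotypes=haps, sites=tuple(kept)
    )


def expand_to_sites(
    hapset: HaplotypeSet,
    union_sites: Sequence[int],
    reference: str,
) -> HaplotypeSet:
    """Re-express haplotypes over a harmonised site union.

    Sites absent from the pool's own set are filled with the reference
    allele (the pool showed no accepted variant there); full-length
    haplotype sets are simply restricted to the union positions.
    """
    union = tuple(sorted(union_sites))
    out: Counter = Counter()
    if hapset.sites is None:
        for hap, mult in hapset.haplotypes:
            out["".join(hap[p] for p in union)] += mult
    else:
        index = {p: k for k, p in enumerate(hapset.sites)}
        for hap, mult in hapset.haplotypes:
            out[
                "".join(
                    hap[index[p]] if p in index else reference[p] for p in union
                )
            ] += mult
    haps = tuple(sorted(out.items(), key=lambda kv: (-kv[1], kv[0])))
    return HaplotypeSet(
        pool_id=hapset.pool_id,
        N=hapset.N,
        haplotypes=haps,
        sites=union,
        ambiguous_pairs=hapset.ambiguous_pairs,
    )


def write_haplotype_tsv(hapsets: Sequence[HaplotypeSet], path) -> None:
    with open(path, "w") as fh:
        fh.write("pool_id\thaplotype\tmultiplicity\tambiguous_pairs\n")
        for hs in hapsets:
            amb = ",".join(f"{i + 1}-{j + 1}" for i, j in hs.ambiguous_pairs) or "."
            for hap, mult in hs.haplotypes:
                fh.write(f"{hs.pool_id}\t{hap or '.'}\t{mult}\t{amb}\n")


def expanded_fasta_records(hapset: HaplotypeSet, reference: str):
    """Full-length sequences (reference with alleles substituted) for export."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if hapset.sites is None:
        seqs = [(hap, mult) for hap, mult in hapset.haplotypes]
    else:
        seqs = []
        for hap, mult in hapset.haplotypes:
            full = list(reference)
            for k, pos in enumerate(hapset.sites):
                full[pos] = hap[k]
            seqs.append(("".join(full), mult))
    return [
        SeqRecord(Seq(seq), id=f"{hapset.pool_id}_h{i + 1}_x{mult}", description="")
        for i, (seq, mult) in enumerate(seqs)
    ]
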