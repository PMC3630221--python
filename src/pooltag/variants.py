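"""Pileup construction and SNP calling for pooled and individual data.

Pooled mode follows the conservative criteria used for pooled amplicon
data: a variant allele at a site is reported only when the site depth
is at least 20 reads, the allele's mean central Phred quality and the
mean quality of the neighbouring columns are both at least 20, and the
allele's read frequency clears a floor of 5% — approximately the
lowest expected frequency of a real haplotype in the pools studied
(the expected frequency of a single-copy variant in an equimolar pool
of N haploid individuals is 1/N, e.g. ~14% for N = 7). The floor can
optionally be adjusted per pool as max(floor, c/N).

Individual mode operates on one full-length sequence per individual:
variant counts rather than read frequencies, minimum coverage two
sequences, and sites carrying IUPAC ambiguity codes excluded outright.

Sites inside reference homopolymer runs (length >= 3) are flagged but
not excluded: pyrosequencing concentrates indel miscalls there, so
flagged calls deserve scrutiny, yet real variants do occur in runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .mapping import MappedRead
from .simdata import homopolymer_runs

_NUCS = "ACGT"
_NUC_INDEX = {n: i for i, n in enumerate(_NUCS)}


@dataclass(frozen=True)
class PileupColumn:
    reference_name: str
    position: int  # 0-based
    depth: int
    counts: dict[str, int]
    mean_quals: dict[str, float]
    in_homopolymer: bool


class Pileup:
    """Per-position allele counts and quality sums over a reference."""

    def __init__(self, reference_name: str, reference: str):
        self.reference_name = reference_name
        self.reference = reference
        L = len(reference)
        self.counts = np.zeros((L, 4), dtype=np.int64)
        self.qual_sums = np.zeros((L, 4), dtype=np.float64)
        self.homopolymer = np.zeros(L, dtype=bool)
        for start, end in homopolymer_runs(reference, min_len=3):
            self.homopolymer[start:end] = True

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def column(self, position: int) -> Optional[PileupColumn]:
        """The pileup column at ``position``, or None when uncovered."""
        row = self.counts[position]
        depth = int(row.sum())
        if depth == 0:
            return None
        counts = {n: int(row[i]) for n, i in _NUC_INDEX.items() if row[i] > 0}
        quals = {
            n: float(self.qual_sums[position, i] / row[i])
            for n, i in _NUC_INDEX.items()
            if row[i] > 0
        }
        return PileupColumn(
            reference_name=self.reference_name,
            position=position,
            depth=depth,
            counts=counts,
            mean_quals=quals,
            in_homopolymer=bool(self.homopolymer[position]),
        )

    def columns(self) -> Iterable[PileupColumn]:
        for pos in np.nonzero(self.depth > 0)[0]:
            yield self.column(int(pos))


def build_pileup(
    mappings: Sequence[MappedRead], reference_name: str, reference: str
) -> Pileup:
    """Accumulate accepted mappings into a pileup.

    Read deletions contribute no allele and insertions are ignored
    entirely (site-based substitution model).
    """
    pile = Pileup(reference_name, reference)
    for m in mappings:
        if m.reference_name != reference_name or m.ref_positions.size == 0:
            continue
        allele_idx = np.array([_NUC_INDEX.get(b, -1) for b in m.bases], dtype=np.int64)
        keep = allele_idx >= 0
        pos = m.ref_positions[keep].astype(np.int64)
        idx = allele_idx[keep]
        np.add.at(pile.counts, (pos, idx), 1)
        np.add.at(pile.qual_sums, (pos, idx), m.quals[keep].astype(np.float64))
    return pile


@dataclass(frozen=True)
class SnpCall:
    """One called site.

    ``alleles`` maps allele -> read frequency in pooled mode and
    allele -> individual count in individual mode; ``variant_alleles``
    are the non-reference alleles that passed every filter.
    """

    position: int  # 0-based
    ref: str
    alleles: dict[str, float]
    variant_alleles: tuple[str, ...]
    depth: int
    mode: str  # "pooled" | "individual"
    passes: bool
    flags: tuple[str, ...] = ()
    in_homopolymer: bool = False

    def polymorphic_within_pool(self, floor: float = 0.0) -> bool:
        """True when >= 2 alleles clear ``floor`` (frequency or count)."""
        return sum(1 for v in self.alleles.values() if v > floor) >= 2


def expected_singleton_freq(N: int) -> float:
    """Expected percent frequency of a single-copy variant in a pool of N.

    For an equimolar pool of N haploid individuals a variant carried by
    one individual is expected in 1/N of the reads, i.e. 100/N percent
    (about 14% for N = 7).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    return 100.0 / N


def call_snps_pooled(
    pileup: Pileup,
    N: int,
    min_q: float = 20.0,
    min_cov: int = 20,
    freq_floor: float = 0.05,
    adjust_per_pool: bool = False,
    floor_scale: float = 1.0,
    neighborhood_radius: int = 5,
    include_filtered: bool = False,
) -> list[SnpCall]:
    """Call variant sites from a pooled pileup.

    A variant allele is called iff site depth >= ``min_cov``, its mean
    central quality >= ``min_q``, the mean quality over columns within
    ``neighborhood_radius`` (central column excluded) >= ``min_q``, and
    its read frequency >= the floor. With ``adjust_per_pool`` the floor
    becomes ``max(freq_floor, floor_scale / N)``, mirroring a per-pool
    minimum tied to the expected singleton frequency. By default only
    sites with at least one passing variant allele are returned;
    ``include_filtered`` adds sites whose variant alleles all failed,
    with the failure reasons in ``flags``.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    if N < 2:
        raise ValueError("pool size N must be >= 2")
    floor = max(freq_floor, floor_scale / N) if adjust_per_pool else freq_floor

    depth = pileup.depth
    qual_cum = np.concatenate([[0.0], np.cumsum(pileup.qual_sums.sum(axis=1))])
    depth_cum = np.concatenate([[0], np.cumsum(depth)])
    L = len(depth)

    def neighborhood_quality(pos: int) -> float:
        lo, hi = max(0, pos - neighborhood_radius), min(L, pos + neighborhood_radius + 1)
        q = (qual_cum[hi] - qual_cum[lo]) - pileup.qual_sums[pos].sum()
        d = (depth_cum[hi] - depth_cum[lo]) - depth[pos]
        return float(q / d) if d > 0 else float("inf")

    calls: list[SnpCall] = []
    for pos in np.nonzero(depth > 0)[0]:
        col = pileup.column(int(pos))
        ref_base = pileup.reference[pos]
        variant_counts = {a: c for a, c in col.counts.items() if a != ref_base}
        if not variant_counts:
            continue
        freqs = {a: c / col.depth for a, c in col.counts.items()}
        site_flags: list[str] = []
        if col.depth < min_cov:
            site_flags.append("min_coverage")
        nq = neighborhood_quality(int(pos))
        passing: list[str] = []
        failed: set[str] = set()
        for allele in sorted(variant_counts):
            allele_flags = list(site_flags)
            if col.mean_quals[allele] < min_q:
                allele_flags.append("min_quality")
            if nq < min_q:
                allele_flags.append("min_neighborhood_quality")
            if freqs[allele] < floor:
                allele_flags.append("min_frequency")
            if not allele_flags:
                passing.append(allele)
            else:
                failed.update(allele_flags)
        passes = bool(passing)
        flags = sorted(failed)
        if passes or include_filtered:
            calls.append(
                SnpCall(
                    position=int(pos),
                    ref=ref_base,
                    alleles=freqs,
                    variant_alleles=tuple(passing),
                    depth=col.depth,
                    mode="pooled",
                    passes=passes,
                    flags=tuple(() if passes else flags),
                    in_homopolymer=col.in_homopolymer,
                )
            )
    return calls


def call_snps_individual(
    sequences: Sequence[str],
    reference: str,
    min_cov: int = 2,
) -> tuple[list[SnpCall], list[int]]:
    """Call polymorphic sites from per-individual full-length sequences.

    A site is polymorphic iff at least ``min_cov`` sequences are
    present and >= 2 distinct alleles are observed. Sites showing any
    non-ACGT (ambiguity) character in any sequence are excluded
    pool-wide; their 0-based positions are returned alongside.
    """
    if any(len(s) != len(reference) for s in sequences):
        raise ValueError("sequences must be aligned to the reference length")
    n = len(sequences)
    homopoly = np.zeros(len(reference), dtype=bool)
    for start, end in homopolymer_runs(reference, min_len=3):
        homopoly[start:end] = True

    calls: list[SnpCall] = []
    excluded: list[int] = []
    for pos in range(len(reference)):
        observed = [s[pos] for s in sequences]
        if any(b not in _NUC_INDEX for b in observed):
            excluded.append(pos)
            continue
        alleles = sorted(set(observed))
        if n < min_cov or len(alleles) < 2:
            continue
        counts = {a: float(observed.count(a)) for a in alleles}
        ref_base = reference[pos]
        calls.append(
            SnpCall(
                position=pos,
                ref=ref_base,
                alleles=counts,
                variant_alleles=tuple(a for a in alleles if a != ref_base),
                depth=n,
                mode="individual",
                passes=True,
                in_homopolymer=bool(homopoly[pos]),
            )
        )
    return calls, excluded


def write_snp_tsv(calls: Sequence[SnpCall], pool_id: str, path) -> None:
    """SNP table with 1-based positions; value column is frequency or count."""
    with open(path, "w") as fh:
        fh.write("pool\tposition\tref\talt\tfreq_or_count\tdepth\tflags\n")
        for c in calls:
            alts = c.variant_alleles or tuple(a for a in c.alleles if a != c.ref)
            for alt in alts:
                flags = ";".join(c.flags) if c.flags else (
                    "homopolymer" if c.in_homopolymer else "PASS"
                )
                fh.write(
                    f"{pool_id}\t{c.position + 1}\t{c.ref}\t{alt}"
                    f"\t{c.alleles.get(alt, 0):.4g}\t{c.depth}\t{flags}\n"
                )
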