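"""Synthetic pooled-amplicon read generation with known truth.

Emulates a parallel tagged pyrosequencing experiment on population pools
of haploid (mitochondrial) amplicons: each population pool holds an
equimolar mixture of 2-13 individuals' PCR products, tagged with an 8-bp
pool barcode, and is sequenced as single-end reads whose length is
centred on the instrument's modal read length. Two locus layouts are
provided: a single short amplicon fully covered by one read
("16S-like", ~420 bp) and two overlapping amplicons sharing a start
coordinate whose lengths exceed the modal read length ("Cyt b-like",
570/830 bp) — the latter reproduces the uneven coverage that degrades
SNP detection beyond the short amplicon's end.

Error model: uniform per-base substitutions with a constant Phred
quality derived from the substitution rate, and +/-1 bp homopolymer
indels whose per-run probability grows linearly with run length, the
signature error mode of pyrosequencing. Optional lognormal "pipetting"
noise perturbs per-individual molarities away from equimolarity.
"""

from __future__ import annotations

import math
import zlib
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import barcodes as _barcodes

_NUCS = "ACGT"


@dataclass(frozen=True)
class LocusModel:
    """A reference sequence with one or more amplicons defined on it.

    ``amplicons`` are half-open ``[start, end)`` intervals; every
    individual contributes one PCR product per amplicon to its pool.
    A two-amplicon locus must have both amplicons share their start
    (nested products from a common forward primer).
    """

    name: str
    reference: str
    amplicons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        L = len(self.reference)
        if L == 0:
            raise ValueError("empty reference")
        if not self.amplicons:
            raise ValueError("at least one amplicon required")
        for start, end in self.amplicons:
            if not (0 <= start < end <= L):
                raise ValueError(f"amplicon [{start},{end}) outside [0,{L})")
        if len(self.amplicons) == 2:
            (s1, e1), (s2, e2) = self.amplicons
            if s1 != s2 or e1 == e2:
                raise ValueError(
                    "a two-amplicon locus must share its start with distinct ends"
                )

    @property
    def length(self) -> int:
        return len(self.reference)


@dataclass(frozen=True)
class PoolTruth:
    """Ground truth for one population pool.

    ``haplotypes`` is a collection of ``(full-length sequence,
    multiplicity)`` pairs whose multiplicities sum to the pool size N
    (haploid individuals).
    """

    pool_id: str
    N: int
    haplotypes: tuple[tuple[str, int], ...]
    barcode: str

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("pool size N must be >= 2")
        mults = [m for _, m in self.haplotypes]
        if any(m < 1 for m in mults) or sum(mults) != self.N:
            raise ValueError("multiplicities must be positive and sum to N")
        lengths = {len(h) for h, _ in self.haplotypes}
        if len(lengths) != 1:
            raise ValueError("haplotypes must share one length")

    def individual_sequences(self) -> list[str]:
        """Expand to one full-length sequence per individual."""
        out: list[str] = []
        for hap, mult in self.haplotypes:
            out.extend([hap] * mult)
        return out


@dataclass(frozen=True)
class SimConfig:
    """Sequencing-run parameters.

    modal_read_length : most common read length in bp (GS FLX-era 477).
    read_length_sd : spread of the truncated-normal length distribution.
    per_base_error_rate : substitution probability per base; the
        constant quality string is Q = round(-10 log10(rate)).
    homopolymer_indel_base_rate : per-run indel probability is
        ``rate * (run_length - 1)`` for runs of length >= 2; the indel
        is +/-1 bp with equal probability.
    pipetting_cv : coefficient of variation of per-individual molarity
        (lognormal weights, renormalised); 0 = exactly equimolar.
    reads_per_pool : reads simulated per pool, unless
        ``reads_per_individual`` is set, in which case the pool gets
        ``round(reads_per_individual * N)`` reads.
    """

    modal_read_length: int = 477
    read_length_sd: float = 40.0
    per_base_error_rate: float = 0.0
    homopolymer_indel_base_rate: float = 0.0
    pipetting_cv: float = 0.0
    reads_per_pool: int = 200
    reads_per_individual: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.per_base_error_rate, self.homopolymer_indel_base_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0,1]")
        if self.modal_read_length <= 0:
            raise ValueError("modal_read_length must be positive")
        if self.pipetting_cv < 0:
            raise ValueError("pipetting_cv must be >= 0")

    @property
    def quality(self) -> int:
        """Constant Phred quality consistent with the substitution rate."""
        if self.per_base_error_rate <= 0:
            return 40
        return min(40, round(-10.0 * math.log10(self.per_base_error_rate)))


def random_reference(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(_NUCS[i] for i in rng.integers(0, 4, size=length))


def single_amplicon_locus(length: int = 420, seed: int = 0, name: str = "16S-like") -> LocusModel:
    """A short locus whose single amplicon fits within one read."""
    return LocusModel(name=name, reference=random_reference(length, seed),
                      amplicons=((0, length),))


def two_amplicon_locus(
    length: int = 830, short_end: int = 570, seed: int = 0, name: str = "CytB-like"
) -> LocusModel:
    """Two nested amplicons (570/830 bp style) sharing a forward primer."""
    return LocusModel(name=name, reference=random_reference(length, seed),
                      amplicons=((0, short_end), (0, length)))


# ---------------------------------------------------------------------------
# structured populations

def generate_structured_populations(
    n_pops: int,
    pool_sizes: Sequence[int],
    locus: LocusModel,
    n_site_pool: int = 30,
    within_div: float = 0.15,
    between_div: float = 0.2,
    seed: int = 0,
) -> list[PoolTruth]:
    """Draw genetically structured population pools with known truth.

    Each population receives a private block of candidate positions on
    the reference (a global shuffled partition, so no two populations
    mutate the same site). Per population,
    ``Binomial(n_site_pool, between_div)`` positions become private
    *fixed* differences (all individuals carry the derived base) and
    ``Binomial(n_site_pool, within_div)`` positions become segregating
    sites, each with a derived-allele count uniform on ``1..N-1``
    assigned to a random subset of individuals. Distinct haplotypes per
    pool therefore never exceed N. Pool barcodes are designed with the
    8-bp / distance-3 defaults. Deterministic for a fixed seed.
    """
    if n_pops < 2:
        raise ValueError("n_pops must be >= 2")
    if len(pool_sizes) != n_pops:
        raise ValueError("pool_sizes must have length n_pops")
    if any(n < 2 for n in pool_sizes):
        raise ValueError("every pool size must be >= 2")

    rng = np.random.default_rng(seed)
    L = locus.length
    positions = list(rng.permutation(L))
    tags = _barcodes.design_barcodes(n_pops, seed=seed).tags

    truths: list[PoolTruth] = []
    for i, N in enumerate(pool_sizes):
        n_between = int(rng.binomial(n_site_pool, between_div))
        n_within = int(rng.binomial(n_site_pool, within_div))
        if n_between + n_within > len(positions):
            raise ValueError(
                "not enough reference positions for the requested divergence; "
                "reduce n_site_pool or the rates"
            )
        fixed_sites = [positions.pop() for _ in range(n_between)]
        seg_sites = [positions.pop() for _ in range(n_within)]

        base = list(locus.reference)
        for pos in fixed_sites:
            base[pos] = _mutate_base(base[pos], rng)
        individuals = [list(base) for _ in range(N)]
        for pos in seg_sites:
            derived = _mutate_base(base[pos], rng)
            m = int(rng.integers(1, N))  # 1..N-1 derived copies
            carriers = rng.choice(N, size=m, replace=False)
            for c in carriers:
                individuals[c][pos] = derived

        counts = Counter("".join(ind) for ind in individuals)
        haps = tuple(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
        truths.append(
            PoolTruth(pool_id=f"pop{i + 1:02d}", N=int(N), haplotypes=haps,
                      barcode=tags[i])
        )
    return truths


def _mutate_base(base: str, rng: np.random.Generator) -> str:
    alts = [n for n in _NUCS if n != base]
    return alts[int(rng.integers(0, 3))]


def study_pool_sizes(n_pops: int = 20, total: int = 93, seed: int = 0) -> list[int]:
    """Pool sizes in the study's range (2-13) summing to ``total``.

    Sizes are drawn uniformly on 2..13 and then adjusted within the
    range until they sum to ``total`` (93 individuals across 20
    populations, mean 4.65, in the emulated design).
    """
    lo, hi = 2, 13
    if not n_pops * lo <= total <= n_pops * hi:
        raise ValueError("total individuals incompatible with the 2-13 range")
    rng = np.random.default_rng(seed)
    sizes = list(rng.integers(lo, hi + 1, size=n_pops))
    diff = total - int(sum(sizes))
    step = 1 if diff > 0 else -1
    while diff != 0:
        i = int(rng.integers(0, n_pops))
        if lo <= sizes[i] + step <= hi:
            sizes[i] += step
            diff -= step
    return [int(s) for s in sizes]


# ---------------------------------------------------------------------------
# read simulation

def homopolymer_runs(seq: str, min_len: int = 2) -> list[tuple[int, int]]:
    """Half-open [start, end) intervals of runs of identical bases."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j))
        i = j
    return runs


def _apply_homopolymer_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    """+/-1 bp errors inside homopolymer runs, probability rising with run length."""
    if rate <= 0:
        return seq
    out = []
    last = 0
    for start, end in homopolymer_runs(seq):
        out.append(seq[last:start])
        run = seq[start:end]
        if rng.random() < min(1.0, rate * (end - start - 1)):
            run = run[:-1] if rng.random() < 0.5 else run + run[0]
        out.append(run)
        last = end
    out.append(seq[last:])
    return "".join(out)


def _apply_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        arr[i] = _mutate_base(arr[i], rng)
    return "".join(arr)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def pool_rng(config: SimConfig, pool_id: str) -> np.random.Generator:
    """Per-pool generator derived stably from the run seed and pool id."""
    return np.random.default_rng([config.seed, zlib.crc32(pool_id.encode())])


def simulate_pool_reads(
    truth: PoolTruth, locus: LocusModel, config: SimConfig
) -> list[SeqRecord]:
    """Simulate barcode-prefixed FASTQ records for one pool.

    Each read picks an individual (equimolar, or lognormal weights when
    ``pipetting_cv`` > 0), an amplicon (equal molarity when two are
    present), and a strand uniformly; its length is a truncated normal
    around the modal read length, capped at the amplicon length, and it
    starts at the amplicon terminus matching its strand (primer-anchored
    amplicon sequencing). Homopolymer indels are applied to the insert,
    substitutions to barcode+insert, and the quality string is the
    constant Q implied by the substitution rate.
    """
    rng = pool_rng(config, truth.pool_id)
    individuals = truth.individual_sequences()
    tag = truth.barcode
    min_amp = min(e - s for s, e in locus.amplicons)
    if min_amp <= len(tag):
        raise ValueError("amplicon shorter than the barcode")

    if config.reads_per_individual is not None:
        n_reads = int(round(config.reads_per_individual * truth.N))
    else:
        n_reads = int(config.reads_per_pool)

    if config.pipetting_cv > 0:
        sigma = math.sqrt(math.log(1.0 + config.pipetting_cv**2))
        w = rng.lognormal(mean=0.0, sigma=sigma, size=truth.N)
        weights = w / w.sum()
    else:
        weights = np.full(truth.N, 1.0 / truth.N)

    records: list[SeqRecord] = []
    for r in range(n_reads):
        ind = int(rng.choice(truth.N, p=weights))
        amp = locus.amplicons[int(rng.integers(0, len(locus.amplicons)))]
        strand = "+" if rng.random() < 0.5 else "-"
        amp_len = amp[1] - amp[0]
        length = int(round(rng.normal(config.modal_read_length, config.read_length_sd)))
        length = max(len(tag) + 1, min(length, amp_len))
        template = individuals[ind][amp[0]:amp[1]]
        insert = template[:length] if strand == "+" else _revcomp(template[-length:])
        insert = _apply_homopolymer_indels(
            insert, config.homopolymer_indel_base_rate, rng
        )
        seq = _apply_substitutions(tag + insert, config.per_base_error_rate, rng)
        rec = SeqRecord(
            Seq(seq),
            id=f"{truth.pool_id}_r{r:06d}",
            description="",
        )
        rec.letter_annotations["phred_quality"] = [config.quality] * len(seq)
        records.append(rec)
    return records


def simulate_experiment(
    truths: Sequence[PoolTruth], locus: LocusModel, config: SimConfig
) -> list[SeqRecord]:
    """Simulate and concatenate reads for every pool (one sequencing run)."""
    reads: list[SeqRecord] = []
    for truth in truths:
        reads.extend(simulate_pool_reads(truth, locus, config))
    return reads


# ---------------------------------------------------------------------------
# plain-text I/O

def write_fastq(records: Iterable[SeqRecord], path) -> int:
    return SeqIO.write(records, path, "fastq")


def write_reference_fasta(loci: Sequence[LocusModel], path) -> int:
    recs = [SeqRecord(Seq(l.reference), id=l.name, description="") for l in loci]
    return SeqIO.write(recs, path, "fasta")


def write_truth_tsv(truths: Sequence[PoolTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write("pool_id\thaplotype\tmultiplicity\n")
        for t in truths:
            for hap, mult in t.haplotypes:
                fh.write(f"{t.pool_id}\t{hap}\t{mult}\n")


def write_manifest_tsv(truths: Sequence[PoolTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write("pool_id\tbarcode\tN\n")
        for t in truths:
            fh.write(f"{t.pool_id}\t{t.barcode}\t{t.N}\n")


def read_manifest_tsv(path) -> list[dict]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            vals = line.rstrip("\n").split("\t")
            row = dict(zip(header, vals))
            row["N"] = int(row["N"])
            rows.append(row)
    return rows


def write_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        for key, val in vars(config).items():
            fh.write(f"{key}={val}\n")


def read_config(path) -> SimConfig:
    kwargs: dict = {}
    casts = {f: t for f, t in SimConfig.__annotations__.items()}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            if key == "reads_per_individual":
                kwargs[key] = None if val == "None" else float(val)
            elif key in ("modal_read_length", "reads_per_pool", "seed"):
                kwargs[key] = int(val)
            else:
                kwargs[key] = float(val)
    return SimConfig(**kwargs)
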