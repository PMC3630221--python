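"""End-to-end orchestration: simulate -> demultiplex -> map -> call ->
reconstruct -> estimate -> compare, with QC and coverage reporting.

Two analysis modes mirror the two experimental approaches being
compared. Pooled mode consumes barcoded reads: exact-tag
demultiplexing, filtered mapping, pooled SNP calling, frequency ->
count haplotype reconstruction with spanning-read phasing, then pi /
Hudson F_ST / AMOVA Phi_ST over the pools. Individual mode consumes
one full-length sequence per individual and computes the same
quantities from unambiguous haplotypes. Every stage's in/out counts
are tracked so each input read is accounted for exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import barcodes as _barcodes
from . import concordance as _concordance
from . import haplotypes as _haplotypes
from . import popgen as _popgen
from . import variants as _variants
from .mapping import AlignmentParams, MappedRead, map_reads
from .simdata import LocusModel, PoolTruth, SimConfig, simulate_experiment


@dataclass(frozen=True)
class RunManifest:
    """Pool records plus the locus models and run seed."""

    pools: tuple[tuple[str, str, int], ...]  # (pool_id, barcode, N)
    loci: tuple[LocusModel, ...]
    seed: int = 0
    mode: str = "both"  # pooled | individual | both

    def __post_init__(self) -> None:
        ids = [p[0] for p in self.pools]
        if len(set(ids)) != len(ids):
            raise ValueError("pool ids must be unique")
        # validates tag uniqueness/length via BarcodeSet invariants
        _barcodes.BarcodeSet(tags=tuple(p[1] for p in self.pools), min_distance=1)

    @classmethod
    def from_truths(cls, truths: Sequence[PoolTruth], loci: Sequence[LocusModel],
                    seed: int = 0, mode: str = "both") -> "RunManifest":
        return cls(
            pools=tuple((t.pool_id, t.barcode, t.N) for t in truths),
            loci=tuple(loci),
            seed=seed,
            mode=mode,
        )


def coverage_profile(mappings: Sequence[MappedRead], reference_length: int) -> np.ndarray:
    """Read depth per reference position (0-based array)."""
    depth = np.zeros(reference_length, dtype=np.int64)
    for m in mappings:
        depth[m.ref_start:m.ref_end] += 1
    return depth


def read_qc_summary(reads: Sequence, length_bin: int = 10) -> dict:
    """Count, read-length mean/sd/modal bin, and mean base quality."""
    lengths = np.array([len(r.seq) for r in reads], dtype=float)
    if lengths.size == 0:
        return {
            "count": 0, "length_mean": float("nan"), "length_sd": float("nan"),
            "modal_length_bin": None, "mean_quality": float("nan"),
        }
    quals = np.concatenate(
        [np.asarray(r.letter_annotations.get("phred_quality", []), dtype=float)
         for r in reads]
    )
    bins = (lengths // length_bin).astype(int)
    modal = int(np.bincount(bins).argmax())
    return {
        "count": int(lengths.size),
        "length_mean": float(lengths.mean()),
        "length_sd": float(lengths.std(ddof=1)) if lengths.size > 1 else 0.0,
        "modal_length_bin": (modal * length_bin, (modal + 1) * length_bin),
        "mean_quality": float(quals.mean()) if quals.size else float("nan"),
    }


@dataclass
class PoolResult:
    pool_id: str
    N: int
    n_reads: int
    n_mapped: int
    rejections: dict
    coverage: np.ndarray
    snp_calls: list
    count_table: Optional[_haplotypes.AlleleCountTable]
    hapset: Optional[_haplotypes.HaplotypeSet]

    @property
    def n_polymorphic(self) -> int:
        """Within-pool polymorphic called sites (>= 2 alleles above floor)."""
        return sum(1 for c in self.snp_calls if c.polymorphic_within_pool(0.05))


@dataclass
class PipelineReport:
    """Everything one run produces, for one locus."""

    mode: str
    locus_name: str
    stage_counts: dict
    pools: dict[str, PoolResult]
    estimates: Optional[_popgen.PopGenEstimates]
    qc: dict

    @property
    def snp_counts(self) -> dict[str, int]:
        return {pid: pr.n_polymorphic for pid, pr in self.pools.items()}


def run_pooled_pipeline(
    truths: Sequence[PoolTruth],
    locus: LocusModel,
    config: SimConfig,
    reads: Optional[Sequence] = None,
    params: AlignmentParams = AlignmentParams(),
    min_q: float = 20.0,
    min_cov: int = 20,
    freq_floor: float = 0.05,
    min_span_reads: int = 3,
    n_perm: int = 1000,
    engine: str = "edlib",
) -> PipelineReport:
    """The pooled-approach analysis chain on simulated or provided reads.

    When ``reads`` is None they are simulated from the truths under
    ``config``; either way the reads then flow through exact-barcode
    demultiplexing, filtered mapping, pooled SNP calling, haplotype
    reconstruction, and the population genetic estimators. Pools with
    no accepted mappings are reported with a missing haplotype set and
    excluded from the estimates; the run continues.
    """
    if reads is None:
        reads = simulate_experiment(truths, locus, config)
    qc = read_qc_summary(reads)
    pool_tags = {t.pool_id: t.barcode for t in truths}
    assignments, unassigned = _barcodes.demultiplex(reads, pool_tags)
    stage = {
        "reads_in": len(reads),
        "barcode_matched": sum(len(v) for v in assignments.values()),
        "unassigned": unassigned,
        "mapped": 0,
        "rejected": 0,
    }

    references = [(locus.name, locus.reference)]
    pools: dict[str, PoolResult] = {}
    for truth in truths:
        pool_reads = assignments[truth.pool_id]
        mapped, rejected = map_reads(pool_reads, references, params, engine)
        stage["mapped"] += len(mapped)
        stage["rejected"] += sum(rejected.values())
        cov = coverage_profile(mapped, locus.length)
        if not mapped:
            pools[truth.pool_id] = PoolResult(
                pool_id=truth.pool_id, N=truth.N, n_reads=len(pool_reads),
                n_mapped=0, rejections=dict(rejected), coverage=cov,
                snp_calls=[], count_table=None, hapset=None,
            )
            continue
        pile = _variants.build_pileup(mapped, locus.name, locus.reference)
        calls = _variants.call_snps_pooled(
            pile, N=truth.N, min_q=min_q, min_cov=min_cov, freq_floor=freq_floor
        )
        table = _haplotypes.count_table_from_calls(
            calls, truth.pool_id, truth.N, freq_floor
        )
        hapset = _haplotypes.phase_from_spanning_reads(table, mapped, min_span_reads)
        pools[truth.pool_id] = PoolResult(
            pool_id=truth.pool_id, N=truth.N, n_reads=len(pool_reads),
            n_mapped=len(mapped), rejections=dict(rejected), coverage=cov,
            snp_calls=calls, count_table=table, hapset=hapset,
        )

    estimates = _estimate(
        [p for p in pools.values() if p.hapset is not None],
        locus, n_perm, config.seed,
    )
    return PipelineReport(
        mode="pooled", locus_name=locus.name, stage_counts=stage,
        pools=pools, estimates=estimates, qc=qc,
    )


def _estimate(
    pool_results: Sequence[PoolResult], locus: LocusModel, n_perm: int, seed: int
) -> Optional[_popgen.PopGenEstimates]:
    if len(pool_results) < 2:
        return None
    union: set[int] = set()
    for pr in pool_results:
        union.update(pr.hapset.sites or ())
    expanded = [
        _haplotypes.expand_to_sites(pr.hapset, sorted(union), locus.reference)
        for pr in pool_results
    ]
    return _popgen.estimate_all(expanded, L=locus.length, n_perm=n_perm, seed=seed)


def run_individual_pipeline(
    truths: Sequence[PoolTruth],
    locus: LocusModel,
    sequences: Optional[dict[str, list[str]]] = None,
    min_cov: int = 2,
    n_perm: int = 1000,
    seed: int = 0,
) -> PipelineReport:
    """The individual-approach chain from per-individual sequences.

    ``sequences`` maps pool_id -> full-length sequences (defaults to
    the simulation truth, i.e. error-free Sanger-style data). Variant
    counts come from direct counting at each site; haplotypes are read
    off the sequences, so phase is unambiguous.
    """
    pools: dict[str, PoolResult] = {}
    for truth in truths:
        seqs = (sequences or {}).get(truth.pool_id) or truth.individual_sequences()
        calls, _excluded = _variants.call_snps_individual(
            seqs, locus.reference, min_cov=min_cov
        )
        snp_sites = [c.position for c in calls]
        hapset = _haplotypes.HaplotypeSet(
            pool_id=truth.pool_id,
            N=len(seqs),
            haplotypes=tuple(
                sorted(
                    ((h, m) for h, m in _count_seqs(seqs).items()),
                    key=lambda kv: (-kv[1], kv[0]),
                )
            ),
            sites=None,  # full-length haplotypes
        )
        pools[truth.pool_id] = PoolResult(
            pool_id=truth.pool_id, N=len(seqs), n_reads=len(seqs),
            n_mapped=len(seqs), rejections={},
            coverage=np.full(locus.length, len(seqs), dtype=np.int64),
            snp_calls=calls, count_table=None, hapset=hapset,
        )

    union: set[int] = set()
    for pr in pools.values():
        union.update(c.position for c in pr.snp_calls)
        # fixed differences from the reference also separate pools
        for hap, _ in pr.hapset.haplotypes:
            union.update(
                int(p) for p in np.nonzero(
                    np.frombuffer(hap.encode(), dtype=np.uint8)
                    != np.frombuffer(locus.reference.encode(), dtype=np.uint8)
                )[0]
            )
    expanded = [
        _haplotypes.expand_to_sites(pr.hapset, sorted(union), locus.reference)
        for pr in pools.values()
    ]
    estimates = _popgen.estimate_all(expanded, L=locus.length, n_perm=n_perm, seed=seed)
    return PipelineReport(
        mode="individual", locus_name=locus.name,
        stage_counts={"sequences_in": sum(p.n_reads for p in pools.values())},
        pools=pools, estimates=estimates,
        qc={"count": sum(p.n_reads for p in pools.values())},
    )


def _count_seqs(seqs: Sequence[str]) -> dict[str, int]:
    out: dict[str, int] = {}
    for s in seqs:
        out[s] = out.get(s, 0) + 1
    return out


def compare_pipelines(
    pooled: PipelineReport, individual: PipelineReport
) -> _concordance.ConcordanceReport:
    """Concordance statistics between the two modes of one experiment."""
    if pooled.estimates is None or individual.estimates is None:
        raise ValueError("both runs need estimates over >= 2 pools")
    ids = [pid for pid in individual.estimates.pool_ids
           if pid in pooled.estimates.pool_ids]
    pi_i = [individual.estimates.pi[p] for p in ids]
    pi_p = [pooled.estimates.pi[p] for p in ids]
    idx_i = [individual.estimates.pool_ids.index(p) for p in ids]
    idx_p = [pooled.estimates.pool_ids.index(p) for p in ids]
    fst_i = individual.estimates.fst[np.ix_(idx_i, idx_i)]
    fst_p = pooled.estimates.fst[np.ix_(idx_p, idx_p)]
    return _concordance.compare_estimates(
        pi_i, pi_p, fst_i, fst_p,
        snp_counts_individual=[individual.snp_counts[p] for p in ids],
        snp_counts_pooled=[pooled.snp_counts[p] for p in ids],
    )
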