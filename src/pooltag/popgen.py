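"""Population genetic estimators over reconstructed haplotype sets.

Nucleotide diversity (pi) is the mean number of pairwise differences
per site among the sequences of a population. Pairwise F_ST follows
Hudson's difference-based estimator, F_ST = 1 - Hw/Hb, where Hw is the
mean number of differences between sequences sampled within a
population and Hb between sequences sampled from the two different
populations. Overall structure is summarised by a single-level
analysis of molecular variance (AMOVA): sums of squared
pairwise-difference distances are partitioned into among- and
within-population variance components and Phi_ST =
sigma2_among / (sigma2_among + sigma2_within), with significance from
a seeded permutation of individuals among populations.

All estimators treat haplotypes as allele strings over the analysed
sites with integer multiplicities; distances count differing sites.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .haplotypes import HaplotypeSet


def _hap_matrix(haps: Sequence[tuple[str, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Distinct haplotypes as a byte matrix plus their multiplicities."""
    seqs = np.array(
        [np.frombuffer(h.encode(), dtype=np.uint8) for h, _ in haps]
    ) if haps and haps[0][0] else np.zeros((len(haps), 0), dtype=np.uint8)
    mults = np.array([m for _, m in haps], dtype=np.int64)
    return seqs, mults


def _diff_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise difference counts between rows of two byte matrices."""
    if a.shape[1] == 0:
        return np.zeros((a.shape[0], b.shape[0]), dtype=np.int64)
    return (a[:, None, :] != b[None, :, :]).sum(axis=2).astype(np.int64)


def nucleotide_diversity(haps: HaplotypeSet, L: int) -> float:
    """Mean pairwise differences per site, pi.

    Pairs are drawn with multiplicity over the pool's N sequences and
    the difference count is normalised by the number of unordered pairs
    C(N,2) and by the sequence length ``L`` (the full amplicon length:
    sites not analysed are monomorphic). Undefined (NaN) for N < 2.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    if haps.N < 2:
        return float("nan")
    seqs, mults = _hap_matrix(haps.haplotypes)
    d = _diff_matrix(seqs, seqs)
    total = float((mults[:, None] * mults[None, :] * d).sum()) / 2.0
    n_pairs = haps.N * (haps.N - 1) / 2.0
    return total / n_pairs / L


def pairwise_fst_hudson(
    hapsA: HaplotypeSet, hapsB: HaplotypeSet, weighting: str = "mean_of_pops"
) -> float:
    """Hudson's F_ST = 1 - Hw/Hb between two population pools.

    ``weighting`` fixes how within-population pairs enter Hw:
    ``"mean_of_pops"`` (default) averages the two per-population mean
    pairwise differences with equal weight per population, matching
    Hudson, Slatkin and Maddison's definition of Hw as the mean number
    of differences between sequences sampled from the same
    subpopulation; ``"pooled"`` instead weights every within-pair
    equally, which down-weights small pools. When Hb = 0 both pools are identical
    and monomorphic and F_ST is reported as 0.
    """
    if hapsA.N < 2 or hapsB.N < 2:
        raise ValueError("both pools need N >= 2")
    sa, ma = _hap_matrix(hapsA.haplotypes)
    sb, mb = _hap_matrix(hapsB.haplotypes)
    if sa.shape[1] != sb.shape[1]:
        raise ValueError("haplotype sets must cover the same sites")

    wa = float((ma[:, None] * ma[None, :] * _diff_matrix(sa, sa)).sum()) / 2.0
    wb = float((mb[:, None] * mb[None, :] * _diff_matrix(sb, sb)).sum()) / 2.0
    pa = hapsA.N * (hapsA.N - 1) / 2.0
    pb = hapsB.N * (hapsB.N - 1) / 2.0
    if weighting == "pooled":
        hw = (wa + wb) / (pa + pb)
    elif weighting == "mean_of_pops":
        hw = (wa / pa + wb / pb) / 2.0
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    hb = float((ma[:, None] * mb[None, :] * _diff_matrix(sa, sb)).sum())
    hb /= hapsA.N * hapsB.N
    if hb == 0.0:
        return 0.0
    return 1.0 - hw / hb


def fst_matrix(
    pools: Sequence[HaplotypeSet], weighting: str = "mean_of_pops"
) -> np.ndarray:
    """Symmetric pairwise F_ST matrix (NaN diagonal)."""
    k = len(pools)
    out = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = pairwise_fst_hudson(pools[i], pools[j], weighting)
    return out


def _expand_individuals(pools: Sequence[HaplotypeSet]) -> tuple[np.ndarray, list[int]]:
    rows = []
    sizes = []
    for hs in pools:
        n = 0
        for hap, mult in hs.haplotypes:
            rows.extend([np.frombuffer(hap.encode(), dtype=np.uint8)] * mult)
            n += mult
        sizes.append(n)
    width = len(rows[0]) if rows else 0
    mat = np.array(rows, dtype=np.uint8).reshape(len(rows), width)
    return mat, sizes


def amova_phist(
    pools: Sequence[HaplotypeSet],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Single-level AMOVA Phi_ST with a permutation test.

    Squared distances between individuals are their pairwise difference
    counts. Sums of squares are partitioned into among- and
    within-population components (with the usual unequal-sample-size
    coefficient n_c); Phi_ST = sigma2_among / (sigma2_among +
    sigma2_within). The p-value is the proportion of ``n_perm``
    permutations of individuals among pools (pool sizes fixed) whose
    Phi_ST reaches the observed value, with a +1/(n_perm+1)
    correction. Returns (NaN, NaN) when all sequences are identical.
    """
    if len(pools) < 2:
        raise ValueError("need >= 2 pools")
    mat, sizes = _expand_individuals(pools)
    n = mat.shape[0]
    if n < 3:
        raise ValueError("need >= 3 individuals in total")
    D = _diff_matrix(mat, mat).astype(np.float64)
    if not D.any():
        return float("nan"), float("nan")

    k = len(sizes)
    bounds = np.cumsum([0] + sizes)
    n_c = (n - sum(s * s for s in sizes) / n) / (k - 1)

    def phi(order: np.ndarray) -> float:
        ssd_within = 0.0
        for g in range(k):
            idx = order[bounds[g]:bounds[g + 1]]
            ssd_within += D[np.ix_(idx, idx)].sum() / 2.0 / sizes[g]
        ssd_total = D.sum() / 2.0 / n
        ssd_among = ssd_total - ssd_within
        sigma_w = ssd_within / (n - k)
        sigma_a = (ssd_among / (k - 1) - sigma_w) / n_c
        denom = sigma_a + sigma_w
        return sigma_a / denom if denom > 0 else float("nan")

    identity = np.arange(n)
    observed = phi(identity)
    if math.isnan(observed):
        return float("nan"), float("nan")

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if phi(rng.permutation(n)) >= observed - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return float(observed), float(p)


@dataclass(frozen=True)
class PopGenEstimates:
    """Bundle of per-pool pi, the F_ST matrix, and overall Phi_ST."""

    pool_ids: tuple[str, ...]
    pi: dict[str, float]
    fst: np.ndarray
    phi_st: float
    phi_p: float
    n_permutations: int

    def to_dict(self) -> dict:
        return {
            "pool_ids": list(self.pool_ids),
            "pi": {k: v for k, v in self.pi.items()},
            "fst": [[None if np.isnan(v) else float(v) for v in row] for row in self.fst],
            "phi_st": None if np.isnan(self.phi_st) else float(self.phi_st),
            "phi_p": None if np.isnan(self.phi_p) else float(self.phi_p),
            "n_permutations": self.n_permutations,
        }


def estimate_all(
    pools: Sequence[HaplotypeSet],
    L: int,
    n_perm: int = 1000,
    seed: int = 0,
    weighting: str = "mean_of_pops",
) -> PopGenEstimates:
    """pi per pool, full F_ST matrix, and AMOVA Phi_ST in one pass."""
    pool_ids = tuple(hs.pool_id for hs in pools)
    pi = {hs.pool_id: nucleotide_diversity(hs, L) for hs in pools}
    fst = fst_matrix(pools, weighting)
    phi, p = amova_phist(pools, n_perm=n_perm, seed=seed)
    return PopGenEstimates(
        pool_ids=pool_ids, pi=pi, fst=fst, phi_st=phi, phi_p=p,
        n_permutations=n_perm,
    )


def write_estimates(est: PopGenEstimates, pi_path, fst_path, phi_path) -> None:
    with open(pi_path, "w") as fh:
        fh.write("pool_id\tpi\n")
        for pid in est.pool_ids:
            fh.write(f"{pid}\t{est.pi[pid]:.6g}\n")
    with open(fst_path, "w") as fh:
        fh.write("pool_id\t" + "\t".join(est.pool_ids) + "\n")
        for i, pid in enumerate(est.pool_ids):
            row = "\t".join(
                "." if np.isnan(v) else f"{v:.6g}" for v in est.fst[i]
            )
            fh.write(f"{pid}\t{row}\n")
    with open(phi_path, "w") as fh:
        json.dump(
            {
                "phi_st": None if np.isnan(est.phi_st) else est.phi_st,
                "p": None if np.isnan(est.phi_p) else est.phi_p,
                "n_permutations": est.n_permutations,
            },
            fh,
            indent=2,
        )
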