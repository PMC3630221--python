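"""Barcode (tag) design and exact-match demultiplexing.

Population pools are identified by short synthetic tags ligated to the 5'
end of every read. Tags are designed with a minimum pairwise substitution
(Hamming) distance so that sequencing errors cannot silently convert one
tag into another; demultiplexing requires a complete, mismatch-free tag
and strips it before mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

_NUCS = "ACGT"


def hamming(a: str, b: str) -> int:
    """Substitution distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class BarcodeSet:
    """A set of equal-length DNA tags with a guaranteed minimum distance."""

    tags: tuple[str, ...]
    min_distance: int

    def __post_init__(self) -> None:
        lengths = {len(t) for t in self.tags}
        if len(lengths) > 1:
            raise ValueError("all tags must have the same length")
        if len(set(self.tags)) != len(self.tags):
            raise ValueError("tags must be unique")
        for i, a in enumerate(self.tags):
            for b in self.tags[i + 1 :]:
                if hamming(a, b) < self.min_distance:
                    raise ValueError(
                        f"tags {a!r} and {b!r} violate min_distance={self.min_distance}"
                    )

    @property
    def tag_length(self) -> int:
        return len(self.tags[0]) if self.tags else 0

    def min_pairwise_distance(self) -> int:
        """Smallest Hamming distance over all tag pairs (0 if < 2 tags)."""
        if len(self.tags) < 2:
            return 0
        return min(
            hamming(a, b)
            for i, a in enumerate(self.tags)
            for b in self.tags[i + 1 :]
        )


class BarcodeDesignError(RuntimeError):
    """Raised when the requested number of tags cannot be found."""

    def __init__(self, requested: int, found: int, attempts: int):
        self.requested = requested
        self.found = found
        super().__init__(
            f"could only design {found} of {requested} tags "
            f"after {attempts} random attempts"
        )


def design_barcodes(
    k: int,
    length: int = 8,
    min_dist: int = 3,
    seed: int = 0,
    max_attempts_per_tag: int = 5000,
) -> BarcodeSet:
    """Design ``k`` random tags with pairwise Hamming distance >= ``min_dist``.

    Greedy rejection sampling: random tags are drawn and kept only when
    they respect the distance constraint against every tag accepted so
    far. Deterministic for a fixed seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if min_dist > length:
        raise ValueError("min_dist cannot exceed tag length")
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    attempts = 0
    budget = max_attempts_per_tag * k
    while len(accepted) < k and attempts < budget:
        attempts += 1
        tag = "".join(_NUCS[i] for i in rng.integers(0, 4, size=length))
        if all(hamming(tag, t) >= min_dist for t in accepted) and tag not in accepted:
            accepted.append(tag)
    if len(accepted) < k:
        raise BarcodeDesignError(k, len(accepted), attempts)
    return BarcodeSet(tags=tuple(accepted), min_distance=min_dist)


def demultiplex(
    reads: Iterable,
    pool_tags: Mapping[str, str],
) -> tuple[dict[str, list], int]:
    """Assign reads to pools by exact 5' tag match and strip the tag.

    Parameters
    ----------
    reads
        Iterable of Bio.SeqRecord objects (FASTQ records with
        ``letter_annotations["phred_quality"]``).
    pool_tags
        Mapping pool_id -> tag. All tags must share one length and be
        unique, so assignment is unambiguous.

    Returns
    -------
    (assignments, unassigned)
        ``assignments[pool_id]`` is the list of tag-stripped records
        whose first ``len(tag)`` bases equal that pool's tag exactly;
        ``unassigned`` counts every other read (including reads shorter
        than the tag). Assigned + unassigned == total reads.
    """
    tags = list(pool_tags.values())
    if len(set(tags)) != len(tags):
        raise ValueError("pool tags must be unique")
    lengths = {len(t) for t in tags}
    if len(lengths) != 1:
        raise ValueError("all pool tags must have the same length")
    tag_len = lengths.pop()
    tag_to_pool = {t: p for p, t in pool_tags.items()}

    assignments: dict[str, list] = {pool_id: [] for pool_id in pool_tags}
    unassigned = 0
    for rec in reads:
        prefix = str(rec.seq[:tag_len])
        pool = tag_to_pool.get(prefix) if len(rec.seq) >= tag_len else None
        if pool is None:
            unassigned += 1
        else:
            assignments[pool].append(rec[tag_len:])
    return assignments, unassigned
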