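"""Read-to-amplicon alignment with similarity / length-fraction filters.

Reads are sub-fragments of short amplicon references, so alignment is
semi-global: the read is fully scored while end-gaps on the reference
are free. The cost scheme is the one used throughout the analysis:
match 0, mismatch 2, insertion 2, deletion 2. A mapping is accepted
only when the read shows more than 90% similarity to the reference
over at least 75% of its length.

Because mismatch, insertion and deletion all cost the same, the
minimum-cost alignment is exactly twice the Levenshtein distance, and
the default engine delegates the distance computation to edlib (infix
mode) for speed; ``align_semi_global`` is the explicit dynamic
programme with deterministic tie-breaking, used as the reference
engine and for verification.

Definitions fixed here (the originating toolchain's are undocumented):
the aligned region is the alignment after trimming terminal non-match
columns; ``similarity`` is matches divided by all columns of that
region (read bases plus read gaps); ``aligned_read_fraction`` is the
number of read bases inside the region divided by read length.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
from Bio.Seq import Seq


@dataclass(frozen=True)
class AlignmentParams:
    mismatch_cost: int = 2
    insertion_cost: int = 2
    deletion_cost: int = 2
    length_fraction: float = 0.75
    similarity_fraction: float = 0.9

    def __post_init__(self) -> None:
        if min(self.mismatch_cost, self.insertion_cost, self.deletion_cost) <= 0:
            raise ValueError("costs must be positive")
        for f in (self.length_fraction, self.similarity_fraction):
            if not 0.0 < f <= 1.0:
                raise ValueError("fractions must lie in (0,1]")


@dataclass
class MappedRead:
    """An accepted alignment of one read to one reference.

    ``ref_positions``/``bases``/``quals`` give, for every
    reference-consuming matched column, the 0-based reference position,
    the read base in reference orientation, and its quality; deletions
    contribute no base, insertions no reference position.
    """

    read_id: str
    reference_name: str
    ref_start: int
    ref_end: int
    strand: str
    ref_positions: np.ndarray
    bases: np.ndarray  # dtype '<U1'
    quals: np.ndarray
    similarity: float
    aligned_read_fraction: float


# ---------------------------------------------------------------------------
# explicit dynamic programme

def align_semi_global(
    read: str, reference: str, params: AlignmentParams = AlignmentParams()
) -> tuple[int, list[tuple[Optional[int], Optional[int]]]]:
    """Minimum-cost semi-global alignment (free reference end-gaps).

    Returns ``(cost, aligned_pairs)`` where each pair is
    ``(read_index or None, reference_index or None)`` over the aligned
    region. Ties are broken preferring diagonal (match/mismatch) over
    deletion (reference gap consumed) over insertion, and the smallest
    reference end position.
    """
    if not read or not reference:
        raise ValueError("sequences must be non-empty")
    m, n = len(read), len(reference)
    mis, ins, dele = params.mismatch_cost, params.insertion_cost, params.deletion_cost
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    t = np.frombuffer(reference.encode(), dtype=np.uint8)

    D = np.empty((m + 1, n + 1), dtype=np.int32)
    D[0, :] = 0  # free leading gap on the reference
    js = np.arange(n + 1, dtype=np.int64)
    for i in range(1, m + 1):
        sub = np.where(t == r[i - 1], 0, mis)
        base = np.empty(n + 1, dtype=np.int64)
        base[0] = i * ins
        base[1:] = np.minimum(D[i - 1, :-1] + sub, D[i - 1, 1:] + ins)
        # horizontal (deletion) closure: cur[j] = min_k<=j base[k] + (j-k)*del
        D[i, :] = np.minimum.accumulate(base - js * dele) + js * dele

    j = int(np.argmin(D[m, :]))  # smallest reference end on ties
    cost = int(D[m, j])

    pairs: list[tuple[Optional[int], Optional[int]]] = []
    i = m
    while i > 0:
        here = D[i, j]
        if j > 0 and here == D[i - 1, j - 1] + (0 if read[i - 1] == reference[j - 1] else mis):
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif j > 0 and here == D[i, j - 1] + dele:
            pairs.append((None, j - 1))
            j -= 1
        else:
            pairs.append((i - 1, None))
            i -= 1
    pairs.reverse()
    return cost, pairs


# ---------------------------------------------------------------------------
# candidate evaluation shared by both engines

def _edlib_pairs(
    read: str, reference: str, params: AlignmentParams
) -> tuple[int, list[tuple[Optional[int], Optional[int]]]]:
    """edlib infix alignment, canonicalised to the DP tie-breaking.

    With equal mismatch/indel costs, a pair of nearby substitutions can
    have a co-optimal insertion+deletion representation, and edlib may
    return either — displacing alleles off their true positions. Any
    path containing indels is therefore recomputed with the exact DP
    (which prefers match/mismatch on ties) over a window around the
    edlib hit; pure-substitution paths are already canonical.
    """
    # cheap screen: an accepted mapping keeps >= length_fraction of the
    # read at >= similarity_fraction, so its edit distance is bounded by
    # roughly (1 - similarity) + (1 - length_fraction) of the read
    # length; anything beyond (wrong strand, wrong locus) is rejected
    # without computing or canonicalising a full path.
    max_dist = int(
        len(read)
        * ((1.0 - params.similarity_fraction) + (1.0 - params.length_fraction))
        + 1
    )
    dist = edlib.align(read, reference, mode="HW", task="distance")["editDistance"]
    if dist > max_dist:
        return 2 * dist, []
    res = edlib.align(read, reference, mode="HW", task="path")
    tstart = res["locations"][0][0]
    qpos, tpos = 0, tstart
    pairs: list[tuple[Optional[int], Optional[int]]] = []
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        k = int(num)
        num = ""
        if ch in "=X":
            pairs.extend((qpos + x, tpos + x) for x in range(k))
            qpos += k
            tpos += k
        elif ch == "I":  # read base absent from reference
            pairs.extend((qpos + x, None) for x in range(k))
            qpos += k
        elif ch == "D":  # reference base absent from read
            pairs.extend((None, tpos + x) for x in range(k))
            tpos += k
    if "I" in res["cigar"] or "D" in res["cigar"]:
        pairs = _canonicalize_pairs(
            read, reference, pairs, params, res["editDistance"]
        )
    return 2 * res["editDistance"], pairs


def _align_global(
    read: str, reference: str, params: AlignmentParams
) -> list[tuple[Optional[int], Optional[int]]]:
    """Global minimum-cost alignment of two short segments.

    Plain DP with the same tie-breaking as ``align_semi_global``
    (match/mismatch over deletion over insertion); both sequences are
    consumed entirely. Used to canonicalise small alignment windows.
    """
    m, n = len(read), len(reference)
    mis, ins, dele = params.mismatch_cost, params.insertion_cost, params.deletion_cost
    D = [[0] * (n + 1) for _ in range(m + 1)]
    for j in range(1, n + 1):
        D[0][j] = j * dele
    for i in range(1, m + 1):
        D[i][0] = i * ins
        row, prev = D[i], D[i - 1]
        rc = read[i - 1]
        for j in range(1, n + 1):
            row[j] = min(
                prev[j - 1] + (0 if rc == reference[j - 1] else mis),
                row[j - 1] + dele,
                prev[j] + ins,
            )
    pairs: list[tuple[Optional[int], Optional[int]]] = []
    i, j = m, n
    while i > 0 or j > 0:
        here = D[i][j]
        if i > 0 and j > 0 and here == D[i - 1][j - 1] + (
            0 if read[i - 1] == reference[j - 1] else mis
        ):
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif j > 0 and here == D[i][j - 1] + dele:
            pairs.append((None, j - 1))
            j -= 1
        else:
            pairs.append((i - 1, None))
            i -= 1
    pairs.reverse()
    return pairs


def _canonicalize_pairs(
    read: str,
    reference: str,
    pairs: list[tuple[Optional[int], Optional[int]]],
    params: AlignmentParams,
    edit_distance: int,
) -> list[tuple[Optional[int], Optional[int]]]:
    """Recompute small windows around indel columns with the canonical DP.

    Indel columns are clustered (gap > 40 columns starts a new
    cluster) and each cluster's window, padded by 10 columns, is
    realigned globally; endpoints anchor on the surrounding path, so
    the overall cost is unchanged while co-optimal indel renderings of
    substitution pairs collapse back to substitutions at their true
    positions. A co-optimal indel pair farther apart than a window
    would require a coincidental repeat longer than the padding and is
    left as returned.
    """
    indel_cols = [k for k, (rp, tp) in enumerate(pairs) if rp is None or tp is None]
    if not indel_cols:
        return pairs
    clusters: list[list[int]] = [[indel_cols[0]]]
    for c in indel_cols[1:]:
        if c - clusters[-1][-1] > 40:
            clusters.append([c])
        else:
            clusters[-1].append(c)

    pad = 10
    out = list(pairs)
    for cluster in reversed(clusters):  # right-to-left keeps indices valid
        lo = max(0, cluster[0] - pad)
        hi = min(len(pairs), cluster[-1] + 1 + pad)
        window = out[lo:hi]
        read_idx = [rp for rp, _ in window if rp is not None]
        ref_idx = [tp for _, tp in window if tp is not None]
        if not read_idx or not ref_idx:
            continue
        r0, r1 = read_idx[0], read_idx[-1] + 1
        t0, t1 = ref_idx[0], ref_idx[-1] + 1
        local = _align_global(read[r0:r1], reference[t0:t1], params)
        fixed = [
            (rp + r0 if rp is not None else None,
             tp + t0 if tp is not None else None)
            for rp, tp in local
        ]
        out[lo:hi] = fixed
    return out


def _evaluate(
    read: str,
    quals: Sequence[int],
    reference: str,
    pairs: list[tuple[Optional[int], Optional[int]]],
) -> Optional[dict]:
    """Trim terminal non-match columns and compute the filter quantities."""
    is_match = [
        rp is not None and tp is not None and read[rp] == reference[tp]
        for rp, tp in pairs
    ]
    if not any(is_match):
        return None
    lo = is_match.index(True)
    hi = len(is_match) - 1 - is_match[::-1].index(True)
    region = pairs[lo : hi + 1]
    n_match = sum(is_match[lo : hi + 1])
    n_read_bases = sum(1 for rp, _ in region if rp is not None)
    similarity = n_match / len(region)
    fraction = n_read_bases / len(read)

    ref_positions, bases, qs = [], [], []
    for rp, tp in region:
        if rp is not None and tp is not None:
            ref_positions.append(tp)
            bases.append(read[rp])
            qs.append(quals[rp])
    return {
        "similarity": similarity,
        "fraction": fraction,
        "ref_start": region[0][1] if region[0][1] is not None else ref_positions[0],
        "ref_end": (region[-1][1] + 1) if region[-1][1] is not None else ref_positions[-1] + 1,
        "ref_positions": np.asarray(ref_positions, dtype=np.int32),
        "bases": np.asarray(bases, dtype="<U1"),
        "quals": np.asarray(qs, dtype=np.int16),
    }


def map_read(
    record,
    references: Sequence[tuple[str, str]],
    params: AlignmentParams = AlignmentParams(),
    engine: str = "edlib",
) -> tuple[Optional[MappedRead], Optional[str]]:
    """Map one FASTQ record against every reference on both strands.

    Returns ``(mapped, None)`` for the best accepted candidate by
    similarity (ties: manifest order of references, then forward
    strand) or ``(None, reason)`` when every candidate fails the
    length-fraction / similarity filters.
    """
    seq = str(record.seq)
    quals = record.letter_annotations.get("phred_quality", [0] * len(seq))
    if not seq:
        return None, "empty_read"
    rc = str(Seq(seq).reverse_complement())
    rc_quals = list(reversed(quals))

    best: Optional[MappedRead] = None
    best_reason = "no_alignment"
    for ref_name, ref_seq in references:
        for strand, oriented, oq in (("+", seq, quals), ("-", rc, rc_quals)):
            if engine == "edlib":
                _, pairs = _edlib_pairs(oriented, ref_seq, params)
            elif engine == "dp":
                _, pairs = align_semi_global(oriented, ref_seq, params)
            else:
                raise ValueError(f"unknown engine {engine!r}")
            ev = _evaluate(oriented, oq, ref_seq, pairs)
            if ev is None:
                continue
            if ev["fraction"] < params.length_fraction:
                best_reason = "low_aligned_fraction"
                continue
            if ev["similarity"] < params.similarity_fraction:
                if best_reason != "low_aligned_fraction":
                    best_reason = "low_similarity"
                continue
            if best is None or ev["similarity"] > best.similarity:
                best = MappedRead(
                    read_id=record.id,
                    reference_name=ref_name,
                    ref_start=int(ev["ref_start"]),
                    ref_end=int(ev["ref_end"]),
                    strand=strand,
                    ref_positions=ev["ref_positions"],
                    bases=ev["bases"],
                    quals=ev["quals"],
                    similarity=ev["similarity"],
                    aligned_read_fraction=ev["fraction"],
                )
    if best is None:
        return None, best_reason
    return best, None


def map_reads(
    records: Iterable,
    references: Sequence[tuple[str, str]],
    params: AlignmentParams = AlignmentParams(),
    engine: str = "edlib",
) -> tuple[list[MappedRead], Counter]:
    """Map a read collection; returns accepted mappings and rejection tallies."""
    accepted: list[MappedRead] = []
    rejected: Counter = Counter()
    for rec in records:
        mapped, reason = map_read(rec, references, params, engine)
        if mapped is None:
            rejected[reason] += 1
        else:
            accepted.append(mapped)
    return accepted, rejected


def write_mappings_tsv(mappings: Sequence[MappedRead], path) -> None:
    """Human-readable mapping table (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("read_id\treference\tstart\tend\tstrand\tsimilarity\taligned_read_fraction\n")
        for m in mappings:
            fh.write(
                f"{m.read_id}\t{m.reference_name}\t{m.ref_start + 1}\t{m.ref_end}"
                f"\t{m.strand}\t{m.similarity:.4f}\t{m.aligned_read_fraction:.4f}\n"
            )
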