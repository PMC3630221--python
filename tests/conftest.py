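import numpy as np
import pytest

from pooltag.mapping import MappedRead
from pooltag import simdata


def make_mapped(
    bases: str,
    start: int = 0,
    read_id: str = "r",
    qual: int = 30,
    ref_name: str = "ref",
    strand: str = "+",
) -> MappedRead:
    """A synthetic accepted mapping: contiguous match columns only."""
    n = len(bases)
    return MappedRead(
        read_id=read_id,
        reference_name=ref_name,
        ref_start=start,
        ref_end=start + n,
        strand=strand,
        ref_positions=np.arange(start, start + n, dtype=np.int32),
        bases=np.asarray(list(bases), dtype="<U1"),
        quals=np.full(n, qual, dtype=np.int16),
        similarity=1.0,
        aligned_read_fraction=1.0,
    )


@pytest.fixture
def small_locus() -> simdata.LocusModel:
    """A 60-bp single-amplicon locus, fixed sequence."""
    return simdata.single_amplicon_locus(length=60, seed=11)


@pytest.fixture
def study_truths():
    """Twenty structured pools at the study's sizes on a 420-bp amplicon."""
    locus = simdata.single_amplicon_locus(seed=7)
    sizes = simdata.study_pool_sizes(20, 93, seed=7)
    truths = simdata.generate_structured_populations(20, sizes, locus, seed=7)
    return locus, truths
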