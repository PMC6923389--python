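import numpy as np
import pytest

from adenoclone.pileup import ALLELE_INDEX, ALLELES, AlleleCounts, TargetRegion


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_region():
    return TargetRegion("AMP1", "chr12", 1000, 1020)


def make_counts(
    sample_id,
    region,
    allele_fracs,
    depth=1000,
    ref="A",
):
    """Deterministic AlleleCounts with exact per-allele counts.

    ``allele_fracs`` maps position offset -> {allele: fraction}; the
    remainder goes to the reference allele.  Counts split evenly between
    strands (odd remainders land on the forward strand).
    """
    n = len(region)
    refs = np.full(n, ref, dtype="<U1")
    counts = np.zeros((n, 4, 2), dtype=np.int64)
    for i in range(n):
        fracs = dict(allele_fracs.get(i, {}))
        ref_frac = 1.0 - sum(fracs.values())
        fracs[refs[i]] = fracs.get(refs[i], 0.0) + ref_frac
        total = 0
        for a in ALLELES:
            c = int(round(depth * fracs.get(a, 0.0)))
            counts[i, ALLELE_INDEX[a], 0] = (c + 1) // 2
            counts[i, ALLELE_INDEX[a], 1] = c // 2
            total += c
        # absorb rounding drift into the reference allele
        drift = depth - total
        counts[i, ALLELE_INDEX[refs[i]], 0] += drift
    return AlleleCounts(
        sample_id=sample_id,
        region_id=region.region_id,
        positions=np.arange(region.start, region.end),
        ref=refs,
        counts=counts,
    )
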