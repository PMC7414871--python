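import numpy as np
import pytest

from founderscan.formats_io import GeneticMap, IBDSegment, PhasedCohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def simple_map():
    """One chromosome "1": 1 bp -> 0 cM, 10 Mb -> 100 cM (uniform 10 cM/Mb)."""
    return GeneticMap({"1": (np.array([1, 10_000_000]),
                             np.array([0.0, 100.0]))})


def make_cohort(haps: np.ndarray, positions=None, chrom="1",
                sample_ids=None, mutation_labels=None) -> PhasedCohort:
    """Assemble a PhasedCohort from a (n, 2, m) 0/1 array."""
    n, _, m = haps.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    positions = np.asarray(positions, dtype=np.int64)
    return PhasedCohort(
        sample_ids=sample_ids or [f"S{i}" for i in range(n)],
        chrom=np.full(m, chrom),
        pos=positions,
        ref=np.full(m, "A"),
        alt=np.full(m, "G"),
        variant_ids=np.array([f"{chrom}:{p}" for p in positions]),
        haplotypes=haps.astype(np.int8),
        mutation_labels=mutation_labels or {},
    )


def make_segment(sample_a="A", sample_b="B", hap_a=0, hap_b=0, chrom="1",
                 start_bp=1, end_bp=1_000_000, gmap=None,
                 start_cm=None, end_cm=None) -> IBDSegment:
    if gmap is not None:
        start_cm = float(gmap.interpolate(chrom, start_bp))
        end_cm = float(gmap.interpolate(chrom, end_bp))
    return IBDSegment(
        sample_a=sample_a, hap_a=hap_a, sample_b=sample_b, hap_b=hap_b,
        chrom=chrom, start_bp=start_bp, end_bp=end_bp,
        start_cm=start_cm, end_cm=end_cm, length_cm=end_cm - start_cm,
    )
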