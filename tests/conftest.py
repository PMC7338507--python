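import numpy as np
import pytest

from ighquant.locus import GenomicInterval, LocusModel
from ighquant.synthetic import CohortSimConfig, simulate_cohort


@pytest.fixture
def toy_model() -> LocusModel:
    """Two-class locus with known interval structure on chr14."""
    return LocusModel(
        classes={
            "IGHG1": [GenomicInterval("chr14", 100, 200), GenomicInterval("chr14", 300, 420)],
            "IGHA2": [GenomicInterval("chr14", 1000, 1150)],
        }
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 1500-sample simulated cohort shared across survival tests."""
    table, betas = simulate_cohort(CohortSimConfig(n=1500, seed=42))
    return table, betas


def brute_force_overlap(pos, cigar_ops, intervals, chrom="chr14"):
    """Independent per-position oracle: walk the CIGAR one base at a time.

    Counts aligned read bases (M/=/X) whose reference position falls in the
    union of interval positions.  Deliberately naive; used to check the
    segment-overlap arithmetic of the quantifier.
    """
    inside = set()
    for iv in intervals:
        if iv.chrom == chrom:
            inside.update(range(iv.start, iv.end))
    ref = pos
    hits = 0
    for op, length in cigar_ops:
        if op in "M=X":
            for _ in range(length):
                if ref in inside:
                    hits += 1
                ref += 1
        elif op in "DN":
            ref += length
    return hits


def random_read(rng: np.random.Generator):
    """A random mapped read: position and CIGAR over {M,I,D,N,S,=,X}."""
    pos = int(rng.integers(0, 500))
    n_ops = int(rng.integers(1, 7))
    ops = []
    for i in range(n_ops):
        op = rng.choice(list("MIDNS=X"))
        if op == "S" and 0 < i < n_ops - 1:
            op = "M"  # clips only at the ends, as in real CIGARs
        ops.append((str(op), int(rng.integers(1, 120))))
    if all(op not in "M=X" for op, _ in ops):
        ops.append(("M", int(rng.integers(1, 120))))
    return pos, ops


def random_intervals(rng: np.random.Generator, chrom="chr14"):
    from ighquant.locus import merge_intervals

    ivs = []
    for _ in range(int(rng.integers(1, 6))):
        start = int(rng.integers(0, 900))
        ivs.append(GenomicInterval(chrom, start, start + int(rng.integers(1, 150))))
    return merge_intervals(ivs)
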