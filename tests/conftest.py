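import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from somaspike.reads import AlignedRead
from somaspike.synthgenome import (
    GermlineSet,
    Reference,
    make_reference,
    place_germline_variants,
    simulate_normal_reads,
)


def make_read(
    contig="chr1",
    pos=1,
    seq="ACGT",
    cigar=None,
    qual=37,
    mapq=60,
    fragment_id="f0",
    mate=1,
    strand="+",
    origin="normal",
):
    """Hand-rolled read for directed fixtures."""
    return AlignedRead(
        read_id=f"{fragment_id}/{mate}",
        contig=contig,
        pos=pos,
        cigar=cigar or f"{len(seq)}M",
        seq=seq,
        quals=np.full(len(seq), qual, dtype=np.uint8),
        mapq=mapq,
        strand=strand,
        fragment_id=fragment_id,
        origin=origin,
    )


@pytest.fixture(scope="session")
def small_ref():
    return make_reference(1, 20_000, 0.45, seed=11)


@pytest.fixture(scope="session")
def small_germline(small_ref):
    return place_germline_variants(small_ref, 1e-3, 1e-4, seed=12)


@pytest.fixture(scope="session")
def small_normal_reads(small_ref, small_germline):
    return simulate_normal_reads(
        small_ref, small_germline, coverage=60, error_rate=0.002, seed=13
    )


@pytest.fixture(scope="session")
def clean_ref():
    """Germline-free substrate for spike-focused tests."""
    return make_reference(1, 30_000, 0.5, seed=21)


@pytest.fixture(scope="session")
def clean_normal_reads(clean_ref):
    return simulate_normal_reads(clean_ref, None, coverage=80, error_rate=0.0, seed=22)
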