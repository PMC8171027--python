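"""Shared fixtures: tiny hand-built objects plus the session-wide benchmark."""

import numpy as np
import pytest

from sslvar.genomic_io import EpigeneticTrack, Genome, GenomicLocus, merge_intervals
from sslvar.synthetic_data import default_benchmark


@pytest.fixture()
def toy_genome() -> Genome:
    rng = np.random.default_rng(7)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return Genome({
        "chr1": bases[rng.integers(0, 4, 500)].tobytes().decode(),
        "chr2": bases[rng.integers(0, 4, 400)].tobytes().decode(),
    })


def make_track(mark: str, intervals) -> EpigeneticTrack:
    """Build a track from raw (chrom, start, end, score) tuples, merging overlaps."""
    track = EpigeneticTrack(mark_name=mark)
    per_chrom: dict = {}
    for chrom, s, e, v in intervals:
        per_chrom.setdefault(chrom, []).append((s, e, v))
    for chrom, items in per_chrom.items():
        track.intervals[chrom] = merge_intervals(items)
    return track


@pytest.fixture()
def toy_track() -> EpigeneticTrack:
    return make_track("DNase", [("chr1", 10, 20, 3.0), ("chr1", 30, 40, 5.0)])


@pytest.fixture()
def toy_locus() -> GenomicLocus:
    return GenomicLocus("chr1", 100, 1, "cellX")


def dense_profile(intervals, length: int) -> np.ndarray:
    """Brute-force per-base maximum profile: the oracle for track scoring."""
    out = np.zeros(length)
    for s, e, v in intervals:
        for b in range(max(s, 0), min(e, length)):
            out[b] = max(out[b], v)
    return out


@pytest.fixture(scope="session")
def bundle():
    """The default two-cell-line synthetic benchmark (seed 1)."""
    return default_benchmark(seed=1)


@pytest.fixture(scope="session")
def tables(bundle):
    """Per-cell feature tables built through the standard pipeline."""
    return bundle.feature_tables()
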