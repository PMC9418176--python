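import numpy as np
import pandas as pd
import pytest

from attenpipe.core import GenomicInterval, Peak, PeakSet, SignalTrack


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_track():
    """Two-chromosome step track used across signal tests."""
    return SignalTrack(
        {
            "chr1": [(0, 100, 2.0), (100, 200, 4.0), (300, 400, 1.0)],
            "chr2": [(50, 150, 3.0)],
        }
    )


@pytest.fixture
def small_peaks():
    return PeakSet(
        "test",
        [
            Peak(GenomicInterval("chr1", 0, 200), "p1", 1.0),
            Peak(GenomicInterval("chr1", 300, 400), "p2", 2.0),
            Peak(GenomicInterval("chr2", 40, 160), "p3", 3.0),
        ],
    )


def random_peakset(rng, n=50, name="rand", chroms=("chr1", "chr2"), with_fdr=False):
    peaks = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, 100_000))
        end = start + int(rng.integers(1, 500))
        fdr = float(rng.random()) if with_fdr else None
        peaks.append(Peak(GenomicInterval(chrom, start, end), f"{name}_{i}", float(rng.random() * 10), fdr))
    return PeakSet(name, peaks)


def random_track(rng, n_steps=100, chroms=("chr1", "chr2"), max_pos=10_000):
    """Non-overlapping random steps laid out left to right per chromosome."""
    steps = {c: [] for c in chroms}
    for c in chroms:
        pos = 0
        for _ in range(n_steps // len(chroms)):
            pos += int(rng.integers(0, 50))
            width = int(rng.integers(1, 60))
            steps[c].append((pos, pos + width, float(rng.random() * 5)))
            pos += width
    return SignalTrack(steps)


def dense_expansion(steps, length):
    """Independent per-base oracle: expand raw (start, end, value) triples."""
    out = np.zeros(length)
    for s, e, v in steps:
        out[s:e] = v
    return out
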