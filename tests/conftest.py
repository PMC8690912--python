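import numpy as np
import pytest

from polpause.coverage import CoverageTrack, NormalizationInfo
from polpause.genome_io import ChromSizes, GeneModel, GenomicInterval


@pytest.fixture
def sizes():
    return ChromSizes({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def plus_gene():
    return GeneModel("geneP", GenomicInterval("chr1", 40_000, 50_000, "+"))


@pytest.fixture
def minus_gene():
    return GeneModel("geneM", GenomicInterval("chr1", 40_000, 50_000, "-"))


def make_track(sizes, value=0.0, bin_size=20, norm=None):
    """A track pre-filled with a constant value."""
    track = CoverageTrack(bin_size, sizes,
                          norm=norm or NormalizationInfo(1_000_000))
    for chrom in track.data:
        track.data[chrom][:] = value
    return track


def random_track(sizes, rng, bin_size=20):
    track = CoverageTrack(bin_size, sizes, norm=NormalizationInfo(1_000_000))
    for chrom in track.data:
        track.data[chrom][:] = rng.gamma(2.0, 1.0, size=len(track.data[chrom]))
    return track


def brute_force_coverage(fragments, chrom_length, bin_size, scale):
    """Per-base depth oracle, then bin-averaged. Independent of the
    difference-array implementation."""
    depth = np.zeros(chrom_length)
    for start, end in fragments:
        start, end = max(start, 0), min(end, chrom_length)
        for b in range(start, end):
            depth[b] += 1
    n_bins = int(np.ceil(chrom_length / bin_size))
    out = np.zeros(n_bins)
    for i in range(n_bins):
        chunk = depth[i * bin_size: min((i + 1) * bin_size, chrom_length)]
        out[i] = chunk.mean() * scale
    return out
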