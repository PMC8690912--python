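"""Binned, normalized occupancy tracks from aligned-read intervals.

The pipeline: reads (BED6) are extended to the expected fragment length
toward the interior of the sequenced fragment, per-base fragment depth is
computed, averaged within fixed-width bins (20 bp by default), and scaled
per million mapped reads (optionally by an exogenous spike-in factor).

Bin ``i`` of a track holds the *mean per-base depth* over
``[i*bin_size, (i+1)*bin_size)`` times the normalization factors, so the
conservation identity

    sum_bins(value * bin_width) = factor * sum(fragment lengths)

holds exactly for every track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genome_io import ChromSizes, GenomicInterval

DEFAULT_BIN_SIZE = 20
DEFAULT_EXTEND = 150


@dataclass(frozen=True)
class NormalizationInfo:
    """Scaling metadata attached to a coverage track."""

    total_mapped_reads: int
    spike_in_factor: float = 1.0
    is_ratio: bool = False
    pseudocount: float | None = None

    def __post_init__(self) -> None:
        if not self.is_ratio:
            if self.total_mapped_reads <= 0:
                raise ValueError("total_mapped_reads must be > 0")
            if self.spike_in_factor <= 0:
                raise ValueError("spike_in_factor must be > 0")

    @property
    def per_million_factor(self) -> float:
        return 1e6 / self.total_mapped_reads

    @property
    def scale(self) -> float:
        return self.per_million_factor * self.spike_in_factor


@dataclass
class CoverageTrack:
    """Binned density per chromosome, ``ceil(length / bin_size)`` bins each."""

    bin_size: int
    sizes: ChromSizes
    data: dict[str, np.ndarray] = field(default_factory=dict)
    norm: NormalizationInfo | None = None

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, length in self.sizes.items():
            n_bins = math.ceil(length / self.bin_size)
            if chrom not in self.data:
                self.data[chrom] = np.zeros(n_bins)
            elif len(self.data[chrom]) != n_bins:
                raise ValueError(
                    f"{chrom}: expected {n_bins} bins, got {len(self.data[chrom])}"
                )

    def total_signal(self) -> float:
        """Sum over bins of value x covered bin width (bp units)."""
        total = 0.0
        for chrom, arr in self.data.items():
            widths = _bin_widths(self.sizes[chrom], self.bin_size)
            total += float(np.dot(arr, widths))
        return total

    def scaled(self, c: float) -> "CoverageTrack":
        return CoverageTrack(
            self.bin_size, self.sizes,
            {k: v * c for k, v in self.data.items()}, self.norm,
        )

    def same_grid(self, other: "CoverageTrack") -> bool:
        return self.bin_size == other.bin_size and dict(self.sizes) == dict(other.sizes)


def _bin_widths(chrom_length: int, bin_size: int) -> np.ndarray:
    n_bins = math.ceil(chrom_length / bin_size)
    widths = np.full(n_bins, bin_size, dtype=float)
    rem = chrom_length - (n_bins - 1) * bin_size
    widths[-1] = rem
    return widths


# ---------------------------------------------------------------------------
# read extension
# ---------------------------------------------------------------------------

def extend_reads(
    reads: pd.DataFrame,
    sizes: ChromSizes,
    target_length: int = DEFAULT_EXTEND,
) -> pd.DataFrame:
    """Extend reads to ``target_length`` toward the fragment interior.

    ``+`` strand: ``[start, start + L)``; ``-`` strand: ``[end - L, end)``;
    results clipped to the chromosome. Reads already >= ``target_length``
    are returned unchanged. ``reads`` is a BED6-style DataFrame.
    """
    if (~reads["strand"].isin(["+", "-"])).any():
        bad = reads.index[~reads["strand"].isin(["+", "-"])][0]
        raise ValueError(f"read at row {bad} lacks a strand; extension is "
                         "strand-directed")
    out = reads.copy()
    length = out["end"] - out["start"]
    short = length < target_length
    plus = short & (out["strand"] == "+")
    minus = short & (out["strand"] == "-")
    out.loc[plus, "end"] = out.loc[plus, "start"] + target_length
    out.loc[minus, "start"] = out.loc[minus, "end"] - target_length
    chrom_len = out["chrom"].map(sizes)
    out["start"] = out["start"].clip(lower=0)
    out["end"] = np.minimum(out["end"], chrom_len)
    return out


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def compute_coverage(
    fragments: pd.DataFrame,
    sizes: ChromSizes,
    bin_size: int = DEFAULT_BIN_SIZE,
    norm: NormalizationInfo | None = None,
) -> CoverageTrack:
    """Bin-averaged, normalized fragment depth.

    Each bin value is the mean per-base fragment depth within the bin times
    ``norm.per_million_factor * norm.spike_in_factor``; fragments partially
    overlapping a bin contribute proportionally. ``norm`` defaults to
    per-million over the number of fragments supplied.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if norm is None:
        norm = NormalizationInfo(total_mapped_reads=max(len(fragments), 1))
    track = CoverageTrack(bin_size, sizes, norm=norm)
    scale = norm.scale
    for chrom, grp in fragments.groupby("chrom", sort=False, observed=True):
        if chrom not in sizes:
            raise KeyError(f"fragment chromosome {chrom!r} not in chrom sizes")
        length = sizes[chrom]
        starts = grp["start"].to_numpy(dtype=np.int64).clip(0, length)
        ends = grp["end"].to_numpy(dtype=np.int64).clip(0, length)
        diff = np.zeros(length + 1)
        np.add.at(diff, starts, 1.0)
        np.add.at(diff, ends, -1.0)
        depth = np.cumsum(diff[:-1])
        n_bins = math.ceil(length / bin_size)
        edges = np.arange(n_bins) * bin_size
        sums = np.add.reduceat(depth, edges)
        track.data[chrom] = sums / _bin_widths(length, bin_size) * scale
    return track


def spike_in_factor(sample_spike_reads: int, reference_spike_reads: int) -> float:
    """Exogenous-chromatin scaling: reference spike depth / sample spike depth.

    Scaling every sample by its factor equalizes spike-in coverage across
    samples, making endogenous signal comparable between conditions.
    """
    if sample_spike_reads <= 0 or reference_spike_reads <= 0:
        raise ValueError("spike-in read counts must be > 0")
    return reference_spike_reads / sample_spike_reads


def window_density(track: CoverageTrack, window: GenomicInterval | tuple,
                   ) -> float:
    """Length-weighted mean of bin values over a (possibly fractional) window.

    Accepts a GenomicInterval or a ``(chrom, start, end)`` tuple with float
    bounds (used for percent-scaled gene-body bins). Partial bins are
    weighted by their base overlap.
    """
    if isinstance(window, GenomicInterval):
        chrom, start, end = window.chrom, float(window.start), float(window.end)
    else:
        chrom, start, end = window[0], float(window[1]), float(window[2])
    if end <= start:
        raise ValueError(f"empty window [{start}, {end})")
    arr = track.data[chrom]
    bs = track.bin_size
    chrom_len = track.sizes[chrom]
    start = max(start, 0.0)
    end = min(end, float(chrom_len))
    if end <= start:
        raise ValueError("window entirely outside chromosome")
    first = int(start // bs)
    last = int(math.ceil(end / bs))
    idx = np.arange(first, last)
    lo = np.maximum(idx * bs, start)
    hi = np.minimum((idx + 1) * bs, end)
    w = hi - lo
    return float(np.dot(arr[first:last], w) / w.sum())


def normalized_occupancy(
    factor: CoverageTrack, polII: CoverageTrack, pseudocount: float = 0.1
) -> CoverageTrack:
    """Bin-wise factor/Pol II occupancy ratio, ``(f + eps) / (p + eps)``.

    Used to ask whether a factor is enriched relative to the polymerase
    itself rather than to input chromatin. Both tracks must share the bin
    grid. The result's metadata is marked as a ratio track.
    """
    if not factor.same_grid(polII):
        raise ValueError("tracks are on different bin grids")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    norm = NormalizationInfo(total_mapped_reads=1, is_ratio=True,
                             pseudocount=pseudocount)
    data = {
        chrom: (factor.data[chrom] + pseudocount) / (polII.data[chrom] + pseudocount)
        for chrom in factor.data
    }
    return CoverageTrack(factor.bin_size, factor.sizes, data, norm)


# ---------------------------------------------------------------------------
# bedGraph I/O
# ---------------------------------------------------------------------------

def write_bedgraph(track: CoverageTrack, path: str | Path,
                   header: str | None = None) -> None:
    """Write the track as fixed-step bedGraph (one line per non-zero run)."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            length = track.sizes[chrom]
            bs = track.bin_size
            for i, v in enumerate(arr):
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{i * bs}\t{min((i + 1) * bs, length)}\t{v:.6g}\n")


def read_bedgraph(path: str | Path, sizes: ChromSizes,
                  bin_size: int = DEFAULT_BIN_SIZE) -> CoverageTrack:
    track = CoverageTrack(bin_size, sizes)
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    for r in df.itertuples(index=False):
        if r.start % bin_size:
            raise ValueError(f"bedGraph step not aligned to {bin_size} bp grid")
        track.data[r.chrom][r.start // bin_size] = r.value
    return track
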