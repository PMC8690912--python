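"""Metagene profiles: fixed flanks plus a percent-scaled gene body.

Every gene is mapped onto a common axis of 200 upstream bins (-4 kb to the
TSS at 20 bp), ``body_bins`` equal-length body bins (percent of gene length),
and 200 downstream bins (TES to +4 kb). Vectors are oriented 5'->3' of the
gene, so index 0 is always 4 kb upstream of the biological TSS regardless of
strand. Flank bins that fall off a chromosome end are missing (NaN), not
zero — zero-filling would bias the averaged profile downward at the edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import CoverageTrack, window_density
from .genome_io import GeneModel

DEFAULT_FLANK = 4000
DEFAULT_BODY_BINS = 100


@dataclass
class MetageneProfile:
    upstream: np.ndarray
    body: np.ndarray
    downstream: np.ndarray
    n_genes: int
    aggregator: str = "mean"

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.upstream, self.body, self.downstream])

    def to_frame(self, bin_bp: int = 20) -> pd.DataFrame:
        labels = _column_labels(len(self.upstream), len(self.body),
                                len(self.downstream), bin_bp)
        return pd.DataFrame({"bin": labels, "value": self.values,
                             "n_genes": self.n_genes})


def _column_labels(n_up: int, n_body: int, n_down: int, bin_bp: int) -> list[str]:
    up = [f"u{-(n_up - i) * bin_bp}" for i in range(n_up)]
    body = [f"b{i}" for i in range(n_body)]
    down = [f"d+{(i + 1) * bin_bp}" for i in range(n_down)]
    return up + body + down


def _oriented_window(gene: GeneModel, rel_start: float, rel_end: float,
                     anchor: int) -> tuple[str, float, float]:
    """Map a transcription-direction window [rel_start, rel_end) anchored at
    ``anchor`` (TSS or TES) onto genomic coordinates."""
    if gene.strand == "+":
        return gene.chrom, anchor + rel_start, anchor + rel_end
    return gene.chrom, anchor - rel_end, anchor - rel_start


def gene_signal_vector(
    track: CoverageTrack,
    gene: GeneModel,
    flank: int = DEFAULT_FLANK,
    body_bins: int = DEFAULT_BODY_BINS,
) -> np.ndarray:
    """One row of the signal matrix for ``gene``.

    Flank bins are sampled at the track's bin width; body values are
    ``window_density`` over ``body_bins`` equal sub-intervals of the gene.
    Bins clipped at chromosome ends are NaN. Genes shorter than
    ``body_bins`` bases are rejected.
    """
    if gene.length < body_bins:
        raise ValueError(
            f"gene {gene.gene_id} ({gene.length} bp) shorter than "
            f"{body_bins} body bins")
    bs = track.bin_size
    n_flank = flank // bs
    chrom_len = track.sizes[gene.chrom]
    out = np.empty(2 * n_flank + body_bins)

    def sample(rel_start: float, rel_end: float, anchor: int) -> float:
        chrom, lo, hi = _oriented_window(gene, rel_start, rel_end, anchor)
        if lo < 0 or hi > chrom_len:
            return math.nan
        return window_density(track, (chrom, lo, hi))

    for i in range(n_flank):
        out[i] = sample(-flank + i * bs, -flank + (i + 1) * bs, gene.tss)
    step = gene.length / body_bins
    for i in range(body_bins):
        out[n_flank + i] = sample(i * step, (i + 1) * step, gene.tss)
    for i in range(n_flank):
        out[n_flank + body_bins + i] = sample(i * bs, (i + 1) * bs, gene.tes)
    return out


def signal_matrix(
    track: CoverageTrack,
    genes: list[GeneModel],
    flank: int = DEFAULT_FLANK,
    body_bins: int = DEFAULT_BODY_BINS,
) -> pd.DataFrame:
    """Per-gene signal vectors stacked as a DataFrame (rows in gene order)."""
    bs = track.bin_size
    rows = [gene_signal_vector(track, g, flank, body_bins) for g in genes]
    cols = _column_labels(flank // bs, body_bins, flank // bs, bs)
    return pd.DataFrame(rows, index=[g.gene_id for g in genes], columns=cols)


def aggregate_profile(matrix: pd.DataFrame, aggregator: str = "mean",
                      flank_bins: int | None = None) -> MetageneProfile:
    """Column-wise mean or median, ignoring missing entries."""
    if matrix.empty:
        raise ValueError("cannot aggregate an empty signal matrix")
    if aggregator == "mean":
        vals = np.nanmean(matrix.to_numpy(), axis=0)
    elif aggregator == "median":
        vals = np.nanmedian(matrix.to_numpy(), axis=0)
    else:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    if flank_bins is None:
        flank_bins = sum(c.startswith("u") for c in matrix.columns)
    n_down = sum(c.startswith("d") for c in matrix.columns)
    n_body = len(matrix.columns) - flank_bins - n_down
    return MetageneProfile(
        upstream=vals[:flank_bins],
        body=vals[flank_bins:flank_bins + n_body],
        downstream=vals[flank_bins + n_body:],
        n_genes=len(matrix),
        aggregator=aggregator,
    )
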