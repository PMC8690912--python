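"""Genomic interval primitives and annotation I/O.

All coordinates are 0-based half-open (BED convention) everywhere inside the
package. GTF input (1-based, closed) is converted on read. Gene models carry
strand-aware TSS/TES anchors: on the ``+`` strand the TSS is ``interval.start``
and the TES ``interval.end``; on ``-`` the anchors swap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Edge-to-edge gap in bp; negative magnitude 0 when overlapping."""
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        return max(other.start - self.end, self.start - other.end, 0)


@dataclass
class GeneModel:
    """A gene with strand-aware TSS/TES anchors and optional exon structure."""

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id} needs an explicit strand, got "
                f"{self.interval.strand!r}"
            )
        for ex in self.exons:
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"exon {ex} outside gene body of {self.gene_id}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def tes(self) -> int:
        return self.interval.end if self.strand == "+" else self.interval.start

    @property
    def length(self) -> int:
        return self.interval.length


class ChromSizes(dict):
    """Mapping chrom -> length (bp). Rejects non-positive lengths."""

    def __init__(self, mapping: Mapping[str, int] | None = None):
        super().__init__()
        if mapping:
            for chrom, length in mapping.items():
                self[chrom] = length

    def __setitem__(self, chrom: str, length: int) -> None:
        length = int(length)
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        super().__setitem__(str(chrom), length)

    def clip(self, interval: GenomicInterval) -> GenomicInterval:
        """Clip an interval to its chromosome; warn if anything was trimmed."""
        length = self[interval.chrom]
        start, end = max(interval.start, 0), min(interval.end, length)
        if start >= end:
            raise ValueError(f"interval {interval} entirely outside chromosome")
        if (start, end) != (interval.start, interval.end):
            logger.warning("clipped %s to [%d, %d)", interval, start, end)
            return GenomicInterval(interval.chrom, start, end, interval.strand)
        return interval


@dataclass(frozen=True)
class Peak:
    """A called enrichment peak; ``summit`` is an absolute position if known."""

    interval: GenomicInterval
    score: float = 0.0
    name: str = "."
    summit: int | None = None

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"peak score must be >= 0, got {self.score}")

    @property
    def anchor(self) -> int:
        """Summit when provided, else the interval midpoint."""
        return self.summit if self.summit is not None else self.interval.midpoint


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> ChromSizes:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "length"], dtype={"chrom": str})
    if df["chrom"].duplicated().any():
        dups = df.loc[df["chrom"].duplicated(), "chrom"].tolist()
        raise ValueError(f"duplicate chromosomes in chrom.sizes: {dups}")
    return ChromSizes(dict(zip(df["chrom"], df["length"])))


def write_chrom_sizes(sizes: ChromSizes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


_BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed6(path: str | Path) -> pd.DataFrame:
    """Read a BED6 (or BED3/4/5) file into a DataFrame with BED6 columns."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     dtype={0: str}, keep_default_na=False)
    n = df.shape[1]
    if n < 3:
        raise ValueError(f"{path}: BED needs >= 3 columns, found {n}")
    df = df.iloc[:, : min(n, 6)]
    df.columns = _BED6_COLS[: df.shape[1]]
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in df:
            df[col] = default
    bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])]
    if len(bad):
        raise ValueError(f"{path}: malformed interval at line {bad[0] + 1}")
    bad = df.index[~df["strand"].isin(STRANDS)]
    if len(bad):
        raise ValueError(f"{path}: unknown strand at line {bad[0] + 1}")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df.reset_index(drop=True)


def write_bed6(df: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", header=False, index=False,
                  columns=_BED6_COLS)


def intervals_to_frame(intervals: Iterable[GenomicInterval]) -> pd.DataFrame:
    rows = [(iv.chrom, iv.start, iv.end, ".", 0, iv.strand) for iv in intervals]
    return pd.DataFrame(rows, columns=_BED6_COLS)


def frame_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand)
        for r in df.itertuples(index=False)
    ]


def read_peaks(path: str | Path) -> list[Peak]:
    """Read peaks from BED or narrowPeak; column 10 (summit offset) honoured."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     dtype={0: str}, keep_default_na=False)
    peaks = []
    for i, row in enumerate(df.itertuples(index=False)):
        vals = list(row)
        chrom, start, end = vals[0], int(vals[1]), int(vals[2])
        name = str(vals[3]) if len(vals) > 3 else f"peak_{i}"
        score = float(vals[4]) if len(vals) > 4 else 0.0
        summit = None
        if len(vals) >= 10 and int(vals[9]) >= 0:
            summit = start + int(vals[9])
        peaks.append(Peak(GenomicInterval(chrom, start, end), score, name, summit))
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    rows = [
        (p.interval.chrom, p.interval.start, p.interval.end, p.name, p.score, ".")
        for p in peaks
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def _genes_from_bed6(df: pd.DataFrame, sizes: ChromSizes | None) -> list[GeneModel]:
    genes = []
    for r in df.itertuples(index=False):
        iv = GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand)
        if sizes is not None:
            iv = sizes.clip(iv)
        genes.append(GeneModel(str(r.name), iv))
    return genes


def _genes_from_bed12(path: str | Path, sizes: ChromSizes | None) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     dtype={0: str}, keep_default_na=False)
    if df.shape[1] < 12:
        raise ValueError(f"{path}: BED12 needs 12 columns, found {df.shape[1]}")
    genes = []
    for r in df.itertuples(index=False):
        vals = list(r)
        chrom, start, end, name, _score, strand = vals[:6]
        start, end = int(start), int(end)
        iv = GenomicInterval(chrom, start, end, strand)
        if sizes is not None:
            iv = sizes.clip(iv)
        block_sizes = [int(x) for x in str(vals[10]).rstrip(",").split(",")]
        block_starts = [int(x) for x in str(vals[11]).rstrip(",").split(",")]
        exons = [
            GenomicInterval(chrom, start + bs, start + bs + sz, strand)
            for bs, sz in zip(block_starts, block_sizes)
        ]
        genes.append(GeneModel(str(name), iv, exons))
    return genes


def _genes_from_gtf(path: str | Path, sizes: ChromSizes | None) -> list[GeneModel]:
    import pyranges as pr

    gr = pr.read_gtf(str(path)).df
    gene_rows = gr[gr["Feature"] == "gene"]
    if gene_rows.empty:
        # fall back to transcript records when no gene lines exist
        gene_rows = gr[gr["Feature"] == "transcript"]
    exon_rows = gr[gr["Feature"] == "exon"]
    genes = []
    for r in gene_rows.itertuples(index=False):
        iv = GenomicInterval(str(r.Chromosome), int(r.Start), int(r.End),
                             str(r.Strand))
        if sizes is not None:
            iv = sizes.clip(iv)
        gid = str(r.gene_id)
        exons = []
        if not exon_rows.empty:
            mine = exon_rows[exon_rows["gene_id"] == gid]
            exons = [
                GenomicInterval(str(e.Chromosome), int(e.Start), int(e.End),
                                str(e.Strand))
                for e in mine.itertuples(index=False)
            ]
        genes.append(GeneModel(gid, iv, exons))
    return genes


def read_genes(path: str | Path, format: str = "bed6",
               sizes: ChromSizes | None = None) -> list[GeneModel]:
    """Read gene models from BED6, BED12 or GTF.

    GTF coordinates (1-based closed) are converted to 0-based half-open.
    Output is deterministically sorted by (chrom, start, gene_id). Intervals
    extending past chromosome ends are clipped (with a logged warning) when
    ``sizes`` is given.
    """
    if format == "bed6":
        genes = _genes_from_bed6(read_bed6(path), sizes)
    elif format == "bed12":
        genes = _genes_from_bed12(path, sizes)
    elif format == "gtf":
        genes = _genes_from_gtf(path, sizes)
    else:
        raise ValueError(f"unknown gene annotation format {format!r}")
    genes.sort(key=lambda g: (g.chrom, g.interval.start, g.gene_id))
    return genes


def write_genes_bed6(genes: Sequence[GeneModel], path: str | Path) -> None:
    rows = [
        (g.chrom, g.interval.start, g.interval.end, g.gene_id, 0, g.strand)
        for g in genes
    ]
    pd.DataFrame(rows, columns=_BED6_COLS).to_csv(
        path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# gene selection and blacklist filtering
# ---------------------------------------------------------------------------

def _build_trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def select_isolated_genes(
    genes: Sequence[GeneModel],
    min_distance: int = 4000,
    extra_annotations: Iterable[GenomicInterval] | None = None,
) -> list[GeneModel]:
    """Keep genes >= ``min_distance`` bp (closest-edge gap) from every other
    annotation on the same chromosome.

    The annotation universe is the gene set itself plus any
    ``extra_annotations`` (e.g. non-coding RNA intervals). Overlapping genes
    are always excluded.
    """
    universe = [g.interval for g in genes]
    if extra_annotations:
        universe = universe + list(extra_annotations)
    trees = _build_trees(universe)
    # count duplicates of each gene's own interval so self-hits are discounted
    from collections import Counter

    own = Counter((iv.chrom, iv.start, iv.end) for iv in universe)
    kept = []
    for g in genes:
        iv = g.interval
        tree = trees.get(iv.chrom)
        if tree is None:
            kept.append(g)
            continue
        lo, hi = iv.start - min_distance, iv.end + min_distance
        hits = tree.overlap(lo, hi)
        self_hits = sum(
            1 for h in hits if (iv.chrom, h.begin, h.end) == (iv.chrom, iv.start, iv.end)
        )
        # an identical duplicated annotation still disqualifies the gene
        others = len(hits) - min(self_hits, 1)
        if others == 0 and own[(iv.chrom, iv.start, iv.end)] == 1:
            kept.append(g)
    return kept


def filter_blacklist(
    peaks: Sequence[Peak], blacklist: Iterable[GenomicInterval]
) -> list[Peak]:
    """Drop peaks overlapping any blacklist interval by >= 1 bp.

    Survivor order is preserved; the operation is idempotent.
    """
    trees = _build_trees(blacklist)
    kept = []
    for p in peaks:
        tree = trees.get(p.interval.chrom)
        if tree is not None and tree.overlap(p.interval.start, p.interval.end):
            continue
        kept.append(p)
    return kept
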