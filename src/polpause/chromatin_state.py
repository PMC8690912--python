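"""Chromatin-state classification and differential-expression integration.

Genes are classified from the presence of three histone-mark peak sets in
TSS-anchored windows:

* H3K4me3 (promoter activation) within +/- 2 kb of the TSS,
* H3K79me2 (transcribed chromatin) within the first 5 kb of the gene body,
* H3K27me3 (Polycomb repression) within +/- 5 kb of the TSS.

The default rule table follows the standard bivalent-domain definition:
``bivalent`` if K4me3 and K27me3 co-occur, ``active`` if K4me3 or K79me2 is
present without K27me3, ``silent`` otherwise (K27me3-only or unmarked). The
table is fully configurable as a mapping over all eight flag triples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .genome_io import GeneModel, GenomicInterval, Peak, ChromSizes

logger = logging.getLogger(__name__)

STATES = ("active", "bivalent", "silent")


@dataclass(frozen=True)
class MarkWindows:
    """Strand-oriented query windows for each histone mark (bp)."""

    k4_flank: int = 2000       # +/- around TSS
    k79_body: int = 5000       # [TSS, TSS + 5 kb) in transcription direction
    k27_flank: int = 5000      # +/- around TSS

    def window(self, gene: GeneModel, mark: str,
               sizes: ChromSizes | None = None) -> GenomicInterval:
        tss = gene.tss
        if mark == "k4":
            lo, hi = tss - self.k4_flank, tss + self.k4_flank
        elif mark == "k27":
            lo, hi = tss - self.k27_flank, tss + self.k27_flank
        elif mark == "k79":
            if gene.strand == "+":
                lo, hi = tss, tss + self.k79_body
            else:
                lo, hi = tss - self.k79_body, tss
        else:
            raise ValueError(f"unknown mark {mark!r}")
        if sizes is not None:
            lo = max(lo, 0)
            hi = min(hi, sizes[gene.chrom])
        else:
            lo = max(lo, 0)
        return GenomicInterval(gene.chrom, lo, hi, gene.strand)


DEFAULT_RULE_TABLE: dict[tuple[bool, bool, bool], str] = {
    (k4, k79, k27): (
        "bivalent" if (k4 and k27)
        else "active" if ((k4 or k79) and not k27)
        else "silent"
    )
    for k4, k79, k27 in product([True, False], repeat=3)
}


@dataclass
class ChromatinCall:
    gene_id: str
    k4: bool
    k79: bool
    k27: bool
    state: str


@dataclass(frozen=True)
class DERecord:
    """One row of a differential-expression table."""

    gene_id: str
    log2fc: float
    p: float
    fdr: float

    @property
    def direction(self) -> str:
        return "up" if self.log2fc > 0 else "down"


def _peak_trees(peaks: Iterable[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.interval.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end)
    return trees


def mark_present(gene: GeneModel, peaks: Sequence[Peak] | dict,
                 window: GenomicInterval) -> bool:
    """True iff >= 1 peak overlaps the window by >= 1 bp."""
    trees = peaks if isinstance(peaks, dict) else _peak_trees(peaks)
    tree = trees.get(window.chrom)
    return bool(tree and tree.overlap(window.start, window.end))


def classify_state(flags: tuple[bool, bool, bool],
                   rule_table: Mapping[tuple[bool, bool, bool], str] | None = None,
                   ) -> str:
    """Map a (k4, k79, k27) presence triple to a chromatin state."""
    table = DEFAULT_RULE_TABLE if rule_table is None else rule_table
    if rule_table is not None:
        missing = [t for t in product([True, False], repeat=3) if t not in table]
        if missing:
            raise ValueError(f"rule table incomplete; missing triples {missing}")
        bad = set(table.values()) - set(STATES)
        if bad:
            raise ValueError(f"rule table maps to unknown states {bad}")
    return table[tuple(bool(f) for f in flags)]


def call_chromatin_states(
    genes: Sequence[GeneModel],
    k4_peaks: Sequence[Peak],
    k79_peaks: Sequence[Peak],
    k27_peaks: Sequence[Peak],
    windows: MarkWindows = MarkWindows(),
    rule_table: Mapping | None = None,
    sizes: ChromSizes | None = None,
) -> list[ChromatinCall]:
    """Classify every gene from the three mark peak sets."""
    trees = {m: _peak_trees(p) for m, p in
             (("k4", k4_peaks), ("k79", k79_peaks), ("k27", k27_peaks))}
    calls = []
    for gene in genes:
        flags = tuple(
            mark_present(gene, trees[m], windows.window(gene, m, sizes))
            for m in ("k4", "k79", "k27")
        )
        calls.append(ChromatinCall(gene.gene_id, *flags,
                                   state=classify_state(flags, rule_table)))
    return calls


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

DE_PRESETS = {
    # the three published threshold sets; results-v1 is the default
    "results-v1": dict(fold_min=1.5, p_max=0.05, fdr_max=0.1),
    "results-v2": dict(fold_min=1.5, p_max=0.1, fdr_max=0.05),
    "methods": dict(fold_min=2.0, p_max=1.0, fdr_max=0.05),
}


def read_de_table(path: str | Path,
                  columns: Mapping[str, str] | None = None) -> list[DERecord]:
    """Read a DE table TSV; ``columns`` remaps header names if needed."""
    df = pd.read_csv(path, sep="\t")
    colmap = {"gene_id": "gene_id", "log2fc": "log2fc", "p": "p", "fdr": "fdr"}
    if columns:
        colmap.update(columns)
    records, skipped = [], 0
    for r in df.itertuples(index=False):
        d = r._asdict()
        try:
            rec = DERecord(str(d[colmap["gene_id"]]),
                           float(d[colmap["log2fc"]]),
                           float(d[colmap["p"]]), float(d[colmap["fdr"]]))
            if math.isnan(rec.log2fc) or math.isnan(rec.p) or math.isnan(rec.fdr):
                raise ValueError("NaN field")
        except (KeyError, TypeError, ValueError):
            skipped += 1
            continue
        records.append(rec)
    if skipped:
        logger.warning("skipped %d malformed DE records", skipped)
    return records


def filter_de(records: Sequence[DERecord], fold_min: float = 1.5,
              p_max: float = 0.05, fdr_max: float = 0.1,
              ) -> dict[str, list[DERecord]]:
    """Split records into significantly up- and down-regulated sets.

    A record passes if |fold change| >= fold_min (i.e. |log2fc| >=
    log2(fold_min)), p <= p_max and FDR <= fdr_max; boundary equality is
    included. The sign of log2fc assigns the direction.
    """
    if fold_min <= 0 or p_max <= 0 or fdr_max <= 0:
        raise ValueError("thresholds must be > 0")
    lfc_min = math.log2(fold_min)
    up, down = [], []
    for rec in records:
        if rec.p > p_max or rec.fdr > fdr_max:
            continue
        if rec.log2fc >= lfc_min:
            up.append(rec)
        elif rec.log2fc <= -lfc_min:
            down.append(rec)
    return {"up": up, "down": down}


def state_composition(gene_list: Iterable[str],
                      calls: Sequence[ChromatinCall]) -> dict:
    """Percentage of each chromatin state within a gene list.

    Genes without a call are reported separately (``n_uncalled``), not
    folded into the percentages.
    """
    by_gene = {c.gene_id: c.state for c in calls}
    genes = list(gene_list)
    called = [g for g in genes if g in by_gene]
    out: dict = {f"pct_{s}": 0.0 for s in STATES}
    out["n_genes"] = len(genes)
    out["n_called"] = len(called)
    out["n_uncalled"] = len(genes) - len(called)
    if called:
        for s in STATES:
            n = sum(1 for g in called if by_gene[g] == s)
            out[f"pct_{s}"] = 100.0 * n / len(called)
    return out


@dataclass
class OverlapSummary:
    """Sizes and intersections of 2-3 named gene-id sets."""

    sizes: dict[str, int]
    pairwise: dict[tuple[str, str], int]
    triple: int | None
    non_overlap_pct: dict[str, float]
    union_size: int


def overlap_summary(sets: Mapping[str, set]) -> OverlapSummary:
    """Venn-style summary: per-set sizes, intersections, and the percentage
    of each set not shared with any other (its unique fraction)."""
    names = list(sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("overlap_summary expects 2 or 3 sets")
    sizes = {n: len(sets[n]) for n in names}
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pairwise[(a, b)] = len(sets[a] & sets[b])
    triple = len(sets[names[0]] & sets[names[1]] & sets[names[2]]) \
        if len(names) == 3 else None
    union = set().union(*sets.values())
    non_overlap = {}
    for n in names:
        others = set().union(*(sets[m] for m in names if m != n))
        unique = sets[n] - others
        non_overlap[n] = 100.0 * len(unique) / len(sets[n]) if sets[n] else 0.0
    return OverlapSummary(sizes, pairwise, triple, non_overlap, len(union))
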