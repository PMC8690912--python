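"""Per-gene pausing statistics and between-condition comparisons.

Three strand-oriented windows per gene:

* ``a`` — promoter-proximal, default ``[TSS-30, TSS+300)``: where paused
  polymerase accumulates;
* ``b`` — gene body, default ``[TSS+300, TES)``: productive elongation;
* ``c`` — termination region, default ``[TES, TES+4000)``.

The traveling ratio TR = (density(a) + eps) / (density(b) + eps) rises when
polymerase piles up at the promoter relative to the body; the 3' pausing
index PI3 = (density(c) + eps) / (density(b) + eps) rises when it
accumulates past the TES. Densities are per-bp (length-weighted bin means),
so both metrics are invariant to track rescaling when eps = 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import CoverageTrack, window_density
from .genome_io import GeneModel
from .metagene import _oriented_window

logger = logging.getLogger(__name__)

DEFAULT_EPS = 0.01
DEFAULT_TIER_BOUNDARIES = (0.30, 0.50)


@dataclass(frozen=True)
class PausingWindows:
    """Window bounds in transcription-direction bp. ``None`` end = TES."""

    a_rel: tuple[int, int] = (-30, 300)
    b_rel: tuple[int, int | None] = (300, None)
    c_rel: tuple[int, int] = (0, 4000)

    def resolve(self, gene: GeneModel) -> dict[str, tuple[str, float, float]]:
        """Genomic (chrom, start, end) for each window, clipped to the gene's
        chromosome later by window_density. Raises if ``b`` is empty."""
        b_end = self.b_rel[1] if self.b_rel[1] is not None else gene.length
        if b_end <= self.b_rel[0]:
            raise ValueError(
                f"gene {gene.gene_id}: body window empty "
                f"(length {gene.length} <= {self.b_rel[0]})")
        return {
            "a": _oriented_window(gene, *self.a_rel, anchor=gene.tss),
            "b": _oriented_window(gene, self.b_rel[0], b_end, anchor=gene.tss),
            "c": _oriented_window(gene, *self.c_rel, anchor=gene.tes),
        }


def _window_ratio(track: CoverageTrack, gene: GeneModel,
                  windows: PausingWindows, num: str, den: str,
                  eps: float) -> float:
    w = windows.resolve(gene)
    d_num = window_density(track, w[num])
    d_den = window_density(track, w[den])
    return (d_num + eps) / (d_den + eps)


def traveling_ratio(track: CoverageTrack, gene: GeneModel,
                    windows: PausingWindows = PausingWindows(),
                    eps: float = DEFAULT_EPS) -> float:
    """Promoter-proximal / gene-body density ratio; > 1 indicates pausing."""
    return _window_ratio(track, gene, windows, "a", "b", eps)


def pausing_index_3prime(track: CoverageTrack, gene: GeneModel,
                         windows: PausingWindows = PausingWindows(),
                         eps: float = DEFAULT_EPS) -> float:
    """Termination-region / gene-body density ratio; > 1 indicates 3' pileup."""
    return _window_ratio(track, gene, windows, "c", "b", eps)


def average_signal(track: CoverageTrack, gene: GeneModel,
                   flank: int = 4000) -> float:
    """Mean density over [TSS - flank, TES + flank], clipped to chromosome."""
    lo = max(gene.interval.start - flank, 0)
    hi = min(gene.interval.end + flank, track.sizes[gene.chrom])
    return window_density(track, (gene.chrom, lo, hi))


def assign_tiers(
    avg_signals: dict[str, float],
    boundaries: tuple[float, float] = DEFAULT_TIER_BOUNDARIES,
) -> dict[str, str]:
    """Rank genes by average signal and cut into high/intermediate/low tiers.

    Genes are ranked descending by signal (ties broken by gene_id, stable);
    the top ``ceil(b0*N)`` ranks are ``high``, ranks through ``ceil(b1*N)``
    are ``intermediate``, the rest ``low``. With the default (0.30, 0.50)
    boundaries, N=515 splits 155/103/257 and N=680 splits 204/136/340.
    """
    if not avg_signals:
        return {}
    b0, b1 = boundaries
    if not (0 < b0 < b1 <= 1):
        raise ValueError(f"invalid tier boundaries {boundaries}")
    ranked = sorted(avg_signals, key=lambda g: (-avg_signals[g], g))
    n = len(ranked)
    n_high = math.ceil(b0 * n)
    n_mid_end = math.ceil(b1 * n)
    tiers = {}
    for rank, gene in enumerate(ranked, start=1):
        if rank <= n_high:
            tiers[gene] = "high"
        elif rank <= n_mid_end:
            tiers[gene] = "intermediate"
        else:
            tiers[gene] = "low"
    return tiers


def compute_pausing_metrics(
    track: CoverageTrack,
    genes: list[GeneModel],
    windows: PausingWindows = PausingWindows(),
    eps: float = DEFAULT_EPS,
    tier_boundaries: tuple[float, float] = DEFAULT_TIER_BOUNDARIES,
    flank: int = 4000,
) -> pd.DataFrame:
    """TR, PI3, average signal and tier for every analyzable gene.

    Genes whose body window is empty are skipped with a logged reason.
    Returns a DataFrame indexed by gene_id.
    """
    rows = {}
    for gene in genes:
        try:
            tr = traveling_ratio(track, gene, windows, eps)
            pi3 = pausing_index_3prime(track, gene, windows, eps)
        except ValueError as exc:
            logger.info("skipping %s: %s", gene.gene_id, exc)
            continue
        rows[gene.gene_id] = {
            "tr": tr,
            "pi3": pi3,
            "avg_signal": average_signal(track, gene, flank),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    if df.empty:
        return pd.DataFrame(columns=["tr", "pi3", "avg_signal", "tier"])
    tiers = assign_tiers(df["avg_signal"].to_dict(), tier_boundaries)
    df["tier"] = df.index.map(tiers)
    df.index.name = "gene_id"
    return df


def compare_conditions(metrics_a: "list[float] | np.ndarray",
                       metrics_b: "list[float] | np.ndarray") -> dict:
    """Two-sided Mann-Whitney U between per-gene metric distributions.

    Uses the exact null when sample sizes permit and no ties are present,
    otherwise the tie-corrected normal approximation. Reports medians and
    the direction of the shift.
    """
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 values per condition")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if med_a > med_b:
        direction = "a>b"
    elif med_a < med_b:
        direction = "a<b"
    else:
        direction = "a=b"
    return {
        "statistic": float(res.statistic),
        "p_two_sided": float(res.pvalue),
        "median_a": med_a,
        "median_b": med_b,
        "direction": direction,
        "n_a": len(a),
        "n_b": len(b),
    }


def permutation_test_medians(metrics_a, metrics_b, n_perm: int = 5000,
                             seed: int = 0) -> float:
    """Permutation p-value for the median difference (cross-check for the
    U test on small synthetic cohorts)."""
    rng = np.random.default_rng(seed)
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    pooled = np.concatenate([a, b])
    obs = abs(np.median(a) - np.median(b))
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        stat = abs(np.median(pooled[:len(a)]) - np.median(pooled[len(a):]))
        if stat >= obs - 1e-15:
            hits += 1
    return (hits + 1) / (n_perm + 1)
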