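"""Synthetic ChIP-seq data with planted ground truth.

Reads are drawn from a four-component mixture over fragment 5' ends that
mimics the canonical Pol II occupancy shape: a promoter-proximal peak
(Normal around TSS + mu_p), a gene-body plateau (Uniform over the body), a
3'-end peak (Normal around the TES) and uniform genomic background. A
"depleted" condition reweights the mixture (promoter weight up, body weight
down) to emulate a pause-release defect: polymerase accumulates at
promoters and thins out over gene bodies.

The model places fragment 5' ends only (no fragment-size distribution) —
sufficient to exercise strand-directed read extension and every downstream
metric, but it does not emulate mappability, GC bias or sequence content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genome_io import ChromSizes, GeneModel, GenomicInterval, Peak

DEFAULT_READ_LENGTH = 36
# control-condition mixture: moderate pausing, strong body signal
DEFAULT_PI = (0.40, 0.45, 0.10, 0.05)
# depletion reweighting: promoter up, body down (pause-release defect)
DEFAULT_DEPLETION_MULTIPLIERS = {"pi_p": 1.75, "pi_b": 0.50, "pi_t": 1.0}

_COMPONENTS = ("promoter", "body", "terminal", "background")


@dataclass(frozen=True)
class SimGeneParams:
    """Planted per-gene simulation parameters."""

    gene_id: str
    pi_p: float = DEFAULT_PI[0]
    pi_b: float = DEFAULT_PI[1]
    pi_t: float = DEFAULT_PI[2]
    pi_bg: float = DEFAULT_PI[3]
    mu_p: float = 50.0        # promoter peak centre, bp downstream of TSS
    sigma_p: float = 60.0     # promoter peak spread (bp)
    sigma_t: float = 300.0    # 3' peak spread (bp)
    expression: float = 500.0  # expected read count

    def __post_init__(self) -> None:
        pis = (self.pi_p, self.pi_b, self.pi_t, self.pi_bg)
        if any(not 0 <= p <= 1 for p in pis):
            raise ValueError(f"{self.gene_id}: weights must be in [0, 1]")
        if abs(sum(pis) - 1.0) > 1e-9:
            raise ValueError(f"{self.gene_id}: weights sum to {sum(pis)}, not 1")
        if self.sigma_p <= 0 or self.sigma_t <= 0:
            raise ValueError(f"{self.gene_id}: sigmas must be > 0")
        if self.expression < 0:
            raise ValueError(f"{self.gene_id}: expression must be >= 0")

    @property
    def pis(self) -> tuple[float, float, float, float]:
        return (self.pi_p, self.pi_b, self.pi_t, self.pi_bg)

    def reweighted(self, multipliers: Mapping[str, float]) -> "SimGeneParams":
        """Multiply selected mixture weights, then renormalize to sum 1."""
        w = {
            "pi_p": self.pi_p * multipliers.get("pi_p", 1.0),
            "pi_b": self.pi_b * multipliers.get("pi_b", 1.0),
            "pi_t": self.pi_t * multipliers.get("pi_t", 1.0),
            "pi_bg": self.pi_bg * multipliers.get("pi_bg", 1.0),
        }
        total = sum(w.values())
        if total <= 0:
            raise ValueError("reweighting zeroed all components")
        return replace(self, **{k: v / total for k, v in w.items()})


@dataclass
class SimTruth:
    """The full planted parameter set for one simulated experiment."""

    genes: list[SimGeneParams]
    seed: int
    condition_multipliers: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"depleted": dict(DEFAULT_DEPLETION_MULTIPLIERS)})

    def condition(self, name: str) -> "SimTruth":
        """Per-condition truth; ``control`` is the identity."""
        if name == "control":
            return self
        mult = self.condition_multipliers[name]
        return SimTruth([g.reweighted(mult) for g in self.genes], self.seed,
                        self.condition_multipliers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(g) for g in self.genes])


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def make_genome(
    n_genes: int = 200,
    seed: int = 0,
    gene_length: tuple[int, int] = (2000, 10000),
    spacing: int = 25000,
    n_chroms: int = 2,
    margin: int = 10000,
) -> tuple[list[GeneModel], ChromSizes]:
    """Well-separated genes on ``n_chroms`` chromosomes, alternating strand.

    ``spacing`` >= 25 kb keeps every gene's mark windows and 4 kb flanks
    clear of its neighbours, so isolation selection keeps all genes.
    """
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    sizes = {}
    per_chrom = math.ceil(n_genes / n_chroms)
    gid = 0
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        pos = margin
        for _ in range(per_chrom):
            if gid >= n_genes:
                break
            length = int(rng.integers(gene_length[0], gene_length[1] + 1))
            strand = "+" if gid % 2 == 0 else "-"
            genes.append(GeneModel(f"g{gid:04d}",
                                   GenomicInterval(chrom, pos, pos + length,
                                                   strand)))
            pos += length + spacing
            gid += 1
        sizes[chrom] = pos + margin
    return genes, ChromSizes(sizes)


def default_truth(genes: Sequence[GeneModel], seed: int = 0,
                  pi: tuple[float, float, float, float] = DEFAULT_PI,
                  expression: float = 500.0,
                  pi_p_per_gene: Mapping[str, float] | None = None) -> SimTruth:
    """Uniform truth over a gene set; ``pi_p_per_gene`` overrides the
    promoter weight gene-by-gene (the other weights shrink proportionally)."""
    params = []
    for g in genes:
        if pi_p_per_gene and g.gene_id in pi_p_per_gene:
            pp = pi_p_per_gene[g.gene_id]
            rest = 1.0 - pp
            base_rest = pi[1] + pi[2] + pi[3]
            params.append(SimGeneParams(
                g.gene_id, pp, pi[1] / base_rest * rest,
                pi[2] / base_rest * rest, pi[3] / base_rest * rest,
                expression=expression))
        else:
            params.append(SimGeneParams(g.gene_id, *pi, expression=expression))
    return SimTruth(params, seed)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_reads(
    truth: SimTruth,
    genes: Sequence[GeneModel],
    sizes: ChromSizes,
    read_length: int = DEFAULT_READ_LENGTH,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw strand-aware reads (BED6 DataFrame) from the planted mixture.

    Per gene: N ~ Poisson(expression) fragments; 5' ends from the
    promoter/body/terminal/background components; read strand equals the
    gene strand except for background (random). Reads are clipped to the
    chromosome. Identical seed + truth reproduce the identical read set.
    """
    if seed is None:
        seed = truth.seed
    rng = np.random.default_rng(seed)
    by_id = {g.gene_id: g for g in genes}
    chroms, starts, ends, strands, comps = [], [], [], [], []
    for params in truth.genes:
        gene = by_id[params.gene_id]
        if gene.length <= 300:
            raise ValueError(
                f"gene {gene.gene_id} too short to simulate ({gene.length} bp)")
        n = rng.poisson(params.expression)
        if n == 0:
            continue
        comp = rng.choice(4, size=n, p=params.pis)
        direction = 1 if gene.strand == "+" else -1
        chrom_len = sizes[gene.chrom]
        # transcription-direction offsets of fragment 5' ends
        offsets = np.zeros(n)
        m = comp == 0
        offsets[m] = rng.normal(params.mu_p, params.sigma_p, m.sum())
        m = comp == 1
        offsets[m] = rng.uniform(300, gene.length, m.sum())
        m = comp == 2
        offsets[m] = gene.length + rng.normal(0.0, params.sigma_t, m.sum())
        pos = np.rint(gene.tss + direction * offsets).astype(np.int64)
        strand = np.full(n, gene.strand, dtype=object)
        m = comp == 3
        if m.any():
            pos[m] = rng.integers(0, chrom_len, m.sum())
            strand[m] = np.where(rng.random(m.sum()) < 0.5, "+", "-")
        s = np.where(strand == "+", pos, pos - read_length + 1)
        e = s + read_length
        s = np.clip(s, 0, chrom_len)
        e = np.clip(e, 0, chrom_len)
        keep = e > s
        chroms.append(np.full(keep.sum(), gene.chrom, dtype=object))
        starts.append(s[keep])
        ends.append(e[keep])
        strands.append(strand[keep])
        comps.append(np.array(_COMPONENTS, dtype=object)[comp[keep]])
    if not chroms:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "score",
                                     "strand"])
    df = pd.DataFrame({
        "chrom": np.concatenate(chroms),
        "start": np.concatenate(starts),
        "end": np.concatenate(ends),
        "name": np.concatenate(comps),
        "score": 0,
        "strand": np.concatenate(strands),
    })
    return df


def expected_body_plateau(params: SimGeneParams, gene: GeneModel,
                          total_reads: int, extend: int = 150) -> float:
    """Analytic per-bp normalized depth of the gene-body plateau.

    5'-end density over the body is expression*pi_b/(length-300) per bp;
    each fragment covers ``extend`` bp, and per-million scaling divides by
    total reads. Valid away from the body edges.
    """
    dens_5p = params.expression * params.pi_b / (gene.length - 300)
    return dens_5p * extend * 1e6 / total_reads


# ---------------------------------------------------------------------------
# histone-mark peaks
# ---------------------------------------------------------------------------

def simulate_marks(
    genes: Sequence[GeneModel],
    state_assignment: Mapping[str, str],
    seed: int = 0,
    sizes: ChromSizes | None = None,
) -> dict[str, list[Peak]]:
    """Emit K4me3/K79me2/K27me3 peak sets realizing a state assignment.

    Construction is the inverse of the default classification rule:
    active genes get K4 and/or K79 peaks, bivalent genes K4 + K27, silent
    genes K27-only or nothing. Classifying the output recovers the
    assignment exactly (genes must be well separated, as from
    :func:`make_genome`).
    """
    rng = np.random.default_rng(seed)
    out: dict[str, list[Peak]] = {"k4": [], "k79": [], "k27": []}

    def add(mark: str, gene: GeneModel, lo: int, hi: int) -> None:
        if sizes is not None:
            lo = max(lo, 0)
            hi = min(hi, sizes[gene.chrom])
        else:
            lo = max(lo, 0)
        out[mark].append(Peak(GenomicInterval(gene.chrom, lo, hi),
                              score=float(rng.uniform(5, 50)),
                              name=f"{mark}_{gene.gene_id}"))

    for gene in genes:
        state = state_assignment[gene.gene_id]
        tss, d = gene.tss, (1 if gene.strand == "+" else -1)
        if state == "active":
            variant = rng.choice(["k4", "k79", "both"])
            if variant in ("k4", "both"):
                add("k4", gene, tss - 250, tss + 250)
            if variant in ("k79", "both"):
                body = sorted((tss + d * 500, tss + d * 1500))
                add("k79", gene, body[0], body[1])
        elif state == "bivalent":
            add("k4", gene, tss - 250, tss + 250)
            add("k27", gene, tss - 500, tss + 500)
        elif state == "silent":
            if rng.random() < 0.5:
                add("k27", gene, tss - 500, tss + 500)
        else:
            raise ValueError(f"unknown state {state!r} for {gene.gene_id}")
    return out


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def simulate_de(
    genes: Sequence[GeneModel] | Sequence[str],
    down: Iterable[str] = (),
    up: Iterable[str] = (),
    fold: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """A DE table with planted up/down sets recoverable at default filters.

    Planted genes get |log2fc| >= log2(fold) and tiny p; null genes get
    p ~ Uniform(0, 1) and |log2fc| < log2(1.5), so the default
    fold/p/FDR filter recovers the planted sets exactly. The FDR column is
    Benjamini-Hochberg over the p column.
    """
    rng = np.random.default_rng(seed)
    ids = [g.gene_id if isinstance(g, GeneModel) else str(g) for g in genes]
    down, up = set(down), set(up)
    if down & up:
        raise ValueError("a gene cannot be planted both up and down")
    lfc_fold = math.log2(fold)
    rows = []
    for gid in ids:
        if gid in down or gid in up:
            sign = 1.0 if gid in up else -1.0
            lfc = sign * lfc_fold * (1.0 + abs(rng.normal(0, 0.15)))
            p = float(rng.uniform(1e-10, 1e-6))
        else:
            lfc = float(np.clip(rng.normal(0, 0.15), -0.55, 0.55))
            p = float(rng.uniform(0, 1))
        rows.append({"gene_id": gid, "log2fc": lfc, "p": p})
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df
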