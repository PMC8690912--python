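"""End-to-end validation experiments on synthetic data with known truth.

Each function runs one self-contained experiment — simulate, analyze,
measure — and returns plain numbers. They back both the test suite and the
reproducibility script, so the same code path produces every reported
quantity.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats

from . import chromatin_state as cs
from . import coverage as cov
from . import metagene as mg
from . import pausing as pz
from . import synthetic_data as sd
from .genome_io import ChromSizes
from .synthetic_data import default_truth, make_genome, simulate_reads


def _cohort_metrics(genes, sizes, pi_p, expression, seed):
    truth = default_truth(genes, seed=seed, expression=expression,
                          pi_p_per_gene={g.gene_id: pi_p for g in genes})
    reads = simulate_reads(truth, genes, sizes, seed=seed)
    frags = cov.extend_reads(reads, sizes, 150)
    track = cov.compute_coverage(frags, sizes, 20,
                                 cov.NormalizationInfo(len(reads)))
    return pz.compute_pausing_metrics(track, genes), track, len(reads)


def tr_parameter_recovery(seed: int, n_genes: int = 200,
                          reads_per_cohort: int = 100_000,
                          pi_high: float = 0.8, pi_low: float = 0.2) -> dict:
    """One replicate of the promoter-weight recovery experiment.

    Two cohorts of ``n_genes`` genes are simulated at ``reads_per_cohort``
    expected depth, one with planted promoter weight ``pi_high`` and one
    with ``pi_low``. Returns the two median traveling ratios and the
    Spearman correlation between planted weight and estimated TR over the
    pooled genes.
    """
    genes, sizes = make_genome(n_genes=n_genes, seed=seed)
    expression = reads_per_cohort / n_genes
    trs, planted = [], []
    medians = {}
    for pi_p in (pi_high, pi_low):
        metrics, _, _ = _cohort_metrics(genes, sizes, pi_p, expression,
                                        seed=seed * 7 + int(pi_p * 10))
        medians[pi_p] = float(metrics["tr"].median())
        trs.extend(metrics["tr"].tolist())
        planted.extend([pi_p] * len(metrics))
    rho = float(stats.spearmanr(planted, trs).statistic)
    return {
        "median_tr_high": medians[pi_high],
        "median_tr_low": medians[pi_low],
        "spearman": rho,
        "high_gt_low": medians[pi_high] > medians[pi_low],
    }


def depletion_shift(seed: int, n_genes: int = 200,
                    expression: float = 500.0) -> dict:
    """Emulate the depletion phenotype (promoter weight up, body weight
    down) and measure the TR shift and metagene consequences.

    Returns the two-sided Mann-Whitney p for the TR shift, the TR medians,
    and the TSS-proximal and gene-body means of the two metagene profiles.
    """
    genes, sizes = make_genome(n_genes=n_genes, seed=seed)
    truth = default_truth(genes, seed=seed, expression=expression)
    results = {}
    metrics = {}
    for i, cond in enumerate(("control", "depleted")):
        reads = simulate_reads(truth.condition(cond), genes, sizes,
                               seed=seed * 11 + i)
        frags = cov.extend_reads(reads, sizes, 150)
        track = cov.compute_coverage(frags, sizes, 20,
                                     cov.NormalizationInfo(len(reads)))
        metrics[cond] = pz.compute_pausing_metrics(track, genes)
        profile = mg.aggregate_profile(mg.signal_matrix(track, genes))
        # TSS-proximal = first 15 body bins (~[TSS, TSS+300) for median gene)
        results[f"tss_mean_{cond}"] = float(np.nanmean(profile.body[:15]))
        results[f"body_mean_{cond}"] = float(np.nanmean(profile.body[30:90]))
    comparison = pz.compare_conditions(metrics["depleted"]["tr"],
                                       metrics["control"]["tr"])
    results.update({
        "p_two_sided": comparison["p_two_sided"],
        "median_tr_control": comparison["median_b"],
        "median_tr_depleted": comparison["median_a"],
    })
    return results


def coverage_oracle_error(seed: int, n_instances: int = 100) -> dict:
    """Binned coverage vs an independent per-base counting oracle on random
    small instances, plus the worst conservation-identity error."""
    rng = np.random.default_rng(seed)
    max_abs = 0.0
    max_conservation_rel = 0.0
    for _ in range(n_instances):
        chrom_len = int(rng.integers(200, 10_000))
        sizes = ChromSizes({"c": chrom_len})
        n = int(rng.integers(1, 200))
        starts = rng.integers(0, chrom_len - 1, n)
        lens = rng.integers(1, 500, n)
        ends = np.minimum(starts + lens, chrom_len)
        import pandas as pd

        frags = pd.DataFrame({"chrom": "c", "start": starts, "end": ends,
                              "name": ".", "score": 0, "strand": "+"})
        bin_size = int(rng.choice([5, 20, 37]))
        norm = cov.NormalizationInfo(n, spike_in_factor=float(rng.uniform(0.5, 2)))
        track = cov.compute_coverage(frags, sizes, bin_size, norm)
        # oracle: per-base depth by direct counting
        depth = np.zeros(chrom_len)
        for s, e in zip(starts, ends):
            depth[s:e] += 1
        n_bins = int(np.ceil(chrom_len / bin_size))
        oracle = np.array([
            depth[i * bin_size: min((i + 1) * bin_size, chrom_len)].mean()
            for i in range(n_bins)]) * norm.scale
        max_abs = max(max_abs, float(np.abs(track.data["c"] - oracle).max()))
        expected_total = norm.scale * float((ends - starts).sum())
        rel = abs(track.total_signal() - expected_total) / expected_total
        max_conservation_rel = max(max_conservation_rel, rel)
    return {"max_abs_error": max_abs,
            "max_conservation_rel_error": max_conservation_rel}


def tr_sanity(seed: int = 0) -> dict:
    """Uniform-track TR/PI3 and the worst scale-invariance error at eps=0."""
    from .genome_io import GeneModel, GenomicInterval

    sizes = ChromSizes({"c": 100_000})
    gene_p = GeneModel("gp", GenomicInterval("c", 40_000, 50_000, "+"))
    gene_m = GeneModel("gm", GenomicInterval("c", 40_000, 50_000, "-"))
    uniform = cov.CoverageTrack(20, sizes, norm=cov.NormalizationInfo(1))
    uniform.data["c"][:] = 3.7
    rng = np.random.default_rng(seed)
    random = cov.CoverageTrack(20, sizes, norm=cov.NormalizationInfo(1))
    random.data["c"][:] = rng.gamma(2.0, 1.0, len(random.data["c"]))
    worst_dev = 0.0
    for g in (gene_p, gene_m):
        for c in (2.0, 1e3, 1e-3):
            for f in (pz.traveling_ratio, pz.pausing_index_3prime):
                base = f(random, g, eps=0.0)
                scaled = f(random.scaled(c), g, eps=0.0)
                worst_dev = max(worst_dev, abs(scaled - base) / base)
    return {
        "uniform_tr": pz.traveling_ratio(uniform, gene_p),
        "uniform_pi3": pz.pausing_index_3prime(uniform, gene_p),
        "scale_invariance_max_rel_dev": worst_dev,
    }


def tier_partitions() -> dict:
    """Tier partition sizes for the three published gene-set sizes."""
    out = {}
    for n in (515, 1994, 680):
        signals = {f"g{i:05d}": float(n - i) for i in range(n)}
        tiers = pz.assign_tiers(signals)
        for lab in ("high", "intermediate", "low"):
            out[f"n{n}_{lab}"] = sum(1 for t in tiers.values() if t == lab)
    return out


def classifier_round_trip(seed: int, n_genes: int = 200) -> dict:
    genes, sizes = make_genome(n_genes=n_genes, seed=seed)
    rng = np.random.default_rng(seed)
    assignment = {g.gene_id: s for g, s in zip(
        genes, rng.choice(["active", "bivalent", "silent"], n_genes))}
    marks = sd.simulate_marks(genes, assignment, seed=seed, sizes=sizes)
    calls = cs.call_chromatin_states(genes, marks["k4"], marks["k79"],
                                     marks["k27"], sizes=sizes)
    n_ok = sum(1 for c in calls if assignment[c.gene_id] == c.state)
    return {"recovery_pct": 100.0 * n_ok / n_genes, "n_genes": n_genes}


def de_round_trip(seed: int, n_genes: int = 300, n_down: int = 20,
                  n_up: int = 15) -> dict:
    genes, _ = make_genome(n_genes=n_genes, seed=seed)
    down = {g.gene_id for g in genes[:n_down]}
    up = {g.gene_id for g in genes[n_down:n_down + n_up]}
    df = sd.simulate_de(genes, down=down, up=up, fold=2.0, seed=seed)
    recs = [cs.DERecord(r.gene_id, r.log2fc, r.p, r.fdr)
            for r in df.itertuples(index=False)]
    hits = cs.filter_de(recs)
    got_down = {r.gene_id for r in hits["down"]}
    got_up = {r.gene_id for r in hits["up"]}
    # independent BH oracle
    p = df["p"].to_numpy()
    order = np.argsort(p)
    adj = np.empty(len(p))
    running = 1.0
    for rank in range(len(p), 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * len(p) / rank)
        adj[i] = running
    return {
        "down_exact": got_down == down,
        "up_exact": got_up == up,
        "n_down_recovered": len(got_down & down),
        "n_up_recovered": len(got_up & up),
        "n_false": len(got_down - down) + len(got_up - up),
        "bh_max_abs_diff": float(np.abs(df["fdr"].to_numpy() - adj).max()),
    }


def mwu_exact_oracle(seed: int, n_cases: int = 10) -> dict:
    """compare_conditions vs brute-force enumeration of the exact U null on
    small tie-free samples."""
    rng = np.random.default_rng(seed)
    max_p_diff = 0.0
    max_u_diff = 0.0
    for _ in range(n_cases):
        n_a, n_b = int(rng.integers(3, 9)), int(rng.integers(3, 9))
        vals = rng.permutation(np.arange(1.0, 50.0))[:n_a + n_b]
        a, b = list(vals[:n_a]), list(vals[n_a:])

        def u_stat(xs, ys):
            return sum(1 for x in xs for y in ys if x > y)

        obs = u_stat(a, b)
        pooled = a + b
        mean_u = n_a * n_b / 2
        count = total = 0
        for idx in itertools.combinations(range(n_a + n_b), n_a):
            chosen = set(idx)
            xs = [pooled[i] for i in chosen]
            ys = [pooled[i] for i in range(n_a + n_b) if i not in chosen]
            total += 1
            if abs(u_stat(xs, ys) - mean_u) >= abs(obs - mean_u) - 1e-12:
                count += 1
        res = pz.compare_conditions(a, b)
        max_u_diff = max(max_u_diff, abs(res["statistic"] - obs))
        max_p_diff = max(max_p_diff, abs(res["p_two_sided"] - count / total))
    return {"max_p_abs_diff": max_p_diff, "max_u_abs_diff": max_u_diff,
            "n_cases": n_cases}
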