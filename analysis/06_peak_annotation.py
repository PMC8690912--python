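#!/usr/bin/env python
"""Peak annotation and bound-gene / DE integration.

Derives promoter peaks for half of the genes (plus intergenic decoys),
annotates every peak to promoter/3'/exon/intron/intergenic, extracts the
promoter-bound gene set and intersects it with the filtered DE sets.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from polpause import chromatin_state as cs
from polpause import genome_io as gio
from polpause import peaks as pk

BASE = Path(__file__).resolve().parent.parent / "results"
DATA = BASE / "data"
OUT = BASE / "peaks"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    sizes = gio.read_chrom_sizes(DATA / "chrom.sizes")
    genes = gio.read_genes(DATA / "genes.bed", "bed6", sizes)
    rng = np.random.default_rng(SEED)
    target = genes[: len(genes) // 2]
    peak_list = [
        gio.Peak(gio.GenomicInterval(g.chrom, max(g.tss - 150, 0), g.tss + 150),
                 score=float(rng.uniform(10, 100)), name=f"pk_{g.gene_id}")
        for g in target
    ]
    # intergenic decoys halfway between genes
    for i, g in enumerate(genes[:-1:10]):
        mid = g.interval.end + 12_000
        peak_list.append(gio.Peak(gio.GenomicInterval(g.chrom, mid, mid + 300),
                                  score=1.0, name=f"decoy_{i}"))
    anns = pk.annotate_peaks(peak_list, genes)
    pk.annotations_to_frame(anns).to_csv(OUT / "annotations.tsv", sep="\t",
                                         index=False)
    dist = pk.feature_distribution(anns)
    print("feature distribution: "
          + ", ".join(f"{k} {v:.1f}%" for k, v in dist.items()))

    bound = pk.bound_genes(peak_list, genes)
    print(f"promoter-bound genes: {len(bound)} "
          f"(planted {len(target)}; decoys excluded)")
    pd.Series(sorted(bound)).to_csv(OUT / "bound_genes.txt", index=False,
                                    header=False)

    de = cs.read_de_table(DATA / "de_table.tsv")
    hits = cs.filter_de(de, **cs.DE_PRESETS["results-v1"])
    fracs = pk.bound_vs_de(bound, {r.gene_id for r in hits["up"]},
                           {r.gene_id for r in hits["down"]})
    pd.DataFrame([fracs]).to_csv(OUT / "bound_vs_de.tsv", sep="\t",
                                 index=False)
    print(f"bound ∩ DE: {fracs['frac_down']:.1%} down, "
          f"{fracs['frac_up']:.1%} up, {fracs['frac_neither']:.1%} neither")
    print(f"wrote peak outputs to {OUT}")


if __name__ == "__main__":
    main()
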