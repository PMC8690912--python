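#!/usr/bin/env python
"""Generate the synthetic study dataset.

Builds a 200-gene two-chromosome genome, draws Pol II ChIP reads for a
control and a depleted condition (promoter weight up, body weight down in
the depleted mixture), histone-mark peak sets realizing a random
active/bivalent/silent assignment, and a DE table with planted up/down
sets. Everything downstream runs from these files.
"""

from pathlib import Path

import pandas as pd

from polpause import genome_io as gio
from polpause import synthetic_data as sd

SEED = 1
N_GENES = 200
EXPRESSION = 500.0

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genes, sizes = sd.make_genome(n_genes=N_GENES, seed=SEED)
    truth = sd.default_truth(genes, seed=SEED, expression=EXPRESSION)
    gio.write_genes_bed6(genes, OUT / "genes.bed")
    gio.write_chrom_sizes(sizes, OUT / "chrom.sizes")
    truth.to_frame().to_csv(OUT / "truth.tsv", sep="\t", index=False)

    for i, cond in enumerate(("control", "depleted")):
        reads = sd.simulate_reads(truth.condition(cond), genes, sizes,
                                  seed=SEED + i)
        gio.write_bed6(reads, OUT / f"reads_{cond}.bed")
        print(f"{cond}: {len(reads)} reads "
              f"({reads['name'].value_counts().to_dict()})")

    import numpy as np
    rng = np.random.default_rng(SEED)
    assignment = {g.gene_id: s for g, s in zip(
        genes, rng.choice(["active", "bivalent", "silent"], N_GENES))}
    marks = sd.simulate_marks(genes, assignment, seed=SEED, sizes=sizes)
    for mark, plist in marks.items():
        gio.write_peaks(plist, OUT / f"marks_{mark}.bed")
    pd.DataFrame(assignment.items(), columns=["gene_id", "state"]).to_csv(
        OUT / "true_states.tsv", sep="\t", index=False)
    print("true states:", pd.Series(assignment).value_counts().to_dict())

    down = [g.gene_id for g in genes[:20]]
    up = [g.gene_id for g in genes[20:35]]
    de = sd.simulate_de(genes, down=down, up=up, seed=SEED)
    de.to_csv(OUT / "de_table.tsv", sep="\t", index=False)
    print(f"DE table: {len(de)} genes, planted {len(down)} down / {len(up)} up")
    print(f"wrote dataset to {OUT}")


if __name__ == "__main__":
    main()
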