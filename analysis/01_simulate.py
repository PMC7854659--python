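#!/usr/bin/env python
"""Generate the synthetic study: 600 genes, 3 tissues, 7 CON + 7 RES fetuses.

Writes the count matrix, sample metadata and ground-truth tables under
results/data/.  The planted structure: 30 tissue-specific genes per tissue,
40 stand-alone DE genes, and three 20-gene regulator modules -- one stable
(coupling 0.9/0.9), one sign-flipped between conditions (+0.8/-0.8) and one
decoupled in RES (0.9/0.0).
"""

from pathlib import Path

from coexnet import io, simulate

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 2021


def main() -> None:
    cfg = simulate.SimConfig(seed=SEED)
    counts, metadata, truth = simulate.simulate_dataset(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    io.write_counts(counts, OUT / "counts.tsv")
    io.write_metadata(metadata, OUT / "samples.tsv")
    simulate.write_truth(truth, OUT, genes=list(counts.index))
    io.write_gene_list(sorted(truth.de_genes), OUT / "deg.txt")
    print(f"wrote {counts.shape[0]} genes x {counts.shape[1]} samples to {OUT}")
    print(f"planted: {len(truth.ts_genes)} TS genes, {len(truth.de_genes)} DE "
          f"genes, {len(truth.modules)} modules "
          f"({len(truth.rewired_genes)} rewired genes), "
          f"{len(truth.tf_catalogue)} catalogue TFs")


if __name__ == "__main__":
    main()
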