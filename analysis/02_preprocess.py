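#!/usr/bin/env python
"""Filter and normalize the counts under both strategies.

Strategy 1 (pooled over all tissues) feeds tissue-specificity, regulator
scoring and the tissue-to-tissue network; strategy 2 (per tissue, with the
additional low-dispersion filter) feeds the condition-contrast analyses.
"""

from pathlib import Path

from coexnet import io, preprocess

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    counts = io.read_counts(BASE / "data" / "counts.tsv")
    metadata = io.read_metadata(BASE / "data" / "samples.tsv")
    out = BASE / "normalized"
    out.mkdir(parents=True, exist_ok=True)

    pooled = preprocess.normalize_counts(counts, metadata,
                                         strategy="pooled")["pooled"]
    pooled.data.rename_axis("gene").to_csv(out / "pooled.tsv", sep="\t")
    print(f"pooled: {pooled.data.shape[0]} genes kept; filters: {pooled.filters}")

    per_tissue = preprocess.normalize_counts(counts, metadata,
                                             strategy="per-tissue")
    for tissue, nm in per_tissue.items():
        nm.data.rename_axis("gene").to_csv(out / f"{tissue}.tsv", sep="\t")
        print(f"{tissue}: {nm.data.shape[0]} genes kept; filters: {nm.filters}")


if __name__ == "__main__":
    main()
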