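#!/usr/bin/env python
"""Contrast condition-specific networks: DK scores and union networks.

Per tissue, PCIT networks are built separately from CON and RES samples
(edges must touch a DE gene or catalogue TF and exceed |r| > 0.9), gene
connectivities are max-normalized, and DK = K_CON - K_RES is z-scored;
|z| >= 1.96 flags rewired genes.  Writes the DK tables, the union networks
with provenance tags, a connectivity CDF table and (if matplotlib is
available) the CDF plot.
"""

from pathlib import Path

import pandas as pd

from coexnet import connectivity as conn
from coexnet import io, network, simulate

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    metadata = io.read_metadata(BASE / "data" / "samples.tsv")
    truth = simulate.read_truth(BASE / "data")
    flag = set(truth.de_genes) | set(truth.tf_catalogue)
    rewired_regs = [m.regulator for m in truth.modules.values() if m.rewired]

    cdf_rows = []
    for tissue in metadata["tissue"].unique():
        norm = pd.read_csv(BASE / "normalized" / f"{tissue}.tsv",
                           sep="\t", index_col=0)
        nets = {}
        for cond in ("CON", "RES"):
            cols = [c for c in norm.columns
                    if metadata.loc[c, "condition"] == cond]
            nets[cond] = network.build_network(norm[cols], min_abs_r=0.9,
                                               require_flag_genes=flag)
        dk = conn.dk_scores(nets["CON"], nets["RES"])
        dk.to_csv(BASE / f"dk_{tissue}.tsv", sep="\t")
        uni = conn.union_network(nets["CON"], nets["RES"])
        io.export_network(uni, BASE / f"union_{tissue}")
        gain = conn.connectivity_gain(nets["CON"], nets["RES"])
        print(f"{tissue}: CON {gain['CON']['n_edges']} edges, "
              f"RES {gain['RES']['n_edges']} edges -> connectivity gain in "
              f"{gain['gain']}; {int(dk['significant'].sum())} DK genes")
        for reg in rewired_regs:
            if reg in dk.index:
                row = dk.loc[reg]
                print(f"  {reg}: DK = {row.dk:+.2f}, z = {row.z:+.2f}, "
                      f"significant = {bool(row.significant)}")
        tbl = gain["cdf"].assign(tissue=tissue)
        cdf_rows.append(tbl)
    cdf = pd.concat(cdf_rows, ignore_index=True)
    cdf.to_csv(BASE / "connectivity_cdf.tsv", sep="\t", index=False)

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, cdf["tissue"].nunique(), figsize=(11, 3.2),
                                 sharey=True)
        for ax, (tissue, grp) in zip(axes, cdf.groupby("tissue")):
            for cond, sub in grp.groupby("condition"):
                ax.step(sub["degree"], sub["cdf"], where="post", label=cond)
            ax.set_title(tissue)
            ax.set_xlabel("connectivity (degree)")
        axes[0].set_ylabel("cumulative fraction of genes")
        axes[0].legend()
        fig.tight_layout()
        fig.savefig(BASE / "connectivity_cdf.png", dpi=150)
        print(f"wrote {BASE / 'connectivity_cdf.png'}")
    except ImportError:
        print("matplotlib not available; skipped the CDF plot")


if __name__ == "__main__":
    main()
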