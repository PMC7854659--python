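"""End-to-end orchestration of the multi-tissue network workflow.

``run_all`` reproduces the full analysis on one dataset (synthetic by
default): pooled and per-tissue normalization, Tau tissue-specificity,
per-tissue regulator scoring (RIF), the tissue-to-tissue PCIT network over
the prioritized genes (DEG u TS u significant TFs), per-tissue differential
co-expression, and per-tissue condition networks with differential
connectivity.  Every stage logs its input/output gene counts and all tables
land in the output directory together with a JSON manifest (seed,
thresholds, package versions) sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import dgca, io, network, preprocess, rif, simulate, tau

__all__ = ["PipelineConfig", "run_all"]

log = logging.getLogger("coexnet")


@dataclass
class PipelineConfig:
    """Paths, thresholds and switches of one pipeline run."""

    # inputs; all None -> simulate a synthetic dataset
    counts: str | None = None
    metadata: str | None = None
    deg_lists: dict[str, str] = field(default_factory=dict)   # tissue -> path
    tf_catalogue: str | None = None
    # thresholds (defaults are the study's printed cutoffs)
    cpm_threshold: float = 1.0
    cpm_fraction: float = 0.8
    dispersion_quantile: float = 0.2
    tau_cutoff: float = 0.8
    rif_alpha: float = 0.01
    min_abs_r: float = 0.9
    dc_q: float = 0.05
    dc_alpha_within: float = 0.05
    dk_z: float = 1.96
    hub_sd: float = 2.0
    # switches
    adjust_sex: bool = False
    dc_permutations: int = 0
    seed: int = 0
    sim: simulate.SimConfig | None = None

    def validate(self) -> None:
        for name, val, lo, hi in (
                ("cpm_fraction", self.cpm_fraction, 0.0, 1.0),
                ("dispersion_quantile", self.dispersion_quantile, 0.0, 1.0),
                ("tau_cutoff", self.tau_cutoff, 0.0, 1.0),
                ("rif_alpha", self.rif_alpha, 0.0, 1.0),
                ("min_abs_r", self.min_abs_r, 0.0, 1.0),
                ("dc_q", self.dc_q, 0.0, 1.0),
                ("dc_alpha_within", self.dc_alpha_within, 0.0, 1.0)):
            if not lo <= val <= hi:
                raise ValueError(f"{name}={val} outside [{lo}, {hi}]")
        if self.dk_z < 0 or self.hub_sd < 0:
            raise ValueError("dk_z and hub_sd must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_cfg = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_cfg:
            cfg.sim = simulate.SimConfig(**sim_cfg)
        return cfg


def _versions() -> dict[str, str]:
    import networkx
    import scipy
    import statsmodels

    return {"numpy": np.__version__, "pandas": pd.__version__,
            "scipy": scipy.__version__, "networkx": networkx.__version__,
            "statsmodels": statsmodels.__version__}


def _stage(name: str):
    log.info("stage: %s", name)


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the whole workflow; returns a dict of in-memory results.

    Partial outputs are retained on failure; the raised error names the
    stage that failed.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest: dict = {
        "seed": config.seed,
        "thresholds": {k: getattr(config, k) for k in (
            "cpm_threshold", "cpm_fraction", "dispersion_quantile", "tau_cutoff",
            "rif_alpha", "min_abs_r", "dc_q", "dc_alpha_within", "dk_z", "hub_sd")},
        "versions": _versions(),
        "stages": {},
    }
    stage = "inputs"
    try:
        # ------------------------------------------------------------------
        _stage(stage)
        if config.counts is None:
            sim_cfg = config.sim or simulate.SimConfig(seed=config.seed)
            if config.sim is None:
                sim_cfg = dataclasses.replace(sim_cfg, seed=config.seed)
            counts, metadata, truth = simulate.simulate_dataset(sim_cfg)
            io.write_counts(counts, outdir / "counts.tsv")
            io.write_metadata(metadata, outdir / "samples.tsv")
            simulate.write_truth(truth, outdir, genes=list(counts.index))
            deg_lists = {t: sorted(truth.de_genes) for t in metadata["tissue"].unique()}
            tf_list = list(truth.tf_catalogue)
            results["truth"] = truth
            manifest["stages"][stage] = {"source": "synthetic",
                                         "sim": dataclasses.asdict(sim_cfg)}
        else:
            counts = io.read_counts(config.counts)
            metadata = io.read_metadata(config.metadata)
            known = set(counts.index)
            deg_lists = {t: io.read_gene_list(p, known)
                         for t, p in config.deg_lists.items()}
            if config.tf_catalogue:
                tf_list = io.read_gene_list(config.tf_catalogue, known)
            else:
                tf_list = []
            manifest["stages"][stage] = {"source": str(config.counts)}
        results["counts"], results["metadata"] = counts, metadata
        manifest["stages"][stage].update(
            n_genes=int(counts.shape[0]), n_samples=int(counts.shape[1]))

        # ------------------------------------------------------------------
        stage = "preprocess"
        _stage(stage)
        pooled = preprocess.normalize_counts(
            counts, metadata, strategy="pooled",
            cpm_threshold=config.cpm_threshold, cpm_fraction=config.cpm_fraction,
            adjust_sex=config.adjust_sex)["pooled"]
        per_tissue = preprocess.normalize_counts(
            counts, metadata, strategy="per-tissue",
            cpm_threshold=config.cpm_threshold, cpm_fraction=config.cpm_fraction,
            dispersion_quantile=config.dispersion_quantile,
            adjust_sex=config.adjust_sex)
        pooled.data.rename_axis("gene").to_csv(outdir / "normalized_pooled.tsv", sep="\t")
        results["pooled"], results["per_tissue"] = pooled, per_tissue
        manifest["stages"][stage] = {
            "pooled": {"genes": int(pooled.data.shape[0]), "filters": pooled.filters},
            **{t: {"genes": int(nm.data.shape[0]), "filters": nm.filters}
               for t, nm in per_tissue.items()}}

        # ------------------------------------------------------------------
        stage = "tau"
        _stage(stage)
        means = tau.tissue_means(pooled.data, metadata)
        tau_tbl = tau.tau_table(means)
        ts_tbl = tau.call_tissue_specific(tau_tbl, config.tau_cutoff)
        tau_tbl.rename_axis("gene").to_csv(outdir / "tau.tsv", sep="\t")
        ts_genes = {t: ts_tbl.index[ts_tbl["home_tissue"] == t].tolist()
                    for t in metadata["tissue"].unique()}
        results["tau"], results["ts_genes"] = tau_tbl, ts_genes
        manifest["stages"][stage] = {"n_ts": int(len(ts_tbl)),
                                     "per_tissue": {t: len(g) for t, g in ts_genes.items()}}

        # ------------------------------------------------------------------
        stage = "rif"
        _stage(stage)
        rif_tables = {}
        sig_tfs: set[str] = set()
        tfs_present = [g for g in tf_list if g in pooled.data.index]
        if not tfs_present:
            warnings.warn("no TF catalogue genes present; RIF stage skipped")
            manifest["stages"][stage] = {"skipped": True}
        else:
            for t in metadata["tissue"].unique():
                cols = metadata.index[metadata["tissue"] == t]
                sub = pooled.data[[c for c in cols if c in pooled.data.columns]]
                targets = sorted((set(deg_lists.get(t, [])) | set(ts_genes[t]))
                                 & set(sub.index) - set(tfs_present))
                if not targets:
                    warnings.warn(f"no RIF targets for tissue {t}; skipped")
                    continue
                r_con, r_res = rif.condition_correlations(sub, metadata,
                                                          tfs_present, targets)
                summ = rif.target_summaries(sub, metadata, targets)
                scores = rif.rif_scores(r_con, r_res, summ, alpha=config.rif_alpha)
                scores.insert(0, "tissue", t)
                rif_tables[t] = scores
                sig_tfs |= set(scores.index[scores["significant"]])
            if rif_tables:
                all_rif = pd.concat(rif_tables.values())
                all_rif.rename_axis("tf").to_csv(outdir / "rif.tsv", sep="\t")
            manifest["stages"][stage] = {
                t: int(tbl["significant"].sum()) for t, tbl in rif_tables.items()}
        results["rif"] = rif_tables

        # ------------------------------------------------------------------
        stage = "tissue_network"
        _stage(stage)
        all_deg = set().union(*deg_lists.values()) if deg_lists else set()
        all_ts = set(ts_tbl.index)
        prioritized = sorted((all_deg | all_ts | sig_tfs) & set(pooled.data.index))
        flags = {g: {"is_deg": g in all_deg, "is_ts": g in all_ts,
                     "is_tf": g in sig_tfs} for g in prioritized}
        home = tau_tbl["home_tissue"].to_dict()
        net = network.build_network(pooled.data, prioritized,
                                    min_abs_r=config.min_abs_r,
                                    node_flags=flags, node_tissue=home)
        stats = network.network_stats(net, groups=home, hub_sd=config.hub_sd)
        io.export_network(net, outdir / "tissue_network")
        results["tissue_network"], results["tissue_network_stats"] = net, stats
        manifest["stages"][stage] = {
            "prioritized": len(prioritized), "nodes": stats.n_nodes,
            "edges": stats.n_edges, "clustering": stats.clustering,
            "scale_free_r2": None if np.isnan(stats.scale_free_r2)
            else stats.scale_free_r2,
            "hubs": len(stats.hubs)}

        # ------------------------------------------------------------------
        stage = "differential_coexpression"
        _stage(stage)
        dc_tables = {}
        for t, nm in per_tissue.items():
            touching = None
            if t == "cerebrum":   # largest pair universe is cut post hoc
                keep = (all_deg | all_ts | sig_tfs) & set(nm.data.index)
                touching = keep or None
            tbl = dgca.dc_analysis(nm.data, metadata, touching=touching,
                                   alpha_within=config.dc_alpha_within,
                                   q_threshold=config.dc_q,
                                   permutations=config.dc_permutations,
                                   seed=config.seed)
            tbl.to_csv(outdir / f"dc_{t}.tsv", sep="\t", index=False)
            dc_tables[t] = tbl
            manifest["stages"].setdefault(stage, {})[t] = {
                "pairs": int(len(tbl)), "significant": int(tbl["significant"].sum())}
        results["dc"] = dc_tables

        # ------------------------------------------------------------------
        stage = "differential_connectivity"
        _stage(stage)
        dk_tables, unions = {}, {}
        flag_genes = all_deg | set(tfs_present)
        for t, nm in per_tissue.items():
            nets = {}
            for cond in ("CON", "RES"):
                cols = [c for c in nm.data.columns
                        if metadata.loc[c, "condition"] == cond]
                nets[cond] = network.build_network(
                    nm.data[cols], min_abs_r=config.min_abs_r,
                    require_flag_genes=flag_genes or None)
            if any(n.number_of_edges() == 0 for n in nets.values()):
                warnings.warn(f"tissue {t}: empty condition network; DK skipped")
                continue
            dk = conn.dk_scores(nets["CON"], nets["RES"], z_threshold=config.dk_z)
            dk.to_csv(outdir / f"dk_{t}.tsv", sep="\t")
            uni = conn.union_network(nets["CON"], nets["RES"])
            io.export_network(uni, outdir / f"union_{t}")
            gain = conn.connectivity_gain(nets["CON"], nets["RES"])
            dk_tables[t], unions[t] = dk, uni
            manifest["stages"].setdefault(stage, {})[t] = {
                "dk_significant": int(dk["significant"].sum()),
                "gain": gain["gain"],
                "con": {k: gain["CON"][k] for k in ("n_nodes", "n_edges")},
                "res": {k: gain["RES"][k] for k in ("n_nodes", "n_edges")}}
        results["dk"], results["unions"] = dk_tables, unions

    except Exception as err:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
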