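"""Synthetic RNA-seq count generator for a multi-tissue, two-condition design.

Emulates a study layout of three fetal tissues (cerebrum, liver, muscle)
sampled under two maternal-diet conditions (CON, RES) with seven animals per
condition and tissue.  The generator plants the structures every downstream
stage of the pipeline looks for:

* tissue-specific genes -- strongly elevated in one home tissue, nearly silent
  elsewhere, so the Tau index approaches 1;
* differentially expressed genes -- a fixed log2 fold change between the
  conditions, in every tissue;
* transcription-factor modules -- one regulator plus a block of targets whose
  co-expression is induced by a per-sample latent Gaussian factor.  The
  regulator carries the factor with loading one; target loadings are solved so
  the model-implied regulator-target Pearson correlation on the log scale
  equals the configured coupling, separately per condition.  Modules whose
  coupling differs between conditions are the planted "rewired" structure;
* a housekeeping background of uncorrelated genes spanning a wide expression
  range, so low-expression filtering has something to remove.

Counts follow a hierarchical log-normal / Gamma-Poisson (negative binomial)
model: a per-gene, per-sample log mean (baseline + planted effects + latent
factors + biological noise) is converted to within-sample proportions,
multiplied by a log-normal library size, and overdispersed with a technical
dispersion parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "ModuleTruth",
    "GroundTruth",
    "simulate_dataset",
    "write_truth",
    "read_truth",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reproduce a small but complete version of the study design:
    600 genes, 3 tissues x (7 CON + 7 RES) fetuses, 30 tissue-specific genes
    per tissue, 40 stand-alone DE genes and 3 regulator modules of 20 genes,
    one stable, one sign-flipped between conditions and one decoupled in RES.
    """

    n_genes: int = 600
    n_tissues: int = 3
    n_per_condition: int = 7
    tissue_names: tuple[str, ...] = ("cerebrum", "liver", "muscle")
    condition_names: tuple[str, str] = ("CON", "RES")
    # tissue-specific genes
    n_ts_per_tissue: int = 30
    ts_fold: float = 100.0          # home/off-home expression ratio
    ts_off_cpm: float = 0.5         # off-home abundance, anchored in CPM units
    # differentially expressed genes (stand-alone; module targets may add more)
    n_de: int = 40
    de_log2fc: float = 1.0
    # regulator modules (regulator + module_size-1 targets each)
    n_modules: int = 3
    module_size: int = 20
    coupling_con: tuple[float, ...] = (0.9, 0.8, 0.9)
    coupling_res: tuple[float, ...] = (0.9, -0.8, 0.0)
    module_de_frac: float = 0.5     # fraction of targets that are also DE
    # noise model
    nb_dispersion: float = 0.01     # technical Gamma-Poisson dispersion
    bio_sd: float = 0.25           # biological log-normal sd (natural log)
    sex_effect: float = 0.35       # additive natural-log effect on ~1% genes
    library_size_mean: float = 2.0e6
    library_size_cv: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_tissues < 1 or len(self.tissue_names) != self.n_tissues:
            raise ValueError("tissue_names must match n_tissues")
        if len(self.condition_names) != 2:
            raise ValueError("exactly two conditions are supported")
        if self.n_per_condition < 1:
            raise ValueError("n_per_condition must be >= 1")
        if self.module_size < 2 and self.n_modules > 0:
            raise ValueError("module_size must be >= 2 (regulator + targets)")
        if len(self.coupling_con) != self.n_modules or len(self.coupling_res) != self.n_modules:
            raise ValueError("coupling_con/coupling_res must have one entry per module")
        for rho in (*self.coupling_con, *self.coupling_res):
            if not abs(rho) < 1:
                raise ValueError(f"module coupling must satisfy |rho| < 1, got {rho}")
        if self.ts_fold <= 1:
            raise ValueError("ts_fold must be > 1")
        if self.ts_off_cpm <= 0:
            raise ValueError("ts_off_cpm must be positive")
        if not 0 <= self.module_de_frac <= 1:
            raise ValueError("module_de_frac must be in [0, 1]")
        if self.nb_dispersion < 0 or self.bio_sd < 0:
            raise ValueError("dispersion parameters must be non-negative")
        if self.library_size_mean <= 0 or self.library_size_cv < 0:
            raise ValueError("library size parameters out of range")
        budget = (self.n_ts_per_tissue * self.n_tissues
                  + self.n_modules * self.module_size + self.n_de)
        if budget > self.n_genes:
            raise ValueError(
                f"gene budget infeasible: {budget} planted genes > n_genes={self.n_genes}")


@dataclass(frozen=True)
class ModuleTruth:
    name: str
    regulator: str
    members: tuple[str, ...]        # targets, excluding the regulator
    coupling_con: float
    coupling_res: float

    @property
    def rewired(self) -> bool:
        return self.coupling_con != self.coupling_res


@dataclass
class GroundTruth:
    """What was planted, keyed by gene id."""

    ts_genes: dict[str, str]            # gene -> home tissue
    de_genes: dict[str, float]          # gene -> log2 fold change (CON -> RES)
    modules: dict[str, ModuleTruth]
    tf_catalogue: tuple[str, ...]       # regulators + background decoys

    @property
    def rewired_genes(self) -> set[str]:
        out: set[str] = set()
        for mod in self.modules.values():
            if mod.rewired:
                out.update((mod.regulator, *mod.members))
        return out

    def validate_against(self, genes: Sequence[str]) -> None:
        known = set(genes)
        listed = (set(self.ts_genes) | set(self.de_genes) | set(self.tf_catalogue)
                  | {g for m in self.modules.values() for g in (m.regulator, *m.members)})
        unknown = sorted(listed - known)
        if unknown:
            raise ValueError(f"truth refers to unknown genes: {unknown[:10]}")


def _target_loading(rho: float, sigma2: float, psi: float) -> float:
    """Latent-factor loading giving regulator-target correlation rho.

    The regulator carries the factor with loading 1 and idiosyncratic
    log-variance psi (count noise); a target has loading a, biological
    variance sigma2 and the same count noise.  Solving
    corr = a / sqrt((1 + psi)(a^2 + sigma2 + psi)) = |rho| for a gives the
    expression below; the sign of rho is carried by the loading.
    """
    if rho == 0:
        return 0.0
    r2 = rho * rho * (1.0 + psi)
    if r2 >= 1:
        raise ValueError(f"coupling {rho} unattainable under count noise psi={psi:.3g}")
    return math.copysign(math.sqrt(r2 * (sigma2 + psi) / (1.0 - r2)), rho)


def _gene_ids(cfg: SimConfig) -> tuple[list[str], dict[str, list[str]]]:
    """Deterministic gene naming; returns all ids and the planted blocks."""
    blocks: dict[str, list[str]] = {}
    ids: list[str] = []
    for t in cfg.tissue_names:
        names = [f"TS_{t}_{i:03d}" for i in range(cfg.n_ts_per_tissue)]
        blocks[f"ts_{t}"] = names
        ids += names
    for m in range(cfg.n_modules):
        reg = f"M{m + 1}_REG"
        tgts = [f"M{m + 1}_T{i:02d}" for i in range(1, cfg.module_size)]
        blocks[f"module_{m}"] = [reg] + tgts
        ids += [reg] + tgts
    de = [f"DE_{i:03d}" for i in range(cfg.n_de)]
    blocks["de"] = de
    ids += de
    n_bg = cfg.n_genes - len(ids)
    bg = [f"BG_{i:04d}" for i in range(n_bg)]
    blocks["background"] = bg
    ids += bg
    return ids, blocks


def simulate_dataset(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw one synthetic dataset.

    Returns
    -------
    counts : DataFrame, genes x samples, non-negative integers.
    metadata : DataFrame indexed by sample with tissue/condition/sex columns.
    truth : GroundTruth of the planted structure.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes, blocks = _gene_ids(cfg)
    n_genes = cfg.n_genes
    gene_pos = {g: i for i, g in enumerate(genes)}

    # -- samples ------------------------------------------------------------
    rows = []
    for t in cfg.tissue_names:
        for cond in cfg.condition_names:
            for k in range(cfg.n_per_condition):
                rows.append({
                    "sample": f"{t}_{cond}_{k + 1:02d}",
                    "tissue": t,
                    "condition": cond,
                    # alternate sexes within each tissue x condition cell
                    "sex": "M" if k % 2 == 0 else "F",
                })
    metadata = pd.DataFrame(rows).set_index("sample")
    n_samples = len(metadata)
    con_name, res_name = cfg.condition_names
    is_res = (metadata["condition"] == res_name).to_numpy()
    is_male = (metadata["sex"] == "M").to_numpy()
    tissue_idx = np.array([cfg.tissue_names.index(t) for t in metadata["tissue"]])

    # -- per-gene, per-tissue baselines (natural log of relative expression) -
    base = np.empty((n_genes, cfg.n_tissues))
    n_bg = len(blocks["background"])
    bg_rows = [gene_pos[g] for g in blocks["background"]]
    base[bg_rows, :] = rng.normal(math.log(50.0), 1.5, size=n_bg)[:, None]
    for g in blocks["de"]:
        base[gene_pos[g], :] = rng.normal(math.log(100.0), 0.5)
    module_rows: list[int] = []
    for m in range(cfg.n_modules):
        for g in blocks[f"module_{m}"]:
            r = gene_pos[g]
            base[r, :] = math.log(300.0) + rng.normal(0.0, 0.2)
            module_rows.append(r)
    # TS baselines are anchored to a target off-home CPM so the planted Tau
    # profile does not drift with the size of the gene panel
    non_ts = bg_rows + [gene_pos[g] for g in blocks["de"]] + module_rows
    t_rest = float(np.exp(base[non_ts, :]).sum(axis=0).mean()) if non_ts else 1.0
    ts_low = math.log(cfg.ts_off_cpm / 1.0e6 * max(t_rest, 1e-12))
    ts_high = ts_low + math.log(cfg.ts_fold)
    truth_ts: dict[str, str] = {}
    for ti, t in enumerate(cfg.tissue_names):
        for g in blocks[f"ts_{t}"]:
            base[gene_pos[g], :] = ts_low
            base[gene_pos[g], ti] = ts_high
            truth_ts[g] = t

    # -- DE effects ----------------------------------------------------------
    truth_de: dict[str, float] = {}
    lfc = np.zeros(n_genes)
    for i, g in enumerate(blocks["de"]):
        truth_de[g] = cfg.de_log2fc * (1 if i % 2 == 0 else -1)
        lfc[gene_pos[g]] = truth_de[g]
    # a fraction of each module's targets is also DE, so regulator scoring
    # (which looks only at DEG/TS targets) can see the planted modules
    modules: dict[str, ModuleTruth] = {}
    for m in range(cfg.n_modules):
        block = blocks[f"module_{m}"]
        reg, tgts = block[0], block[1:]
        n_mde = int(round(cfg.module_de_frac * len(tgts)))
        # one coherent DE direction per module (a jointly activated or
        # repressed target program), alternating across modules -- signed
        # PIF weights would cancel if directions alternated within a module
        sign = 1 if m % 2 == 0 else -1
        for g in tgts[:n_mde]:
            truth_de[g] = cfg.de_log2fc * sign
            lfc[gene_pos[g]] = truth_de[g]
        modules[f"M{m + 1}"] = ModuleTruth(
            name=f"M{m + 1}", regulator=reg, members=tuple(tgts),
            coupling_con=cfg.coupling_con[m], coupling_res=cfg.coupling_res[m])

    # -- sex covariate: small additive effect on ~1% of genes ----------------
    n_sex = max(1, int(round(0.01 * n_genes)))
    sex_rows = rng.choice(n_genes, size=n_sex, replace=False)
    sex_eff = np.zeros(n_genes)
    sex_eff[sex_rows] = cfg.sex_effect

    # -- latent module factors ------------------------------------------------
    # expected count-noise log-variance for module genes (they are highly
    # expressed, so 1/mu is a small correction on top of the NB dispersion)
    mean_total = np.exp(base).sum(axis=0).mean()
    mu_module = cfg.library_size_mean * 300.0 / mean_total
    psi = cfg.nb_dispersion + 1.0 / mu_module
    sigma2 = cfg.bio_sd ** 2
    loadings = np.zeros((n_genes, 2))  # columns: CON, RES
    factor_of_gene = np.full(n_genes, -1)
    for m, mod in enumerate(modules.values()):
        a_con = _target_loading(mod.coupling_con, sigma2, psi)
        a_res = _target_loading(mod.coupling_res, sigma2, psi)
        loadings[gene_pos[mod.regulator]] = (1.0, 1.0)
        factor_of_gene[gene_pos[mod.regulator]] = m
        for g in mod.members:
            loadings[gene_pos[g]] = (a_con, a_res)
            factor_of_gene[gene_pos[g]] = m
    factors = rng.standard_normal((max(cfg.n_modules, 1), n_samples))

    # -- assemble log means ----------------------------------------------------
    log_mu = base[:, tissue_idx]
    log_mu = log_mu + np.where(is_res[None, :], lfc[:, None] * math.log(2.0), 0.0)
    log_mu = log_mu + sex_eff[:, None] * is_male[None, :]
    cond_col = is_res.astype(int)
    in_module = factor_of_gene >= 0
    if cfg.n_modules:
        load_per_sample = loadings[:, cond_col]          # genes x samples
        fac_per_gene = factors[np.clip(factor_of_gene, 0, None), :]
        log_mu = log_mu + np.where(in_module[:, None], load_per_sample * fac_per_gene, 0.0)
    # biological noise for every gene except module regulators (which carry
    # the latent factor as their entire biological signal)
    noise = rng.normal(0.0, cfg.bio_sd, size=(n_genes, n_samples))
    is_reg = np.array([factor_of_gene[i] >= 0 and loadings[i, 0] == 1.0
                       for i in range(n_genes)])
    noise[is_reg, :] = 0.0
    log_mu = log_mu + noise

    # -- proportions, library sizes, counts ------------------------------------
    rel = np.exp(log_mu)
    props = rel / rel.sum(axis=0, keepdims=True)
    sigma_lib = math.sqrt(math.log(1.0 + cfg.library_size_cv ** 2))
    lib = rng.lognormal(math.log(cfg.library_size_mean) - sigma_lib ** 2 / 2.0,
                        sigma_lib, size=n_samples)
    mu = props * lib[None, :]
    if cfg.nb_dispersion > 0:
        lam = rng.gamma(1.0 / cfg.nb_dispersion, mu * cfg.nb_dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(np.int64)

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                             columns=metadata.index)

    # TF catalogue sized like a real one (~6.5% of the expressed panel):
    # the module regulators plus background decoys with no regulatory role
    n_decoys = min(max(int(round(0.065 * n_genes)) - cfg.n_modules, 10), n_bg)
    decoys = list(blocks["background"][:n_decoys])
    tf_catalogue = tuple([m.regulator for m in modules.values()] + decoys)
    truth = GroundTruth(ts_genes=truth_ts, de_genes=truth_de,
                        modules=modules, tf_catalogue=tf_catalogue)
    truth.validate_against(genes)
    return counts_df, metadata, truth


# ---------------------------------------------------------------------------
# truth round-trip
# ---------------------------------------------------------------------------

def write_truth(truth: GroundTruth, outdir: str | Path,
                genes: Sequence[str] | None = None) -> dict[str, Path]:
    """Write the ground truth as plain TSV/TXT files; returns written paths."""
    if genes is not None:
        truth.validate_against(genes)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    ts = pd.DataFrame(sorted(truth.ts_genes.items()), columns=["gene", "tissue"])
    paths["ts"] = outdir / "truth_ts.tsv"
    ts.to_csv(paths["ts"], sep="\t", index=False)
    de = pd.DataFrame(sorted(truth.de_genes.items()), columns=["gene", "log2fc"])
    paths["de"] = outdir / "truth_de.tsv"
    de.to_csv(paths["de"], sep="\t", index=False)
    rows = []
    for mod in truth.modules.values():
        rows.append({"module": mod.name, "role": "regulator", "gene": mod.regulator,
                     "coupling_con": mod.coupling_con, "coupling_res": mod.coupling_res})
        for g in mod.members:
            rows.append({"module": mod.name, "role": "target", "gene": g,
                         "coupling_con": mod.coupling_con, "coupling_res": mod.coupling_res})
    cols = ["module", "role", "gene", "coupling_con", "coupling_res"]
    paths["modules"] = outdir / "truth_modules.tsv"
    pd.DataFrame(rows, columns=cols).to_csv(paths["modules"], sep="\t", index=False)
    paths["tf"] = outdir / "truth_tf_catalogue.txt"
    paths["tf"].write_text("".join(f"{g}\n" for g in truth.tf_catalogue))
    return paths


def read_truth(outdir: str | Path) -> GroundTruth:
    """Inverse of :func:`write_truth`."""
    outdir = Path(outdir)
    ts = pd.read_csv(outdir / "truth_ts.tsv", sep="\t")
    de = pd.read_csv(outdir / "truth_de.tsv", sep="\t")
    mods = pd.read_csv(outdir / "truth_modules.tsv", sep="\t")
    modules: dict[str, ModuleTruth] = {}
    for name, grp in mods.groupby("module", sort=False):
        regs = grp.loc[grp["role"] == "regulator", "gene"].tolist()
        if len(regs) != 1:
            raise ValueError(f"module {name} must have exactly one regulator")
        modules[str(name)] = ModuleTruth(
            name=str(name), regulator=regs[0],
            members=tuple(grp.loc[grp["role"] == "target", "gene"]),
            coupling_con=float(grp["coupling_con"].iloc[0]),
            coupling_res=float(grp["coupling_res"].iloc[0]))
    tf_path = outdir / "truth_tf_catalogue.txt"
    tfs = tuple(tf_path.read_text().split()) if tf_path.exists() else ()
    return GroundTruth(ts_genes=dict(zip(ts["gene"], ts["tissue"])),
                       de_genes=dict(zip(de["gene"], de["log2fc"])),
                       modules=modules, tf_catalogue=tfs)
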