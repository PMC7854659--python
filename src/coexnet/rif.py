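"""Regulatory impact factors (RIF1 / RIF2).

Scores each candidate regulator (transcription factor) by how differently it
is wired to a list of target genes in two conditions.  For target j with mean
expression e1_j (condition 1) and e2_j (condition 2), abundance
a_j = (e1_j + e2_j)/2, differential expression d_j = e1_j - e2_j and
phenotypic impact factor PIF_j = a_j * d_j; with r1_ij, r2_ij the
within-condition Pearson correlations of regulator i with target j and
dw_ij = r1_ij - r2_ij the differential wiring:

    RIF1_i = (1/n_t) * sum_j PIF_j * dw_ij^2
    RIF2_i = (1/n_t) * sum_j [(e1_j * r1_ij)^2 - (e2_j * r2_ij)^2]

RIF1 rewards regulators whose connection to high-impact targets changes;
RIF2 rewards change in a regulator's ability to predict target abundance.
Raw scores are z-standardized over the regulators of one tissue, and a
regulator is called significant when either |z| exceeds the two-sided normal
quantile for the chosen alpha (default 0.01).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "condition_correlations",
    "target_summaries",
    "rif_scores",
    "rank_regulators",
]


def _corr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of every row of `a` with every row of `b`.

    Rows with zero variance correlate 0 with everything (with a warning),
    so constant genes do not poison downstream scores.
    """
    n = a.shape[1]
    if n < 4:
        raise ValueError(f"need >= 4 samples per condition, got {n}")

    def _standardize(x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        flat = (sd == 0).ravel()
        if flat.any():
            warnings.warn(f"{int(flat.sum())} zero-variance gene(s); r set to 0")
        z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        return z

    za, zb = _standardize(np.asarray(a, float)), _standardize(np.asarray(b, float))
    r = za @ zb.T / n
    return np.clip(r, -1.0, 1.0)


def condition_correlations(norm: pd.DataFrame, metadata: pd.DataFrame,
                           tfs: list[str], targets: list[str],
                           conditions: tuple[str, str] = ("CON", "RES"),
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TF x target Pearson matrices within each condition."""
    for gset, name in ((tfs, "TF"), (targets, "target")):
        missing = [g for g in gset if g not in norm.index]
        if missing:
            raise ValueError(f"{name} gene(s) absent from matrix: {missing[:5]}")
    cond = metadata.loc[norm.columns, "condition"]
    out = []
    for c in conditions:
        cols = norm.columns[(cond == c).to_numpy()]
        if len(cols) == 0:
            raise ValueError(f"condition {c!r} has no samples")
        sub = norm[cols]
        r = _corr_rows(sub.loc[tfs].to_numpy(), sub.loc[targets].to_numpy())
        out.append(pd.DataFrame(r, index=pd.Index(tfs, name="tf"),
                                columns=pd.Index(targets, name="target")))
    return out[0], out[1]


def target_summaries(norm: pd.DataFrame, metadata: pd.DataFrame,
                     targets: list[str],
                     conditions: tuple[str, str] = ("CON", "RES")) -> pd.DataFrame:
    """Per-target condition means, abundance, DE and PIF."""
    cond = metadata.loc[norm.columns, "condition"]
    e1 = norm.loc[targets, norm.columns[(cond == conditions[0]).to_numpy()]].mean(axis=1)
    e2 = norm.loc[targets, norm.columns[(cond == conditions[1]).to_numpy()]].mean(axis=1)
    out = pd.DataFrame({"e_con": e1, "e_res": e2})
    out["abundance"] = (out["e_con"] + out["e_res"]) / 2.0
    out["de"] = out["e_con"] - out["e_res"]
    out["pif"] = out["abundance"] * out["de"]
    out.index.name = "target"
    return out


def rif_scores(corr_con: pd.DataFrame, corr_res: pd.DataFrame,
               summaries: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Raw and z-standardized RIF1/RIF2 per regulator.

    This function is the single place the RIF formulas live; swap it out to
    try a different scoring variant.
    """
    if not corr_con.index.equals(corr_res.index) or not corr_con.columns.equals(corr_res.columns):
        raise ValueError("condition correlation matrices must be conformable")
    targets = corr_con.columns
    n_t = len(targets)
    if n_t == 0:
        raise ValueError("no targets")
    s = summaries.loc[targets]
    r1 = corr_con.to_numpy()
    r2 = corr_res.to_numpy()
    dw = r1 - r2
    pif = s["pif"].to_numpy()
    e1 = s["e_con"].to_numpy()
    e2 = s["e_res"].to_numpy()
    rif1 = (pif[None, :] * dw ** 2).sum(axis=1) / n_t
    rif2 = ((e1[None, :] * r1) ** 2 - (e2[None, :] * r2) ** 2).sum(axis=1) / n_t

    def _z(x: np.ndarray) -> np.ndarray:
        sd = x.std(ddof=1) if x.size > 1 else 0.0
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    out = pd.DataFrame({
        "rif1_raw": rif1, "rif2_raw": rif2,
        "rif1_z": _z(rif1), "rif2_z": _z(rif2),
    }, index=corr_con.index.copy())
    out["significant"] = (out["rif1_z"].abs() >= zcrit) | (out["rif2_z"].abs() >= zcrit)
    return out


def rank_regulators(results: pd.DataFrame) -> pd.DataFrame:
    """Sort by the more extreme of |RIF1 z| and |RIF2 z|; ties by gene id."""
    if len(results) < 2:
        raise ValueError("need at least two regulators to rank")
    score = np.maximum(results["rif1_z"].abs(), results["rif2_z"].abs())
    out = results.assign(score=score).sort_index(kind="mergesort")
    return out.sort_values("score", ascending=False, kind="mergesort")
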