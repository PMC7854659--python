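"""Differential gene co-expression between two conditions.

For every unordered gene pair within one tissue, the Pearson correlation is
computed separately in each condition, the difference is tested with the
Fisher z statistic,

    dz = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)),

p-values come from the standard-normal tail (or optionally from permutation
of condition labels), and Benjamini-Hochberg q-values control the FDR over
all tested pairs.  Each pair is also assigned a differential-correlation
class: each condition is mapped to '+', '-' or '0' by the sign of its
correlation and its own two-sided significance (t-test on r at
``alpha_within``), and the class is the composite label such as "+/-" or
"0/+".  Pairs that are '0' in both conditions fall outside the eight
informative classes.

Note: the normal approximation behind the analytic Fisher z p-value is
anti-conservative for very small per-condition sample sizes (n ~ 7); the
permutation mode is the safer choice there.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "condition_pair_correlations",
    "fisher_z_diff",
    "adjust_fdr",
    "classify_pair",
    "dc_analysis",
    "dc_hubs",
]

_CLAMP = 1.0 - 1e-12


def _corr_and_p(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Full correlation matrix and two-sided t-test p-values for one condition."""
    n = x.shape[1]
    if n < 4:
        raise ValueError(f"need >= 4 samples per condition, got {n}")
    sd = x.std(axis=1)
    mu = x.mean(axis=1, keepdims=True)
    z = np.where(sd[:, None] > 0, (x - mu) / np.where(sd[:, None] > 0, sd[:, None], 1.0), 0.0)
    r = np.clip(z @ z.T / n, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r * r, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return r, p, n


def condition_pair_correlations(norm: pd.DataFrame, metadata: pd.DataFrame,
                                genes: list[str] | None = None,
                                conditions: tuple[str, str] = ("CON", "RES"),
                                touching: set[str] | None = None) -> pd.DataFrame:
    """Per-pair condition correlations and within-condition p-values.

    Returns one row per unordered pair (geneA < geneB in matrix order) with
    columns r_con, r_res, p_con, p_res, n_con, n_res.  ``touching``
    optionally restricts the output to pairs with at least one endpoint in
    the given set (used to cut the pair universe of large tissues).
    """
    if genes is not None:
        missing = [g for g in genes if g not in norm.index]
        if missing:
            raise ValueError(f"gene(s) absent from matrix: {missing[:5]}")
        norm = norm.loc[genes]
    cond = metadata.loc[norm.columns, "condition"]
    mats = {}
    for c in conditions:
        cols = norm.columns[(cond == c).to_numpy()]
        if len(cols) == 0:
            raise ValueError(f"condition {c!r} has no samples")
        mats[c] = _corr_and_p(norm[cols].to_numpy(dtype=float))
    ids = norm.index.to_numpy()
    iu = np.triu_indices(len(ids), k=1)
    r1, p1, n1 = mats[conditions[0]]
    r2, p2, n2 = mats[conditions[1]]
    out = pd.DataFrame({
        "geneA": ids[iu[0]], "geneB": ids[iu[1]],
        "r_con": r1[iu], "r_res": r2[iu],
        "p_con": p1[iu], "p_res": p2[iu],
    })
    out["n_con"] = n1
    out["n_res"] = n2
    if touching is not None:
        keep = out["geneA"].isin(touching) | out["geneB"].isin(touching)
        out = out.loc[keep].reset_index(drop=True)
    return out


def fisher_z_diff(r1, n1, r2, n2) -> tuple[np.ndarray, np.ndarray]:
    """Fisher z statistic and two-sided p for a difference in correlations.

    Correlations at exactly +-1 are clamped to +-(1 - 1e-12).
    Works element-wise on arrays.
    """
    r1 = np.clip(np.asarray(r1, dtype=float), -_CLAMP, _CLAMP)
    r2 = np.clip(np.asarray(r2, dtype=float), -_CLAMP, _CLAMP)
    n1 = np.asarray(n1)
    n2 = np.asarray(n2)
    if np.any(n1 < 4) or np.any(n2 < 4):
        raise ValueError("need n >= 4 in each condition")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    dz = (np.arctanh(r1) - np.arctanh(r2)) / se
    p = 2.0 * stats.norm.sf(np.abs(dz))
    return dz, p


def adjust_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _sign_code(r: np.ndarray, p: np.ndarray, alpha: float) -> np.ndarray:
    code = np.full(r.shape, "0", dtype=object)
    code[(p <= alpha) & (r > 0)] = "+"
    code[(p <= alpha) & (r < 0)] = "-"
    return code


def classify_pair(pairs: pd.DataFrame, alpha_within: float = 0.05) -> pd.Series:
    """Differential-correlation class label per pair, e.g. "+/-" or "0/+"."""
    con = _sign_code(pairs["r_con"].to_numpy(), pairs["p_con"].to_numpy(), alpha_within)
    res = _sign_code(pairs["r_res"].to_numpy(), pairs["p_res"].to_numpy(), alpha_within)
    return pd.Series([f"{a}/{b}" for a, b in zip(con, res)],
                     index=pairs.index, name="class")


def _permutation_p(norm: pd.DataFrame, metadata: pd.DataFrame,
                   pairs: pd.DataFrame, dz_obs: np.ndarray,
                   conditions: tuple[str, str], n_perm: int,
                   seed: int) -> np.ndarray:
    """Empirical two-sided p for dz by permuting condition labels."""
    rng = np.random.default_rng(seed)
    cond = metadata.loc[norm.columns, "condition"].to_numpy()
    x = norm.to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(norm.index)}
    ia = pairs["geneA"].map(pos).to_numpy()
    ib = pairs["geneB"].map(pos).to_numpy()
    exceed = np.ones(len(pairs))          # add-one correction
    n1 = int((cond == conditions[0]).sum())
    for _ in range(n_perm):
        perm = rng.permutation(len(cond))
        g1, g2 = perm[:n1], perm[n1:]

        def _r(cols: np.ndarray) -> np.ndarray:
            sub = x[:, cols]
            mu = sub.mean(axis=1, keepdims=True)
            sd = sub.std(axis=1, keepdims=True)
            z = np.where(sd > 0, (sub - mu) / np.where(sd > 0, sd, 1.0), 0.0)
            rr = np.clip(z @ z.T / sub.shape[1], -1.0, 1.0)
            return rr

        rr1, rr2 = _r(g1), _r(g2)
        dz_perm, _ = fisher_z_diff(rr1[ia, ib], len(g1), rr2[ia, ib], len(g2))
        exceed += np.abs(dz_perm) >= np.abs(dz_obs)
    return exceed / (n_perm + 1)


def dc_analysis(norm: pd.DataFrame, metadata: pd.DataFrame, *,
                genes: list[str] | None = None,
                conditions: tuple[str, str] = ("CON", "RES"),
                touching: set[str] | None = None,
                alpha_within: float = 0.05, q_threshold: float = 0.05,
                permutations: int = 0, seed: int = 0) -> pd.DataFrame:
    """Full differential co-expression table for one tissue.

    With ``permutations > 0`` the analytic Fisher z p-value is replaced by a
    label-permutation p-value (seed-controlled); otherwise the analytic
    normal tail is used.
    """
    pairs = condition_pair_correlations(norm, metadata, genes=genes,
                                        conditions=conditions, touching=touching)
    dz, p = fisher_z_diff(pairs["r_con"], pairs["n_con"],
                          pairs["r_res"], pairs["n_res"])
    pairs["dz"] = dz
    if permutations > 0:
        p = _permutation_p(norm if genes is None else norm.loc[genes], metadata,
                           pairs, dz, conditions, permutations, seed)
    pairs["p_diff"] = p
    pairs["q_diff"] = adjust_fdr(p)
    pairs["class"] = classify_pair(pairs, alpha_within)
    pairs["significant"] = pairs["q_diff"] <= q_threshold
    return pairs


def dc_hubs(pairs: pd.DataFrame, q_threshold: float = 0.05,
            sd_mult: float = 2.0) -> pd.DataFrame:
    """Per-gene count of significant DC partners, with hub calls.

    Hubs follow the shared degree rule: count >= mean + sd_mult * SD over
    genes appearing in at least one significant pair.
    """
    sig = pairs.loc[pairs["q_diff"] <= q_threshold]
    if sig.empty:
        return pd.DataFrame(columns=["dc_degree", "is_hub"])
    deg = pd.concat([sig["geneA"], sig["geneB"]]).value_counts().sort_index()
    mu, sd = float(deg.mean()), float(deg.std(ddof=1))
    cut = np.inf if (np.isnan(sd) or sd == 0) else mu + sd_mult * sd
    out = pd.DataFrame({"dc_degree": deg})
    out["is_hub"] = deg >= cut
    return out.sort_values("dc_degree", ascending=False)
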