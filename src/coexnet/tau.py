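"""Tissue-specificity scoring with the Tau index.

For a gene with mean expression x_i in each of n tissues, the profile is
max-normalized, x_hat_i = x_i / max_i(x_i), and

    tau = sum_i (1 - x_hat_i) / (n - 1)

Tau is 0 for a perfectly uniform profile and 1 for expression confined to a
single tissue.  Genes with tau >= 0.8 are called tissue-specific, annotated
with the tissue of maximal expression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["tissue_means", "tau_index", "tau_table", "call_tissue_specific"]

TS_CUTOFF = 0.8


def tissue_means(norm: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean expression per (gene, tissue).

    Negative normalized values are clipped to zero first, so the Tau index
    stays within [0, 1] (the index assumes non-negative expression).
    """
    tissues = metadata.loc[norm.columns, "tissue"]
    if tissues.isna().any():
        missing = norm.columns[tissues.isna()].tolist()
        raise ValueError(f"samples without tissue annotation: {missing[:5]}")
    clipped = norm.clip(lower=0.0)
    means = clipped.T.groupby(tissues).mean().T
    means.columns.name = "tissue"
    return means


def tau_index(profile) -> float:
    """Tau of a single per-tissue mean profile; NaN for an all-zero profile."""
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("profile must be a 1-D vector over >= 2 tissues")
    if (x < 0).any():
        raise ValueError("profile must be non-negative (clip first)")
    m = x.max()
    if m == 0:
        return float("nan")
    xhat = x / m
    return float((1.0 - xhat).sum() / (x.size - 1))


def tau_table(means: pd.DataFrame,
              tissue_order: list[str] | None = None) -> pd.DataFrame:
    """Per-gene Tau, home tissue and max-normalized profile.

    Ties for the home tissue are broken by `tissue_order` (defaults to the
    column order of `means`).
    """
    if means.shape[1] < 2:
        raise ValueError("need at least two tissues")
    order = list(tissue_order) if tissue_order else list(means.columns)
    m = means[order].to_numpy(dtype=float)
    if (m < 0).any():
        raise ValueError("tissue means must be non-negative (clip first)")
    maxv = m.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        xhat = m / maxv[:, None]
    tau = (1.0 - xhat).sum(axis=1) / (m.shape[1] - 1)
    tau[maxv == 0] = np.nan
    home = np.array(order, dtype=object)[m.argmax(axis=1)]
    home[maxv == 0] = None
    out = means[order].copy()
    out.columns = [f"mean_{t}" for t in order]
    out["tau"] = tau
    out["home_tissue"] = home
    return out


def call_tissue_specific(tau_tbl: pd.DataFrame, cutoff: float = TS_CUTOFF) -> pd.DataFrame:
    """Genes with tau >= cutoff (inclusive), sorted by tau descending."""
    out = tau_tbl.copy()
    out["is_ts"] = out["tau"] >= cutoff
    return (out[out["is_ts"]]
            .sort_values(["tau", "home_tissue"], ascending=[False, True],
                         kind="mergesort"))
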