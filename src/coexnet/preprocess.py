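"""Count filtering and normalization.

Two normalization strategies are supported, mirroring a common multi-tissue
design: (1) pooled -- all samples of all tissues normalized together, used by
the tissue-specificity, regulator-scoring and tissue-to-tissue network stages;
(2) per-tissue -- each tissue normalized on its own samples and additionally
filtered for low dispersion, used by the condition-contrast stages
(differential co-expression and differential connectivity).

The variance-stabilizing step is median-of-ratios size factors followed by
log2(x/sf + 1); downstream methods only require a monotone, roughly
variance-stabilized scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NormalizedMatrix",
    "cpm",
    "filter_low_expression",
    "estimate_size_factors",
    "vst_transform",
    "filter_low_dispersion",
    "adjust_covariate",
    "normalize_counts",
]


@dataclass
class NormalizedMatrix:
    """Log-scale expression with provenance of how it was produced."""

    data: pd.DataFrame                       # genes x samples
    strategy: str                            # "pooled" or "per-tissue:<name>"
    size_factors: pd.Series
    filters: list[str] = field(default_factory=list)

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates:
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dups[:5]}")
    if counts.columns.has_duplicates:
        dups = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups[:5]}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: each column rescaled to sum to 1e6."""
    _check_counts(counts)
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"sample(s) with all-zero counts: {zero}")
    return counts / totals * 1.0e6


def filter_low_expression(counts: pd.DataFrame, threshold: float = 1.0,
                          fraction: float = 0.8) -> pd.DataFrame:
    """Drop genes with CPM < `threshold` in at least `fraction` of samples.

    The boundary is read strictly: a gene is removed when the number of
    low-CPM samples is >= ceil(fraction * n_samples).
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    c = cpm(counts)
    n_low = (c < threshold).sum(axis=1)
    cut = math.ceil(fraction * counts.shape[1])
    return counts.loc[n_low < cut]


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Only genes with nonzero counts in every sample enter the reference
    geometric mean, as in the standard median-of-ratios estimator.
    """
    _check_counts(counts)
    if counts.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns, name="size_factor")
    x = counts.to_numpy(dtype=float)
    all_pos = (x > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; filter low-expression "
            "genes first")
    logx = np.log(x[all_pos])
    log_geo = logx.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logx - log_geo, axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def vst_transform(counts: pd.DataFrame,
                  size_factors: pd.Series | None = None) -> pd.DataFrame:
    """log2(count / size_factor + 1) on the size-factor-corrected scale."""
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    sf = size_factors.reindex(counts.columns)
    if sf.isna().any() or (sf <= 0).any():
        raise ValueError("size factors must be positive and cover all samples")
    return np.log2(counts / sf + 1.0)


def _dispersion(norm: pd.DataFrame) -> pd.Series:
    """Per-gene coefficient of variation of the normalized values."""
    mean = norm.mean(axis=1)
    sd = norm.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean.abs() > 0, sd / mean.abs(), 0.0)
    return pd.Series(cv, index=norm.index, name="cv")


def filter_low_dispersion(norm: pd.DataFrame, quantile: float = 0.2) -> pd.DataFrame:
    """Drop genes whose CV falls below the given quantile of all gene CVs."""
    if not 0 <= quantile < 1:
        raise ValueError(f"quantile must be in [0, 1), got {quantile}")
    if quantile == 0:
        return norm
    if norm.shape[0] < 5:
        raise ValueError("need at least 5 genes to estimate a dispersion quantile")
    disp = _dispersion(norm)
    cut = float(np.quantile(disp.to_numpy(), quantile))
    keep = disp >= cut
    if keep.all() and disp.nunique() == 1:
        warnings.warn("all genes tie on dispersion; nothing removed")
    return norm.loc[keep]


def adjust_covariate(norm: pd.DataFrame, metadata: pd.DataFrame,
                     covariate: str = "sex") -> pd.DataFrame:
    """Remove a categorical covariate by per-gene OLS residualization.

    The covariate's group means are equalized per gene; the grand mean is
    restored so the output stays on the input scale.
    """
    if covariate not in metadata.columns:
        raise ValueError(f"covariate {covariate!r} missing from metadata")
    labels = metadata.loc[norm.columns, covariate]
    if labels.isna().any():
        raise ValueError(f"covariate {covariate!r} undefined for some samples")
    if labels.nunique() < 2:
        warnings.warn(f"covariate {covariate!r} has a single level; no adjustment")
        return norm.copy()
    x = norm.to_numpy(dtype=float)
    out = np.empty_like(x)
    grand = x.mean(axis=1, keepdims=True)
    resid = np.empty_like(x)
    for lev in labels.unique():
        cols = (labels == lev).to_numpy()
        sub = x[:, cols]
        resid[:, cols] = sub - sub.mean(axis=1, keepdims=True)
    out = resid + grand
    return pd.DataFrame(out, index=norm.index, columns=norm.columns)


def normalize_counts(counts: pd.DataFrame, metadata: pd.DataFrame, *,
                     strategy: str = "pooled",
                     cpm_threshold: float = 1.0, cpm_fraction: float = 0.8,
                     dispersion_quantile: float | None = None,
                     adjust_sex: bool = False) -> dict[str, NormalizedMatrix]:
    """Filter and normalize under one of the two strategies.

    Returns a mapping; the pooled strategy yields a single entry under key
    ``"pooled"``, the per-tissue strategy one entry per tissue.  The
    dispersion filter defaults to off for pooled and to the 0.2 quantile for
    per-tissue, matching how the two matrices are consumed downstream.
    """
    _check_counts(counts)
    missing = [s for s in counts.columns if s not in metadata.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")

    def _one(sub: pd.DataFrame, label: str, dq: float | None) -> NormalizedMatrix:
        filters = []
        kept = filter_low_expression(sub, cpm_threshold, cpm_fraction)
        filters.append(f"cpm<{cpm_threshold} in >={cpm_fraction:.0%} removed "
                       f"({sub.shape[0]} -> {kept.shape[0]} genes)")
        sf = estimate_size_factors(kept)
        norm = vst_transform(kept, sf)
        if dq:
            before = norm.shape[0]
            norm = filter_low_dispersion(norm, dq)
            filters.append(f"dispersion quantile<{dq} removed "
                           f"({before} -> {norm.shape[0]} genes)")
        if adjust_sex:
            norm = adjust_covariate(norm, metadata, "sex")
            filters.append("sex covariate residualized")
        return NormalizedMatrix(data=norm, strategy=label, size_factors=sf,
                                filters=filters)

    if strategy == "pooled":
        return {"pooled": _one(counts, "pooled", dispersion_quantile)}
    if strategy == "per-tissue":
        dq = 0.2 if dispersion_quantile is None else dispersion_quantile
        out = {}
        for tissue in metadata.loc[counts.columns, "tissue"].unique():
            cols = metadata.index[(metadata["tissue"] == tissue)
                                  & metadata.index.isin(counts.columns)]
            out[tissue] = _one(counts[cols], f"per-tissue:{tissue}", dq)
        return out
    raise ValueError(f"unknown strategy {strategy!r}")
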