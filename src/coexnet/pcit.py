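"""PCIT: partial-correlation-and-information-theory edge filtering.

Given a gene-gene Pearson correlation matrix, PCIT examines every trio of
genes (x, y, z).  For each trio it computes the three first-order partial
correlations, e.g.

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) * (1 - r_yz^2)),

and a trio-local tolerance -- the average ratio of partial to raw
correlation:

    eps_xyz = (r_xy.z / r_xy + r_xz.y / r_xz + r_yz.x / r_yz) / 3.

The association x--y is declared non-significant if some third gene z
explains it away, i.e. |r_xy| <= |eps * r_xz| and |r_xy| <= |eps * r_yz|.
Pairs never eliminated by any z form the significant mask.

Two implementations are provided: a plain triple loop (`pcit_edges_naive`),
kept as an independent oracle, and a per-conditioning-gene vectorized sweep
(`pcit_edges`) that performs the same floating-point operations and therefore
returns an identical mask.

Numerical guards (applied identically in both paths):

* a ratio whose raw correlation is below 1e-12 in magnitude counts as 1
  (maximal redundancy) instead of dividing by ~0;
* if a flanking correlation |r_xz| or |r_yz| is 1 (within 1e-12), the
  partial is undefined and z is treated as fully explaining x--y: the edge is
  eliminated;
* a pair with |r_xy| = 1 (a duplicated gene) is never eliminated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["pearson_matrix", "first_order_partial", "pcit_edges", "pcit_edges_naive"]

_ZERO = 1e-12
_ONE = 1.0 - 1e-12


def pearson_matrix(norm: pd.DataFrame) -> pd.DataFrame:
    """Gene x gene Pearson correlations over samples (columns).

    Zero-variance genes are excluded (with a warning via pandas-free check)
    since their correlation is undefined.
    """
    if norm.shape[1] < 4:
        raise ValueError(f"need >= 4 samples, got {norm.shape[1]}")
    x = norm.to_numpy(dtype=float)
    sd = x.std(axis=1)
    keep = sd > 0
    if not keep.all():
        import warnings

        dropped = norm.index[~keep].tolist()
        warnings.warn(f"excluding {len(dropped)} zero-variance gene(s)")
    x = x[keep]
    r = np.corrcoef(x)
    np.fill_diagonal(r, 1.0)
    idx = norm.index[keep]
    return pd.DataFrame(np.clip(r, -1.0, 1.0), index=idx, columns=idx)


def first_order_partial(r_xy: float, r_xz: float, r_yz: float) -> float:
    """Partial correlation of x and y given z; NaN when a flank is +-1."""
    dx = 1.0 - r_xz * r_xz
    dy = 1.0 - r_yz * r_yz
    if dx <= 0.0 or dy <= 0.0:
        return float("nan")
    return (r_xy - r_xz * r_yz) / (np.sqrt(dx) * np.sqrt(dy))


def _check_corr(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(r, r.T, atol=1e-8, equal_nan=True):
        raise ValueError("correlation matrix must be symmetric")
    if np.nanmax(np.abs(r)) > 1 + 1e-9:
        raise ValueError("correlations must lie in [-1, 1]")
    # mirror the upper triangle so both implementations see identical floats
    out = np.triu(r) + np.triu(r, k=1).T
    return out


def pcit_edges_naive(corr: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Reference O(n^3) triple-loop implementation; returns a boolean mask."""
    if isinstance(corr, pd.DataFrame):
        corr = corr.to_numpy()
    r = _check_corr(corr)
    n = r.shape[0]
    sig = np.ones((n, n), dtype=bool)
    np.fill_diagonal(sig, False)
    for x in range(n):
        for y in range(x + 1, n):
            rxy = r[x, y]
            if abs(rxy) >= _ONE:
                continue  # duplicate genes stay connected
            for z in range(n):
                if z == x or z == y:
                    continue
                rxz, ryz = r[x, z], r[y, z]
                if abs(rxz) >= _ONE or abs(ryz) >= _ONE:
                    sig[x, y] = sig[y, x] = False
                    break
                pxy = (rxy - rxz * ryz) / (np.sqrt(1.0 - rxz * rxz)
                                           * np.sqrt(1.0 - ryz * ryz))
                pxz = (rxz - rxy * ryz) / (np.sqrt(1.0 - rxy * rxy)
                                           * np.sqrt(1.0 - ryz * ryz))
                pyz = (ryz - rxy * rxz) / (np.sqrt(1.0 - rxy * rxy)
                                           * np.sqrt(1.0 - rxz * rxz))
                t1 = pxy / rxy if abs(rxy) >= _ZERO else 1.0
                t2 = pxz / rxz if abs(rxz) >= _ZERO else 1.0
                t3 = pyz / ryz if abs(ryz) >= _ZERO else 1.0
                eps = (t1 + t2 + t3) / 3.0
                if abs(rxy) <= abs(eps * rxz) and abs(rxy) <= abs(eps * ryz):
                    sig[x, y] = sig[y, x] = False
                    break
    return sig


def pcit_edges(corr: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Vectorized PCIT mask: one broadcasted sweep per conditioning gene z.

    Memory is O(n^2); for each z six n x n temporaries are formed.  Practical
    up to a few thousand genes on one core.
    """
    if isinstance(corr, pd.DataFrame):
        corr = corr.to_numpy()
    r = _check_corr(corr)
    n = r.shape[0]
    if n < 3:
        sig = np.ones((n, n), dtype=bool)
        np.fill_diagonal(sig, False)
        return sig
    abs_r = np.abs(r)
    dup = abs_r >= _ONE          # pairs that can never be eliminated
    near0 = abs_r < _ZERO
    with np.errstate(invalid="ignore", divide="ignore"):
        sqc = np.sqrt(1.0 - r * r)          # sqrt(1 - r^2), 0 where |r| = 1
    eliminated = np.zeros((n, n), dtype=bool)
    for z in range(n):
        rz = r[:, z]                        # r[., z]
        dz = sqc[:, z]                      # sqrt(1 - r[., z]^2)
        flank_one = np.abs(rz) >= _ONE      # z duplicates an endpoint
        with np.errstate(invalid="ignore", divide="ignore"):
            pxy = (r - np.outer(rz, rz)) / (dz[:, None] * dz[None, :])
            pxz = (rz[:, None] - r * rz[None, :]) / (sqc * dz[None, :])
            pyz = (rz[None, :] - r * rz[:, None]) / (sqc * dz[:, None])
            t1 = np.where(near0, 1.0, pxy / r)
            t2 = np.where(np.abs(rz)[:, None] < _ZERO, 1.0, pxz / rz[:, None])
            t3 = np.where(np.abs(rz)[None, :] < _ZERO, 1.0, pyz / rz[None, :])
            eps = (t1 + t2 + t3) / 3.0
            cond = ((abs_r <= np.abs(eps * rz[:, None]))
                    & (abs_r <= np.abs(eps * rz[None, :])))
        # a flank of |r| = 1 eliminates the pair outright
        cond = cond | flank_one[:, None] | flank_one[None, :]
        # z must differ from both endpoints; duplicates are immune
        cond[z, :] = False
        cond[:, z] = False
        cond &= ~dup
        eliminated |= cond
    sig = ~eliminated
    np.fill_diagonal(sig, False)
    return sig
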