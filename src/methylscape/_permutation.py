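"""Vectorized permutation tests for correlation coefficients.

Permutation p values follow the add-one rule p = (1 + #extreme) /
(n_perm + 1), so they are floored at 1/(n_perm + 1).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def _standardize(v: np.ndarray) -> np.ndarray:
    s = v.std()
    if s == 0:
        raise ValueError("constant vector")
    return (v - v.mean()) / s


def perm_corr_many(
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    method: str = "pearson",
) -> tuple[np.ndarray, np.ndarray]:
    """Correlate each row of X with y; two-sided permutation p per row.

    One shared set of ``n_perm`` sample permutations of ``y`` is used for
    all rows.  Rows with zero variance get NaN.  Returns (r, p).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    m, n = X.shape
    if method == "spearman":
        X = np.apply_along_axis(rankdata, 1, X)
        y = rankdata(y)
    ys = _standardize(y)
    sd = X.std(axis=1)
    ok = sd > 0
    Xs = np.zeros_like(X)
    Xs[ok] = (X[ok] - X[ok].mean(axis=1, keepdims=True)) / sd[ok][:, None]
    r = Xs @ ys / n
    P = np.tile(ys, (n_perm, 1))
    P = rng.permuted(P, axis=1)
    rp = P @ Xs.T / n  # (n_perm, m)
    extreme = (np.abs(rp) >= np.abs(r)[None, :] - 1e-12).sum(axis=0)
    p = (1.0 + extreme) / (n_perm + 1)
    r = np.where(ok, r, np.nan)
    p = np.where(ok, p, np.nan)
    return r, p


def perm_corr(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    method: str = "pearson",
) -> tuple[float, float]:
    """Single-pair convenience wrapper around :func:`perm_corr_many`."""
    r, p = perm_corr_many(np.asarray(x)[None, :], y, n_perm, rng, method)
    return float(r[0]), float(p[0])
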