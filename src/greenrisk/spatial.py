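"""Spatial weights and the global Moran's I statistic with permutation inference.

Global Moran's I measures whether a region-level variable is more alike
(positive I) or less alike (negative I) among contiguity neighbors than
expected by chance:

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

with S0 = sum_ij w_ij.  Under exchangeability E[I] = -1/(n-1).  Inference is
by random permutation of the values over the regions, with the GeoDa-style
plus-one pseudo p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .geography import Geography

logger = logging.getLogger(__name__)

__all__ = ["SpatialWeights", "build_weights", "morans_i", "morans_i_permutation"]


class ZeroVarianceError(ValueError):
    """Moran's I is undefined for a constant variable."""


@dataclass(frozen=True)
class SpatialWeights:
    """Sparse region-by-region spatial weights.

    ``style`` is ``"binary"`` (w_ij = 1 for neighbors, symmetric) or
    ``"row"`` (each non-island row standardized to sum to 1).
    """

    matrix: sp.csr_matrix
    style: str

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def s0(self) -> float:
        return float(self.matrix.sum())


def build_weights(geog: Geography, style: str = "row") -> SpatialWeights:
    """Contiguity weights from a geography.

    Island regions produce all-zero rows (and a logged warning via the
    geography itself); row standardization leaves them zero.
    """
    if style not in ("binary", "row"):
        raise ValueError(f"unknown weights style {style!r}")
    n = geog.n_regions
    e = geog.edges
    if len(e):
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        data = np.ones(len(rows))
    else:
        rows = cols = data = np.empty(0)
    w = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    if geog.islands:
        logger.warning("weights built with %d all-zero island row(s)", len(geog.islands))
    if style == "row":
        rowsum = np.asarray(w.sum(axis=1)).ravel()
        inv = np.divide(1.0, rowsum, out=np.zeros_like(rowsum), where=rowsum > 0)
        w = sp.diags(inv) @ w
    return SpatialWeights(sp.csr_matrix(w), style)


def _validate_x(x, W: SpatialWeights) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size != W.n:
        raise ValueError(f"x has {x.size} values for {W.n} regions")
    if x.size < 3:
        raise ValueError("Moran's I needs at least 3 regions")
    if not np.all(np.isfinite(x)):
        raise ValueError("x contains non-finite values")
    if np.ptp(x) == 0:
        raise ZeroVarianceError("Moran's I is undefined for constant x")
    return x


def _moran_stat(Z: np.ndarray, W: SpatialWeights) -> np.ndarray:
    """Moran's I for each row of centered matrix Z (vectorized over rows)."""
    n = W.n
    num = np.einsum("ij,ij->i", Z, (W.matrix @ Z.T).T)
    den = np.einsum("ij,ij->i", Z, Z)
    return (n / W.s0) * num / den


def morans_i(x, W: SpatialWeights) -> float:
    """Global Moran's I of ``x`` under weights ``W``."""
    x = _validate_x(x, W)
    z = x - x.mean()
    return float(_moran_stat(z[None, :], W)[0])


def morans_i_permutation(
    x,
    W: SpatialWeights,
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
):
    """Moran's I with a random-permutation pseudo p-value.

    The p-value uses the plus-one estimator
    ``p = (1 + #extreme) / (1 + n_perm)`` so it is bounded below by
    ``1/(n_perm+1)`` (999 permutations floor at 0.001, the convention
    behind GeoDa-style reports).  ``alternative`` is ``"greater"``
    (positive autocorrelation, the default), ``"less"``, or
    ``"two-sided"`` (extremity of ``|I|``).

    Returns
    -------
    (I, p) : tuple of floats
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = _validate_x(x, W)
    z = x - x.mean()
    i_obs = float(_moran_stat(z[None, :], W)[0])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(z) for _ in range(n_perm)])
    i_star = _moran_stat(perms, W)
    if alternative == "greater":
        extreme = np.count_nonzero(i_star >= i_obs)
    elif alternative == "less":
        extreme = np.count_nonzero(i_star <= i_obs)
    else:
        extreme = np.count_nonzero(np.abs(i_star) >= abs(i_obs))
    p = (1 + extreme) / (1 + n_perm)
    return i_obs, float(p)
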