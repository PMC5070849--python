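"""SVD projection of gene expression matrices onto metagene time series.

A *metagene* compresses many co-varying genes into one time profile.  For
an N x T expression matrix the top-M left singular vectors form the
projection ``W`` (columns orthonormal), and the metagene series is
``scores = W* X`` with ``W* = W^T`` (the pseudo-inverse of an orthonormal
column block, satisfying ``W* W = I``).  The SVD is taken of the raw
(uncentered) matrix so that the explained fraction measures total squared
covariation, not variance about the mean.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError


@dataclass
class MetageneBasis:
    """Result of an SVD metagene fit.

    Attributes
    ----------
    W : (N, M) array with orthonormal columns; gene loadings.
    scores : (M, T) array; metagene time series ``W^T X``.
    singular_values : (M,) non-increasing.
    explained_fraction : share of total squared singular-value mass
        captured by the M retained components.
    group_tag : ``"internal"`` or ``"external"``.
    """

    W: np.ndarray
    scores: np.ndarray
    singular_values: np.ndarray
    explained_fraction: float
    M: int
    group_tag: str = "internal"

    def pseudo_inverse(self) -> np.ndarray:
        """W* such that W* W = I; equals W^T for orthonormal columns."""
        return self.W.T


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-|entry| element is positive.

    Removes the SVD sign ambiguity, making repeated fits bitwise
    reproducible across runs and platforms.
    """
    W = W.copy()
    for j in range(W.shape[1]):
        k = int(np.argmax(np.abs(W[:, j])))
        if W[k, j] < 0:
            W[:, j] = -W[:, j]
    return W


def fit_metagenes(
    matrix: np.ndarray, M: int, group_tag: str = "internal"
) -> MetageneBasis:
    """Project an N x T matrix onto its top-M metagenes.

    Requires ``1 <= M < T`` and ``M <= min(N, T)``: the downstream
    regression needs strictly fewer metagenes than time samples.
    """
    matrix = np.asarray(matrix, dtype=float)
    n, t = matrix.shape
    if not 1 <= M < t:
        raise DimensionError(f"need 1 <= M < T; got M={M}, T={t}")
    if M > min(n, t):
        raise DimensionError(f"M={M} exceeds min(N, T)={min(n, t)}")
    u, s, _ = np.linalg.svd(matrix, full_matrices=False)
    W = _fix_signs(u[:, :M])
    total = float(np.sum(s**2))
    explained = float(np.sum(s[:M] ** 2) / total) if total > 0 else 1.0
    return MetageneBasis(
        W=W,
        scores=W.T @ matrix,
        singular_values=s[:M].copy(),
        explained_fraction=explained,
        M=M,
        group_tag=group_tag,
    )


def choose_dimension(
    matrix: np.ndarray,
    variance_target: float,
    partner_M: int | None = None,
) -> tuple[int, float]:
    """Smallest M whose explained fraction reaches ``variance_target``.

    When ``partner_M`` is given the result is clamped so that
    ``M + partner_M <= T - 2``, leaving the one spare sample the
    (T-1)-column regression requires.  M never drops below 1.
    Returns ``(M, achieved_fraction)``.
    """
    if not 0 < variance_target <= 1:
        raise DimensionError(
            f"variance_target must be in (0, 1], got {variance_target}"
        )
    matrix = np.asarray(matrix, dtype=float)
    n, t = matrix.shape
    s = np.linalg.svd(matrix, compute_uv=False)
    frac = np.cumsum(s**2)
    total = frac[-1]
    frac = frac / total if total > 0 else np.ones_like(frac)
    m_cap = t - 1  # fit_metagenes requires M < T
    if partner_M is not None:
        m_cap = min(m_cap, t - 2 - partner_M)
    m_cap = min(m_cap, min(n, t))
    m_cap = max(m_cap, 1)
    for m in range(1, m_cap + 1):
        if frac[m - 1] >= variance_target - 1e-12:
            return m, float(frac[m - 1])
    return m_cap, float(frac[m_cap - 1])


def project_back(basis: MetageneBasis, metagene_series: np.ndarray) -> np.ndarray:
    """Lift an M x K metagene-level series back to gene space: ``W @ series``."""
    series = np.asarray(metagene_series)
    if series.shape[0] != basis.M:
        raise DimensionError(
            f"series has {series.shape[0]} rows, basis has M={basis.M}"
        )
    return basis.W @ series
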