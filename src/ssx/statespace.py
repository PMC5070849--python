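"""Effective linear state-space model at the metagene level.

The internal metagene state evolves as ``x_{t+1} = A x_t + B u_t`` where
``u_t`` is the external metagene series.  Stacking the one-step equations
over ``t = 1..T-1`` gives ``Z = [A B] Y`` with ``Z`` the columns
``x_2..x_T`` and ``Y`` the stacked past states and inputs; the effective
matrices are recovered with the Moore-Penrose right pseudo-inverse,
``[A B] = Z Y^+``.  Expanding the recursion splits every trajectory into
an internal part ``A^{t-1} x_1``, a purely external part ``B u_{t-1}``
and the lagged interaction terms ``sum_k A^k B u_{t-1-k}``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import EstimabilityError, ValidationError
from .io_data import ExpressionDataset
from .metagene import fit_metagenes

logger = logging.getLogger(__name__)

#: relative singular-value cutoff for the pseudo-inverse
PINV_RTOL = 1e-10


@dataclass
class EffectiveModel:
    """Estimated metagene-level system (A) and control (B) matrices."""

    A_tilde: np.ndarray  # M1 x M1
    B_tilde: np.ndarray  # M1 x M2
    residual_norm: float
    rank_upsilon: int

    @property
    def M1(self) -> int:
        return self.A_tilde.shape[0]

    @property
    def M2(self) -> int:
        return self.B_tilde.shape[1]


@dataclass
class DecompositionResult:
    """Internal / external / interaction split of a metagene trajectory.

    ``internal[:, t-1] = A^{t-1} x_1`` for t = 1..T;
    ``external[:, t-1] = B u_{t-1}`` for t >= 2 (first column zero);
    ``interaction[:, t-1] = sum_{k=1}^{t-2} A^k B u_{t-1-k}`` for t >= 3.
    The three always sum to the model-propagated trajectory — an algebraic
    identity, checked numerically in ``total_check``.
    """

    internal: np.ndarray
    external: np.ndarray
    interaction: np.ndarray
    total_check: float
    propagated: np.ndarray = field(repr=False, default=None)


def estimate_model(X_scores: np.ndarray, U_scores: np.ndarray) -> EffectiveModel:
    """Least-squares fit of the effective model from metagene series.

    Estimability requires ``M1 + M2 <= T - 1`` (the regression matrix has
    T-1 columns and needs a right inverse).  Singular values of the
    regression matrix below ``1e-10 * sigma_max`` are treated as zero; a
    rank-deficient fit is logged since the exact right-inverse condition
    then fails and the returned matrices are the minimum-norm solution.
    """
    X = np.asarray(X_scores, dtype=float)
    U = np.asarray(U_scores, dtype=float)
    m1, t = X.shape
    m2, tu = U.shape
    if t != tu:
        raise ValidationError(f"state has T={t} but input has T={tu}")
    if m1 + m2 > t - 1:
        raise EstimabilityError(
            f"M1+M2={m1 + m2} exceeds T-1={t - 1}; reduce the metagene "
            "dimensions or supply more time samples"
        )
    Z = X[:, 1:]
    Y = np.vstack([X[:, :-1], U[:, :-1]])
    # MP pseudo-inverse via SVD; coincides with the exact right inverse
    # Y^T (Y Y^T)^{-1} whenever Y has full row rank
    u, s, vt = np.linalg.svd(Y, full_matrices=False)
    cutoff = PINV_RTOL * s[0] if s.size and s[0] > 0 else 0.0
    rank = int(np.sum(s > cutoff))
    s_inv = np.where(s > cutoff, 1.0 / np.where(s > cutoff, s, 1.0), 0.0)
    Y_pinv = vt.T @ (s_inv[:, None] * u.T)
    AB = Z @ Y_pinv
    residual = float(np.linalg.norm(Z - AB @ Y))
    if rank < m1 + m2:
        logger.warning(
            "regression matrix is rank deficient (rank %d < %d); "
            "returning the minimum-norm least-squares solution",
            rank, m1 + m2,
        )
    return EffectiveModel(
        A_tilde=AB[:, :m1],
        B_tilde=AB[:, m1:],
        residual_norm=residual,
        rank_upsilon=rank,
    )


def _matrix_powers(A: np.ndarray, kmax: int) -> list[np.ndarray]:
    """[I, A, A^2, ..., A^kmax] by repeated multiplication."""
    powers = [np.eye(A.shape[0])]
    for _ in range(kmax):
        powers.append(powers[-1] @ A)
    return powers


def decompose(
    model: EffectiveModel,
    X1: np.ndarray,
    U_scores: np.ndarray,
    external_lags: int = 1,
) -> DecompositionResult:
    """Split the propagated trajectory into its three driving components.

    ``external_lags`` moves the first L lagged terms
    ``A^k B u`` (k < L) into the external component — the split between
    "purely external" and "interaction" is a bookkeeping choice; the
    default L=1 assigns only the undelayed term ``B u_{t-1}`` to the
    external component.
    """
    A, B = model.A_tilde, model.B_tilde
    X1 = np.asarray(X1, dtype=float).reshape(-1)
    U = np.asarray(U_scores, dtype=float)
    m1 = A.shape[0]
    if X1.shape[0] != m1:
        raise ValidationError(f"X1 has length {X1.shape[0]}, expected {m1}")
    if U.shape[0] != B.shape[1]:
        raise ValidationError(
            f"input has {U.shape[0]} rows, control matrix expects {B.shape[1]}"
        )
    if external_lags < 1:
        raise ValidationError("external_lags must be >= 1")
    t_total = U.shape[1]
    powers = _matrix_powers(A, t_total)
    BU = B @ U  # column t-1 is B u_t

    internal = np.empty((m1, t_total))
    external = np.zeros((m1, t_total))
    interaction = np.zeros((m1, t_total))
    for t in range(1, t_total + 1):
        internal[:, t - 1] = powers[t - 1] @ X1
        # lagged input terms A^k B u_{t-1-k}, k = 0..t-2
        for k in range(0, t - 1):
            term = powers[k] @ BU[:, t - 2 - k]
            if k < external_lags:
                external[:, t - 1] += term
            else:
                interaction[:, t - 1] += term

    propagated = np.empty((m1, t_total))
    propagated[:, 0] = X1
    for t in range(1, t_total):
        propagated[:, t] = A @ propagated[:, t - 1] + BU[:, t - 1]
    total_check = float(
        np.max(np.abs(internal + external + interaction - propagated))
    )
    return DecompositionResult(
        internal=internal,
        external=external,
        interaction=interaction,
        total_check=total_check,
        propagated=propagated,
    )


def simulate(
    A: np.ndarray,
    B: np.ndarray,
    U_series: np.ndarray,
    X1: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Propagate ``x_{t+1} = A x_t + B u_t + eps_t`` from ``x_1``.

    ``eps_t`` is i.i.d. Gaussian with standard deviation ``noise_sd``;
    zero noise gives the deterministic recursion.  Output has one column
    per time point, T columns for a T-column input series.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    U = np.asarray(U_series, dtype=float)
    X1 = np.asarray(X1, dtype=float).reshape(-1)
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    t_total = U.shape[1]
    out = np.empty((A.shape[0], t_total))
    out[:, 0] = X1
    for t in range(1, t_total):
        out[:, t] = A @ out[:, t - 1] + B @ U[:, t - 1]
        if noise_sd > 0:
            out[:, t] += rng.normal(0.0, noise_sd, size=A.shape[0])
    if np.any(np.abs(out) > 1e12):
        logger.warning("simulated trajectory exceeded 1e12; likely unstable")
    return out


def _real_block_matrix(eigen_spec: Sequence[complex]) -> np.ndarray:
    """Real block-diagonal matrix with the requested spectrum.

    Real eigenvalues become 1x1 blocks; each complex-conjugate pair
    a +- bi becomes the rotation-scaling block [[a, b], [-b, a]].
    Complex entries must come in conjugate pairs.
    """
    spec = [complex(z) for z in eigen_spec]
    blocks: list[np.ndarray] = []
    remaining = list(spec)
    while remaining:
        z = remaining.pop(0)
        if abs(z.imag) < 1e-12:
            blocks.append(np.array([[z.real]]))
        else:
            try:
                j = next(
                    i for i, w in enumerate(remaining)
                    if abs(w - z.conjugate()) < 1e-9
                )
            except StopIteration:
                raise ValidationError(
                    f"complex eigenvalue {z} lacks its conjugate in the spec"
                ) from None
            remaining.pop(j)
            a, b = z.real, abs(z.imag)
            blocks.append(np.array([[a, b], [-b, a]]))
    m = sum(b.shape[0] for b in blocks)
    out = np.zeros((m, m))
    i = 0
    for b in blocks:
        k = b.shape[0]
        out[i:i + k, i:i + k] = b
        i += k
    return out


def _random_orthonormal(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, m)))
    return q * np.sign(np.diag(r))


def _smooth_series(rng: np.random.Generator, m: int, t: int) -> np.ndarray:
    """Smooth input curves: low-order Fourier mixtures over the grid."""
    grid = np.linspace(0.0, 1.0, t)
    out = np.empty((m, t))
    for i in range(m):
        coeffs = rng.standard_normal(4)
        out[i] = (
            coeffs[0]
            + coeffs[1] * np.sin(2 * np.pi * grid)
            + coeffs[2] * np.cos(2 * np.pi * grid)
            + coeffs[3] * np.sin(4 * np.pi * grid)
        )
    return out


def make_synthetic_dataset(
    N1: int,
    N2: int,
    M1: int,
    M2: int,
    T: int,
    eigen_spec: Sequence[complex],
    noise_sd: float = 0.0,
    seed: int | None = None,
    name: str = "synthetic",
) -> tuple[ExpressionDataset, dict]:
    """Generate a gene-level dataset with known metagene dynamics.

    A metagene system matrix with the requested spectrum is built from a
    real block form conjugated by a random well-conditioned similarity;
    a random control matrix and smooth external curves drive the state;
    both levels are lifted to gene space through random orthonormal
    loadings.  Returns the dataset plus every generating object (exact
    matrices, scores, spectrum) for parameter-recovery comparisons.
    """
    if len(eigen_spec) != M1:
        raise ValidationError(
            f"eigen_spec has {len(eigen_spec)} entries, expected M1={M1}"
        )
    if M1 + M2 > T - 2:
        raise ValidationError(
            f"M1+M2={M1 + M2} must be <= T-2={T - 2} for an estimable fixture"
        )
    rng = np.random.default_rng(seed)
    block = _real_block_matrix(eigen_spec)
    # similarity transform: keep conditioning mild so recovery is clean
    P = np.eye(M1) + 0.3 * rng.standard_normal((M1, M1))
    while np.linalg.cond(P) > 50:
        P = np.eye(M1) + 0.3 * rng.standard_normal((M1, M1))
    A_tilde = P @ block @ np.linalg.inv(P)
    B_tilde = rng.standard_normal((M1, M2))
    U_scores = _smooth_series(rng, M2, T)
    X1 = rng.standard_normal(M1)
    X_scores = simulate(
        A_tilde, B_tilde, U_scores, X1, noise_sd=noise_sd,
        seed=int(rng.integers(2**31)),
    )
    W_X = _random_orthonormal(rng, N1, M1)
    W_U = _random_orthonormal(rng, N2, M2)
    internal = W_X @ X_scores
    external = W_U @ U_scores
    ids_int = [f"g{i:04d}" for i in range(N1)]
    ids_ext = [f"tf{i:04d}" for i in range(N2)]
    ds = ExpressionDataset(
        name=name,
        internal_ids=ids_int,
        external_ids=ids_ext,
        internal_matrix=internal,
        external_matrix=external,
    ).validate()
    truth = {
        "A_tilde": A_tilde,
        "B_tilde": B_tilde,
        "W_X": W_X,
        "W_U": W_U,
        "X_scores": X_scores,
        "U_scores": U_scores,
        "X1": X1,
        "eigenvalues": np.array([complex(z) for z in eigen_spec]),
    }
    return ds, truth


def fit_dataset(
    dataset: ExpressionDataset, M1: int, M2: int
) -> tuple["MetageneBasis", "MetageneBasis", EffectiveModel]:
    """Convenience: metagene fits for both groups plus the model estimate."""
    basis_x = fit_metagenes(dataset.internal_matrix, M1, group_tag="internal")
    basis_u = fit_metagenes(dataset.external_matrix, M2, group_tag="external")
    model = estimate_model(basis_x.scores, basis_u.scores)
    return basis_x, basis_u, model
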