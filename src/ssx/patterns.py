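"""Principal dynamic patterns: canonical trajectories of the fitted model.

Each eigenvalue ``lambda`` of the effective system matrix contributes an
*internal* principal dynamic pattern (iPDP): the trajectory
``[lambda^1 .. lambda^T]`` weighted by a coefficient vector from the
analytic solution of the linear recursion, so that the weighted patterns
sum exactly to the internally driven component ``A^{t-1} x_1``.
Complex-conjugate eigenvalue pairs are merged into one real oscillatory
pattern ``[lambda^t + conj(lambda)^t]``.  Each external metagene's time
profile is an *external* pattern (ePDP), weighted into the internal
system by the corresponding column of the control matrix.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DimensionError, NotDiagonalizableError, ValidationError
from .metagene import MetageneBasis, fit_metagenes
from .statespace import DecompositionResult, EffectiveModel, estimate_model

logger = logging.getLogger(__name__)

UNIT_TOL = 1e-6       # half-width of the "on the unit circle" band
REAL_TOL = 1e-9       # |Im| below this counts as a real eigenvalue
COND_LIMIT = 1e8      # eigenvector condition number guard
ZERO_EIG_TOL = 1e-12  # |lambda| below this cannot carry a t=1 term


@dataclass
class PrincipalDynamicPattern:
    """One canonical trajectory with its metagene / gene loadings.

    ``trajectory`` holds the raw pattern (iPDP: powers of the eigenvalue,
    conjugate pairs summed; ePDP: the external metagene series over
    t = 1..T-1); ``trajectory_unit`` is the same curve scaled to unit
    vector norm for cross-dataset display.
    """

    kind: str                       # "iPDP" | "ePDP"
    index: int                      # 1-based rank after ordering
    eigenvalue: complex | None
    is_merged_conjugate: bool
    trajectory: np.ndarray
    trajectory_unit: np.ndarray
    metagene_coefficients: np.ndarray
    class_label: str | None = None
    period: float | None = None
    gene_coefficients: np.ndarray | None = field(default=None, repr=False)

    def contribution(self, T: int) -> np.ndarray:
        """M1 x T real array: this pattern's share of the internal component.

        For a merged conjugate pair the pair's joint contribution is
        ``2 Re(K lambda^t)`` — not the coefficient times the merged
        trajectory, because the coefficient itself is complex.
        """
        if self.kind != "iPDP":
            raise ValidationError("contribution() is defined for iPDPs only")
        lam = self.eigenvalue
        powers = lam ** np.arange(1, T + 1)
        outer = np.outer(self.metagene_coefficients, powers)
        if self.is_merged_conjugate:
            return 2.0 * outer.real
        return outer.real


def classify_eigenvalue(
    lam: complex, unit_tol: float = UNIT_TOL, real_tol: float = REAL_TOL
) -> str:
    """Label the canonical trajectory shape implied by an eigenvalue.

    Real eigenvalues yield monotone or sign-alternating power curves;
    complex ones yield oscillations whose envelope is set by the modulus.
    """
    lam = complex(lam)
    if abs(lam.imag) < real_tol:
        x = lam.real
        if abs(x) <= unit_tol:
            return "impulse"
        if x > 1 + unit_tol:
            return "growing"
        if abs(x - 1) <= unit_tol:
            return "constant"
        if x > 0:
            return "decaying"
        if x > -1:
            return "alternating-decaying"
        return "alternating-growing/sustained"
    mod = abs(lam)
    if abs(mod - 1) <= unit_tol:
        return "sustained-oscillation"
    if mod < 1:
        return "damped-oscillation"
    return "growing-oscillation"


def oscillation_period(lam: complex, real_tol: float = REAL_TOL) -> float | None:
    """Period 2*pi/|arg lambda| in time steps; None for real eigenvalues."""
    lam = complex(lam)
    if abs(lam.imag) < real_tol:
        return None
    return float(2 * np.pi / abs(np.angle(lam)))


def _eig_order_key(lam: complex) -> tuple[float, float]:
    """Modulus descending, then real part descending."""
    return (-abs(lam), -lam.real)


def ordered_eigenvalues(A: np.ndarray) -> np.ndarray:
    """Eigenvalues of A sorted by descending modulus, then real part."""
    vals = np.linalg.eigvals(np.asarray(A, dtype=float))
    return np.array(sorted(vals, key=_eig_order_key))


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v.copy()


def extract_ipdps(
    A_tilde: np.ndarray, X1: np.ndarray, T: int
) -> list[PrincipalDynamicPattern]:
    """Eigendecompose the system matrix into internal dynamic patterns.

    The analytic solution of ``x_{t+1} = A x_t`` from ``x_1`` gives
    ``x_t = sum_p K_p lambda_p^t`` with ``K_p = (H^{-1} x_1)_p / lambda_p
    * H_p`` (H = eigenvectors), so the patterns reconstruct
    ``A^{t-1} x_1`` exactly for t = 1..T.  Conjugate pairs appear once,
    merged into a real trajectory, with the positive-imaginary member
    kept as the representative eigenvalue.
    """
    A = np.asarray(A_tilde, dtype=float)
    X1 = np.asarray(X1, dtype=float).reshape(-1)
    if X1.shape[0] != A.shape[0]:
        raise DimensionError(
            f"X1 has length {X1.shape[0]}, system matrix is {A.shape[0]}x"
            f"{A.shape[0]}"
        )
    vals, H = np.linalg.eig(A)
    cond = np.linalg.cond(H)
    if cond > COND_LIMIT:
        raise NotDiagonalizableError(
            f"eigenvector matrix condition number {cond:.2e} exceeds "
            f"{COND_LIMIT:.0e}; the system matrix is numerically defective "
            "— consider perturbing the metagene dimension"
        )
    S = np.linalg.solve(H, X1.astype(complex))
    order = sorted(range(len(vals)), key=lambda i: _eig_order_key(vals[i]))

    patterns: list[PrincipalDynamicPattern] = []
    used: set[int] = set()
    t_powers = np.arange(1, T + 1)
    for i in order:
        if i in used:
            continue
        used.add(i)
        lam = vals[i]
        if abs(lam) > ZERO_EIG_TOL:
            coeff = (S[i] / lam) * H[:, i]
        else:
            # zero eigenvalue: lambda^t vanishes for t >= 1, the t=1 term
            # is unrepresentable on this trajectory; keep the raw weight
            coeff = S[i] * H[:, i]
            logger.warning(
                "eigenvalue ~0 encountered; its t=1 contribution cannot "
                "be carried by the power trajectory"
            )
        if abs(lam.imag) < REAL_TOL:
            traj = (lam.real ** t_powers).astype(float)
            patterns.append(
                PrincipalDynamicPattern(
                    kind="iPDP",
                    index=0,
                    eigenvalue=complex(lam.real),
                    is_merged_conjugate=False,
                    trajectory=traj,
                    trajectory_unit=_unit(traj),
                    metagene_coefficients=coeff,
                    class_label=classify_eigenvalue(lam.real),
                    period=None,
                )
            )
        else:
            # locate the conjugate partner among the remaining eigenvalues
            j = min(
                (k for k in range(len(vals)) if k not in used),
                key=lambda k: abs(vals[k] - lam.conjugate()),
                default=None,
            )
            if j is None or abs(vals[j] - lam.conjugate()) > 1e-6 * max(
                1.0, abs(lam)
            ):
                raise ValidationError(
                    f"complex eigenvalue {lam} has no conjugate partner"
                )
            used.add(j)
            rep = lam if lam.imag > 0 else vals[j]
            rep_coeff = coeff if lam.imag > 0 else (S[j] / vals[j]) * H[:, j]
            merged = (rep ** t_powers) + (np.conj(rep) ** t_powers)
            assert np.max(np.abs(merged.imag)) < 1e-10
            traj = merged.real.astype(float)
            patterns.append(
                PrincipalDynamicPattern(
                    kind="iPDP",
                    index=0,
                    eigenvalue=rep,
                    is_merged_conjugate=True,
                    trajectory=traj,
                    trajectory_unit=_unit(traj),
                    metagene_coefficients=rep_coeff,
                    class_label=classify_eigenvalue(rep),
                    period=oscillation_period(rep),
                )
            )
    for rank, p in enumerate(patterns, start=1):
        p.index = rank
    return patterns


def extract_epdps(
    B_tilde: np.ndarray, U_scores: np.ndarray
) -> list[PrincipalDynamicPattern]:
    """One external pattern per external metagene.

    The q-th pattern's trajectory is the q-th external metagene series
    over t = 1..T-1 (the input acts with a one-step delay), and its
    loading onto internal metagene i is ``B[i, q]``, so the weighted
    patterns reconstruct the external component exactly.
    """
    B = np.asarray(B_tilde, dtype=float)
    U = np.asarray(U_scores, dtype=float)
    if B.shape[1] != U.shape[0]:
        raise DimensionError(
            f"control matrix has {B.shape[1]} columns, input has "
            f"{U.shape[0]} rows"
        )
    patterns = []
    for q in range(U.shape[0]):
        traj = U[q, :-1].astype(float).copy()
        patterns.append(
            PrincipalDynamicPattern(
                kind="ePDP",
                index=q + 1,
                eigenvalue=None,
                is_merged_conjugate=False,
                trajectory=traj,
                trajectory_unit=_unit(traj),
                metagene_coefficients=B[:, q].copy(),
                class_label=None,
                period=None,
            )
        )
    return patterns


def gene_coefficients_ipdp(
    basis_internal: MetageneBasis,
    ipdps: list[PrincipalDynamicPattern],
) -> pd.DataFrame:
    """Back-project iPDP coefficients from metagenes to genes: C = W K.

    Returns a complex-valued genes x patterns table (columns
    ``iPDP1..``); real patterns carry ~zero imaginary part, merged
    conjugate patterns carry the representative member's complex
    coefficient whose real contribution is ``2|C| |lambda|^t
    cos(t arg(lambda) + arg(C))``.  Also fills each pattern's
    ``gene_coefficients``.
    """
    W = basis_internal.W
    cols = {}
    for p in ipdps:
        if p.metagene_coefficients.shape[0] != basis_internal.M:
            raise DimensionError(
                "pattern coefficients do not match the metagene basis"
            )
        c = W @ p.metagene_coefficients
        p.gene_coefficients = c
        cols[f"iPDP{p.index}"] = c
    return pd.DataFrame(cols)


def gene_coefficients_epdp(
    basis_internal: MetageneBasis, B_tilde: np.ndarray
) -> pd.DataFrame:
    """Gene-level external loadings D = W B (genes x external patterns)."""
    B = np.asarray(B_tilde, dtype=float)
    if B.shape[0] != basis_internal.M:
        raise DimensionError(
            f"control matrix has {B.shape[0]} rows, basis has "
            f"M={basis_internal.M}"
        )
    D = basis_internal.W @ B
    return pd.DataFrame(
        {f"ePDP{q + 1}": D[:, q] for q in range(B.shape[1])}
    )


def coefficient_view(table: pd.DataFrame, mode: str = "absolute") -> pd.DataFrame:
    """Real-valued view of a (possibly complex) coefficient table.

    ``absolute`` takes magnitudes (the amplitude scale for oscillatory
    patterns); ``signed`` takes real parts.  Merged-conjugate columns are
    complex; their factor-of-two amplitude convention is uniform within a
    column, so rank-based statistics are unaffected by it.
    """
    if mode == "absolute":
        return table.abs()
    if mode == "signed":
        return table.apply(np.real)
    raise ValidationError(f"unknown mode {mode!r}; use 'absolute' or 'signed'")


def loo_sensitivity(
    dataset,
    M1: int,
    M2: int,
    group: str = "internal",
) -> pd.DataFrame:
    """Leave-one-out eigenvalue stability of the fitted spectrum.

    Each gene of the chosen group is removed in turn, the metagene fit
    and model estimate are rerun, and the ordered eigenvalues recorded.
    Returns per-rank min / max / mean of the modulus, real and imaginary
    parts — the variation band of each eigenvalue under single-gene
    perturbations of the network.
    """
    if group not in ("internal", "external"):
        raise ValidationError("group must be 'internal' or 'external'")
    ids = dataset.internal_ids if group == "internal" else dataset.external_ids
    if len(ids) < 3:
        raise ValidationError(
            f"leave-one-out needs >= 3 genes in the {group} group"
        )
    spectra = np.empty((len(ids), M1), dtype=complex)
    for g in range(len(ids)):
        if group == "internal":
            mat_x = np.delete(dataset.internal_matrix, g, axis=0)
            mat_u = dataset.external_matrix
        else:
            mat_x = dataset.internal_matrix
            mat_u = np.delete(dataset.external_matrix, g, axis=0)
        bx = fit_metagenes(mat_x, M1, group_tag="internal")
        bu = fit_metagenes(mat_u, M2, group_tag="external")
        model = estimate_model(bx.scores, bu.scores)
        spectra[g] = ordered_eigenvalues(model.A_tilde)
    rows = []
    for r in range(M1):
        col = spectra[:, r]
        rows.append(
            {
                "rank": r + 1,
                "modulus_min": np.abs(col).min(),
                "modulus_max": np.abs(col).max(),
                "modulus_mean": np.abs(col).mean(),
                "real_min": col.real.min(),
                "real_max": col.real.max(),
                "real_mean": col.real.mean(),
                "imag_min": col.imag.min(),
                "imag_max": col.imag.max(),
                "imag_mean": col.imag.mean(),
            }
        )
    return pd.DataFrame(rows).set_index("rank")


def interaction_patterns(
    decomp: DecompositionResult, K: int
) -> list[tuple[np.ndarray, float]]:
    """Dominant time profiles of the internal-external interaction term.

    SVD of the stacked interaction series; returns up to K right-singular
    vectors (length-T trajectories) with their squared-singular-value
    fractions.  An identically zero interaction (e.g. no external input)
    yields an empty list with a warning.
    """
    mat = decomp.interaction
    if K >= mat.shape[1]:
        raise DimensionError(f"K={K} must be < T={mat.shape[1]}")
    if not np.any(mat):
        logger.warning("interaction component is identically zero")
        return []
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    total = float(np.sum(s**2))
    out = []
    for k in range(min(K, np.sum(s > 0))):
        v = vt[k].copy()
        peak = int(np.argmax(np.abs(v)))
        if v[peak] < 0:
            v = -v
        out.append((v, float(s[k] ** 2 / total)))
    return out
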