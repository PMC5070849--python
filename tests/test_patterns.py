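"""Dynamic-pattern extraction, classification, and gene back-projection."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ssx.errors import NotDiagonalizableError, ValidationError
from ssx.metagene import MetageneBasis, fit_metagenes
from ssx.patterns import (
    classify_eigenvalue,
    extract_epdps,
    extract_ipdps,
    gene_coefficients_epdp,
    gene_coefficients_ipdp,
    interaction_patterns,
    loo_sensitivity,
    ordered_eigenvalues,
    oscillation_period,
)
from ssx.statespace import (
    EffectiveModel,
    decompose,
    estimate_model,
    make_synthetic_dataset,
    simulate,
)


def _random_diagonalizable(rng, m, include_pair=False):
    if include_pair:
        theta = rng.uniform(0.2, 2.8)
        r = rng.uniform(0.3, 1.1)
        block = np.array([[r * np.cos(theta), r * np.sin(theta)],
                          [-r * np.sin(theta), r * np.cos(theta)]])
        rest = np.diag(rng.uniform(-0.9, 0.9, size=m - 2))
        D = np.block([
            [block, np.zeros((2, m - 2))],
            [np.zeros((m - 2, 2)), rest],
        ])
    else:
        D = np.diag(rng.uniform(-0.9, 0.9, size=m))
    P = np.eye(m) + 0.3 * rng.standard_normal((m, m))
    return P @ D @ np.linalg.inv(P)


class TestExtractIpdps:
    def test_diagonal_case(self):
        """Patterns of diag(0.5, 2): ordered 2 then 0.5, coefficients set
        so the weighted trajectories reconstruct A^{t-1} x1."""
        A = np.diag([0.5, 2.0])
        pats = extract_ipdps(A, np.array([1.0, 1.0]), T=4)
        assert [p.eigenvalue for p in pats] == [2.0, 0.5]
        assert np.allclose(pats[0].trajectory, [2, 4, 8, 16])
        assert np.allclose(pats[1].trajectory, [0.5, 0.25, 0.125, 0.0625])
        # K_p = (H^{-1}x1)_p / lambda_p * H_p: scaled unit vectors
        assert np.allclose(pats[0].metagene_coefficients, [0, 0.5])
        assert np.allclose(pats[1].metagene_coefficients, [2, 0])
        recon = sum(p.contribution(4) for p in pats)
        direct = np.column_stack(
            [np.linalg.matrix_power(A, t) @ [1, 1] for t in range(4)]
        )
        assert np.max(np.abs(recon - direct)) < 1e-12

    def test_merged_conjugate_closed_form(self, rng):
        """A 0.9 e^{+-i pi/4} pair merges to 2 * 0.9^t cos(t pi/4)."""
        block = 0.9 * np.array([
            [np.cos(np.pi / 4), np.sin(np.pi / 4)],
            [-np.sin(np.pi / 4), np.cos(np.pi / 4)],
        ])
        A = np.block([
            [block, np.zeros((2, 2))],
            [np.zeros((2, 2)), np.diag([0.5, 0.3])],
        ])
        pats = extract_ipdps(A, np.ones(4), T=10)
        merged = [p for p in pats if p.is_merged_conjugate]
        assert len(merged) == 1
        t = np.arange(1, 11)
        want = 2 * 0.9**t * np.cos(t * np.pi / 4)
        assert np.max(np.abs(merged[0].trajectory - want)) < 1e-9
        assert merged[0].eigenvalue.imag > 0  # +Im member is representative
        assert merged[0].period == pytest.approx(8.0)

    def test_reconstruction_identity_random(self, rng):
        """Defining identity: pattern contributions sum to A^{t-1} x1."""
        for k in range(10):
            m = int(rng.integers(2, 6))
            A = _random_diagonalizable(rng, m, include_pair=(m >= 3 and k % 2 == 0))
            x1 = rng.standard_normal(m)
            T = 12
            pats = extract_ipdps(A, x1, T)
            recon = sum(p.contribution(T) for p in pats)
            direct = np.column_stack(
                [np.linalg.matrix_power(A, t) @ x1 for t in range(T)]
            )
            assert np.max(np.abs(recon - direct)) < 1e-8

    def test_ordering_by_modulus_then_real(self, rng):
        A = np.diag([0.3, -0.8, 0.8])
        pats = extract_ipdps(A, np.ones(3), T=5)
        assert [p.eigenvalue.real for p in pats] == [0.8, -0.8, 0.3]

    def test_defective_matrix_rejected(self):
        jordan = np.array([[1.0, 1.0], [0.0, 1.0]])
        with pytest.raises(NotDiagonalizableError):
            extract_ipdps(jordan, np.ones(2), T=5)

    def test_unit_norm_trajectories(self, rng):
        A = _random_diagonalizable(rng, 4, include_pair=True)
        for p in extract_ipdps(A, rng.standard_normal(4), T=9):
            assert np.linalg.norm(p.trajectory_unit) == pytest.approx(
                1.0, abs=1e-12
            )


class TestClassifyEigenvalue:
    @pytest.mark.parametrize("lam,label", [
        (0.5, "decaying"),
        (1.0, "constant"),
        (1.5, "growing"),
        (0.0, "impulse"),
        (-0.5, "alternating-decaying"),
        (-1.0, "alternating-growing/sustained"),
        (-1.5, "alternating-growing/sustained"),
        (1 - 9e-7, "constant"),    # inside the unit band
        (1 + 9e-7, "constant"),
        (1.00001, "growing"),
        (0.9 * np.exp(1j * np.pi / 4), "damped-oscillation"),
        (np.exp(1j * np.pi / 3), "sustained-oscillation"),
        (1.2 * np.exp(1j * np.pi / 3), "growing-oscillation"),
    ])
    def test_labels(self, lam, label):
        assert classify_eigenvalue(lam) == label

    def test_periods(self):
        assert oscillation_period(0.9 * np.exp(1j * np.pi / 4)) == pytest.approx(8)
        assert oscillation_period(np.exp(1j * np.pi / 3)) == pytest.approx(6)
        assert oscillation_period(0.7) is None

    @pytest.mark.parametrize("lam", [
        0.6, 1.0, 1.3, -0.7, -1.2,
        0.8 * np.exp(1j * np.pi / 5), np.exp(1j * np.pi / 3),
    ])
    def test_label_predicts_trajectory_behavior(self, lam):
        """The label's qualitative claim holds for the realized curve."""
        label = classify_eigenvalue(lam)
        t = np.arange(1, 25)
        traj = np.real(lam ** t + np.conj(lam) ** t) / 2 if isinstance(
            lam, complex
        ) else np.asarray([np.real(lam**k) for k in t])
        mags = np.abs(np.complex128(lam) ** t)
        if label == "decaying":
            assert np.all(np.diff(traj) < 0) and traj[0] > 0
        elif label == "growing":
            assert np.all(np.diff(traj) > 0)
        elif label == "constant":
            assert np.allclose(traj, traj[0])
        elif label == "alternating-decaying":
            assert np.all(np.sign(traj[:-1]) == -np.sign(traj[1:]))
            assert np.all(np.diff(np.abs(traj)) < 0)
        elif label == "alternating-growing/sustained":
            assert np.all(np.sign(traj[:-1]) == -np.sign(traj[1:]))
            assert np.all(np.diff(np.abs(traj)) >= 0)
        elif label == "damped-oscillation":
            assert np.all(np.diff(mags) < 0)  # shrinking envelope
            assert np.any(traj > 0) and np.any(traj < 0)
        elif label == "sustained-oscillation":
            assert np.allclose(mags, 1.0)
            assert np.any(traj > 0) and np.any(traj < 0)


class TestExtractEpdps:
    def test_zero_B_zero_coefficients(self, rng):
        pats = extract_epdps(np.zeros((3, 2)), rng.standard_normal((2, 8)))
        for p in pats:
            assert np.max(np.abs(p.metagene_coefficients)) == 0

    def test_single_input_reconstruction(self, rng):
        B = rng.standard_normal((3, 1))
        U = rng.standard_normal((1, 8))
        pats = extract_epdps(B, U)
        assert len(pats) == 1
        ext = B @ U[:, :-1]  # X_ext over t = 2..T
        recon = np.outer(pats[0].metagene_coefficients, pats[0].trajectory)
        assert np.max(np.abs(recon - ext)) < 1e-12

    def test_reconstruction_identity_random(self, rng):
        B = rng.standard_normal((4, 3))
        U = rng.standard_normal((3, 10))
        pats = extract_epdps(B, U)
        recon = sum(
            np.outer(p.metagene_coefficients, p.trajectory) for p in pats
        )
        assert np.max(np.abs(recon - B @ U[:, :-1])) < 1e-10

    def test_trajectories_are_input_rows(self, rng):
        U = rng.standard_normal((3, 10))
        pats = extract_epdps(rng.standard_normal((4, 3)), U)
        for q, p in enumerate(pats):
            assert np.array_equal(p.trajectory, U[q, :-1])


class TestGeneCoefficients:
    def test_identity_basis_passthrough(self, rng):
        A = _random_diagonalizable(rng, 3)
        pats = extract_ipdps(A, rng.standard_normal(3), T=8)
        basis = MetageneBasis(
            W=np.eye(3), scores=np.zeros((3, 8)),
            singular_values=np.ones(3), explained_fraction=1.0, M=3,
        )
        table = gene_coefficients_ipdp(basis, pats)
        for p in pats:
            assert np.allclose(table[f"iPDP{p.index}"].to_numpy(),
                               p.metagene_coefficients)

    def test_gene_level_internal_reconstruction(self, rng):
        """Sum_p C_p(i) lambda_p^t reproduces W_X @ X_int."""
        ds, truth = make_synthetic_dataset(
            25, 8, 3, 2, 12, [0.9, 0.5, 0.3], noise_sd=0.0, seed=3
        )
        bx = fit_metagenes(ds.internal_matrix, 3)
        bu = fit_metagenes(ds.external_matrix, 2)
        model = estimate_model(bx.scores, bu.scores)
        X1 = bx.scores[:, 0]
        T = 12
        pats = extract_ipdps(model.A_tilde, X1, T)
        table = gene_coefficients_ipdp(bx, pats)
        t = np.arange(1, T + 1)
        recon = np.zeros((25, T))
        for p in pats:
            c = table[f"iPDP{p.index}"].to_numpy()
            term = np.outer(c, p.eigenvalue**t)
            recon += 2 * term.real if p.is_merged_conjugate else term.real
        d = decompose(model, X1, bu.scores)
        assert np.max(np.abs(recon - bx.W @ d.internal)) < 1e-9

    def test_purely_internal_data_reproduces_truncated_fit(self, rng):
        """With no external drive, the gene-level pattern sum equals the
        rank-M approximation of each gene's trajectory."""
        m1, n1, T = 3, 20, 12
        A = _random_diagonalizable(rng, m1)
        x1 = rng.standard_normal(m1)
        scores = simulate(A, np.zeros((m1, 1)), np.zeros((1, T)), x1)
        W = np.linalg.qr(rng.standard_normal((n1, m1)))[0]
        genes = W @ scores  # exactly rank m1
        bx = fit_metagenes(genes, m1)
        model = estimate_model(bx.scores, np.zeros((2, T)))
        pats = extract_ipdps(model.A_tilde, bx.scores[:, 0], T)
        table = gene_coefficients_ipdp(bx, pats)
        tt = np.arange(1, T + 1)
        recon = np.zeros((n1, T))
        for p in pats:
            term = np.outer(table[f"iPDP{p.index}"].to_numpy(),
                            p.eigenvalue**tt)
            recon += 2 * term.real if p.is_merged_conjugate else term.real
        assert np.max(np.abs(recon - genes)) < 1e-7

    def test_epdp_gene_table_and_frobenius(self, rng):
        basis = fit_metagenes(rng.standard_normal((15, 10)), 3)
        B = rng.standard_normal((3, 2))
        D = gene_coefficients_epdp(basis, B)
        assert np.allclose(D.to_numpy(), basis.W @ B)
        assert np.linalg.norm(D.to_numpy()) == pytest.approx(
            np.linalg.norm(B), abs=1e-10
        )
        assert gene_coefficients_epdp(basis, np.zeros((3, 2))).abs().sum().sum() == 0

    def test_epdp_gene_reconstruction(self, rng):
        basis = fit_metagenes(rng.standard_normal((15, 10)), 3)
        B = rng.standard_normal((3, 2))
        U = rng.standard_normal((2, 10))
        D = gene_coefficients_epdp(basis, B).to_numpy()
        assert np.max(np.abs(D @ U[:, :-1] - basis.W @ (B @ U[:, :-1]))) < 1e-9


class TestLooSensitivity:
    def test_identical_copies_zero_width(self, rng):
        from ssx.io_data import ExpressionDataset

        profile = rng.standard_normal(10)
        ds = ExpressionDataset(
            name="copies",
            internal_ids=[f"g{i}" for i in range(10)],
            external_ids=["u0", "u1"],
            internal_matrix=np.tile(profile, (10, 1)),
            external_matrix=rng.standard_normal((2, 10)),
        ).validate()
        out = loo_sensitivity(ds, M1=1, M2=1, group="internal")
        assert float(out["modulus_max"].iloc[0] - out["modulus_min"].iloc[0]) < 1e-9

    def test_matches_brute_force_loop(self):
        ds, _ = make_synthetic_dataset(
            20, 6, 3, 2, 12, [0.9, 0.5, 0.3], noise_sd=0.0, seed=9
        )
        out = loo_sensitivity(ds, M1=3, M2=2, group="internal")
        # independent explicit re-run loop
        spectra = []
        for g in range(20):
            mat = np.delete(ds.internal_matrix, g, axis=0)
            bx = fit_metagenes(mat, 3)
            bu = fit_metagenes(ds.external_matrix, 2)
            model = estimate_model(bx.scores, bu.scores)
            spectra.append(ordered_eigenvalues(model.A_tilde))
        spectra = np.array(spectra)
        for r in range(3):
            col = spectra[:, r]
            assert out["modulus_min"].iloc[r] == np.abs(col).min()
            assert out["modulus_max"].iloc[r] == np.abs(col).max()
            assert out["real_mean"].iloc[r] == col.real.mean()

    def test_zero_loading_gene_leaves_spectrum_unchanged(self, rng):
        ds, _ = make_synthetic_dataset(
            15, 6, 2, 2, 12, [0.8, 0.4], noise_sd=0.0, seed=2
        )
        spiked = np.vstack([ds.internal_matrix, np.zeros(12)])
        bx_full = fit_metagenes(spiked, 2)
        bx_drop = fit_metagenes(ds.internal_matrix, 2)
        bu = fit_metagenes(ds.external_matrix, 2)
        ev_full = ordered_eigenvalues(
            estimate_model(bx_full.scores, bu.scores).A_tilde
        )
        ev_drop = ordered_eigenvalues(
            estimate_model(bx_drop.scores, bu.scores).A_tilde
        )
        assert np.max(np.abs(ev_full - ev_drop)) < 1e-8

    def test_small_group_rejected(self, small_dataset):
        ds, _ = small_dataset
        ds.external_ids = ds.external_ids[:2]
        ds.external_matrix = ds.external_matrix[:2]
        with pytest.raises(ValidationError):
            loo_sensitivity(ds, M1=2, M2=1, group="external")


class TestInteractionPatterns:
    def test_zero_input_empty(self, rng):
        A = _random_diagonalizable(rng, 2)
        model = EffectiveModel(A, np.zeros((2, 2)), 0.0, 4)
        d = decompose(model, rng.standard_normal(2), np.zeros((2, 10)))
        assert interaction_patterns(d, K=3) == []

    def test_fractions_match_independent_svd(self, rng):
        A = _random_diagonalizable(rng, 3)
        B = rng.standard_normal((3, 2))
        model = EffectiveModel(A, B, 0.0, 5)
        d = decompose(model, rng.standard_normal(3),
                      rng.standard_normal((2, 14)))
        out = interaction_patterns(d, K=3)
        s = np.linalg.svd(d.interaction, compute_uv=False)
        want = s**2 / np.sum(s**2)
        assert len(out) == 3
        for k, (vec, frac) in enumerate(out):
            assert frac == pytest.approx(want[k], abs=1e-12)
            assert len(vec) == 14

    def test_rank_one_interaction_fully_captured(self, rng):
        # A = c*I keeps every lagged term A^k B u parallel to B, so the
        # interaction series is exactly rank 1
        B = rng.standard_normal((3, 1))
        model = EffectiveModel(0.5 * np.eye(3), B, 0.0, 4)
        d = decompose(model, rng.standard_normal(3),
                      rng.standard_normal((1, 14)))
        out = interaction_patterns(d, K=1)
        assert len(out) == 1
        assert out[0][1] == pytest.approx(1.0, abs=1e-12)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(seed=st.integers(0, 2**16), m=st.integers(2, 5))
def test_conjugate_closure_and_real_merged(seed, m):
    """Complex eigenvalues pair up; merged trajectories are real."""
    r = np.random.default_rng(seed)
    A = r.standard_normal((m, m)) * 0.5
    if np.linalg.cond(np.linalg.eig(A)[1]) > 1e8:
        return
    pats = extract_ipdps(A, r.standard_normal(m), T=10)
    n_slots = sum(2 if p.is_merged_conjugate else 1 for p in pats)
    assert n_slots == m
    for p in pats:
        assert np.isrealobj(p.trajectory)
        if p.is_merged_conjugate:
            lam = p.eigenvalue
            t = np.arange(1, 11)
            assert np.max(np.abs(
                p.trajectory - (lam**t + np.conj(lam)**t).real
            )) < 1e-10
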