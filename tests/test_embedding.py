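import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqembed import (
    DECODER, ENCODER, ModelConfig, StateTrace, center_columns, forward_collect,
    init_model, origin_projection, pod, pod_of, project, stack_states,
    sve_mode_count,
)
from seqembed.embedding import load_basis, save_basis


def _trace(rng, Te=5, Td=4, N=3):
    return StateTrace(E=rng.normal(size=(Te, N)), D=rng.normal(size=(Td, N)),
                      Yhat=rng.normal(size=(Td, 2)))


class TestCenterColumns:
    def test_simple_column(self):
        Ac, mu = center_columns(np.array([[1.0], [3.0]]))
        np.testing.assert_array_equal(Ac, [[-1.0], [1.0]])
        np.testing.assert_array_equal(mu, [2.0])

    def test_idempotent(self, rng):
        A = rng.normal(size=(6, 3))
        Ac, _ = center_columns(A)
        Ac2, mu2 = center_columns(Ac)
        np.testing.assert_allclose(Ac2, Ac, atol=1e-14)
        np.testing.assert_allclose(mu2, 0.0, atol=1e-14)

    def test_column_sums_vanish(self, rng):
        Ac, _ = center_columns(rng.normal(size=(10, 4)))
        assert np.all(np.abs(Ac.sum(axis=0)) < 1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            center_columns(np.zeros((0, 3)))


class TestPod:
    def test_rank_one(self):
        basis = pod(np.array([[1.0, 0.0], [-1.0, 0.0]]))
        np.testing.assert_allclose(basis.sigma, [np.sqrt(2.0), 0.0], atol=1e-14)

    def test_two_by_two_eigen_oracle(self):
        # centered matrix; sigma^2 must equal the eigenvalues of Ac^T Ac
        # computed from the characteristic polynomial by hand
        Ac, _ = center_columns(np.array([[1.0, 0.0], [0.0, 1.0]]))
        G = Ac.T @ Ac
        tr, det = G[0, 0] + G[1, 1], G[0, 0] * G[1, 1] - G[0, 1] * G[1, 0]
        disc = np.sqrt(tr * tr - 4 * det)
        eig = sorted([(tr + disc) / 2, (tr - disc) / 2], reverse=True)
        basis = pod(Ac)
        np.testing.assert_allclose(basis.sigma ** 2, eig, atol=1e-12)

    def test_nonzero_sigma_count_is_rank(self, rng):
        A = rng.normal(size=(8, 2))
        A = np.hstack([A, A[:, :1] + A[:, 1:]])  # rank 2, 3 columns
        Ac, _ = center_columns(A)
        basis = pod(Ac)
        assert np.sum(basis.sigma > 1e-10) == np.linalg.matrix_rank(Ac)

    def test_reconstruction(self, rng):
        Ac, _ = center_columns(rng.normal(size=(9, 4)))
        b = pod(Ac)
        recon = b.U @ np.diag(b.sigma) @ b.V.T
        assert np.linalg.norm(recon - Ac) < 1e-8 * np.linalg.norm(Ac)

    def test_orthonormal_modes(self, rng):
        b = pod(center_columns(rng.normal(size=(12, 5)))[0])
        np.testing.assert_allclose(b.V.T @ b.V, np.eye(5), atol=1e-8)

    def test_sign_convention(self, rng):
        b = pod(center_columns(rng.normal(size=(7, 4)))[0])
        for j in range(b.V.shape[1]):
            col = b.V[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            pod(np.array([[1.0, np.nan], [0.0, 1.0]]))

    def test_energy_conservation(self, rng):
        Ac, _ = center_columns(rng.normal(size=(20, 6)))
        b = pod(Ac)
        fro2 = np.sum(Ac ** 2)
        assert abs(np.sum(b.sigma ** 2) - fro2) < 1e-8 * fro2

    def test_sigma_sq_match_eigenvalues_random_6x6(self, rng):
        """Independent eigensolver route on all tested 6x6 instances."""
        for _ in range(20):
            Ac, _ = center_columns(rng.normal(size=(6, 6)))
            b = pod(Ac)
            eig = np.sort(np.linalg.eigvalsh(Ac.T @ Ac))[::-1]
            np.testing.assert_allclose(b.sigma ** 2, np.clip(eig, 0, None),
                                       atol=1e-10)


def _oracle_mode_count(sigma, p):
    energy = np.asarray(sigma, dtype=float) ** 2
    total = energy.sum()
    acc = 0.0
    for k, e in enumerate(energy, start=1):
        acc += e
        if acc / total >= p - 1e-12:
            return k
    return len(energy)


class TestSveModeCount:
    def test_examples(self):
        assert sve_mode_count(np.array([3.0, 1.0]), 0.9) == 1
        assert sve_mode_count(np.array([1.0, 1.0, 1.0, 1.0]), 0.99) == 4

    def test_full_energy_counts_nonzero_modes(self):
        assert sve_mode_count(np.array([2.0, 1.0, 0.0]), 1.0) == 2

    def test_matches_cumsum_oracle(self, rng):
        for _ in range(50):
            sigma = np.sort(rng.uniform(0, 5, size=rng.integers(1, 9)))[::-1]
            for p in (0.5, 0.9, 0.99, 1.0):
                assert sve_mode_count(sigma, p) == _oracle_mode_count(sigma, p)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            sve_mode_count(np.array([1.0]), 0.0)
        with pytest.raises(ValueError):
            sve_mode_count(np.array([1.0]), 1.5)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            sve_mode_count(np.zeros(3), 0.9)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.01, 10.0), min_size=1, max_size=8),
           st.floats(0.01, 1.0), st.floats(0.01, 1.0))
    def test_monotone_in_p(self, values, p1, p2):
        sigma = np.sort(np.asarray(values))[::-1]
        lo, hi = sorted([p1, p2])
        assert sve_mode_count(sigma, lo) <= sve_mode_count(sigma, hi)


class TestStackStates:
    def test_three_trace_shape(self):
        model = init_model(ModelConfig(n_units=16, n_features=2, seed=0))
        rng = np.random.default_rng(0)
        traces = [forward_collect(model, rng.normal(size=(50, 2)), 50)
                  for _ in range(3)]
        gsm = stack_states(traces, [0, 1, 2])
        assert gsm.S.shape == (300, 16)

    def test_single_trace_equals_its_s(self, rng):
        t = _trace(rng)
        gsm = stack_states([t], [0])
        np.testing.assert_array_equal(gsm.S, t.S)

    def test_phase_counts(self, rng):
        traces = [_trace(rng, Te=5, Td=4) for _ in range(3)]
        gsm = stack_states(traces, [0, 1, 2])
        assert int((gsm.phases == ENCODER).sum()) == 15
        assert int((gsm.phases == DECODER).sum()) == 12

    def test_encoder_rows_precede_decoder_rows(self, rng):
        gsm = stack_states([_trace(rng, Te=3, Td=2)], [0])
        np.testing.assert_array_equal(gsm.phases,
                                      [ENCODER] * 3 + [DECODER] * 2)

    def test_mismatched_width_rejected(self, rng):
        with pytest.raises(ValueError):
            stack_states([_trace(rng, N=3), _trace(rng, N=4)], [0, 1])


class TestProject:
    def test_roundtrip_reconstruction(self, rng):
        A = rng.normal(size=(10, 6))
        basis = pod_of(A)
        proj = project(A, basis, 6)
        recon = proj @ basis.V.T + basis.mu
        assert np.linalg.norm(recon - A) < 1e-8 * np.linalg.norm(A)

    def test_zero_row_projects_to_minus_mu_v(self, rng):
        A = rng.normal(size=(8, 4))
        basis = pod_of(A)
        got = project(np.zeros((1, 4)), basis, 3)[0]
        np.testing.assert_allclose(got, -basis.mu @ basis.V[:, :3], atol=1e-12)
        np.testing.assert_allclose(origin_projection(basis, 3), got, atol=1e-15)

    def test_three_columns_for_pc3(self, rng):
        A = rng.normal(size=(8, 5))
        assert project(A, pod_of(A), 3).shape == (8, 3)

    def test_out_of_range_n_rejected(self, rng):
        A = rng.normal(size=(8, 4))
        basis = pod_of(A)
        with pytest.raises(ValueError):
            project(A, basis, 0)
        with pytest.raises(ValueError):
            project(A, basis, 5)

    def test_isometry_at_full_dimension(self, rng):
        from scipy.spatial.distance import pdist
        A = rng.normal(size=(9, 5))
        basis = pod_of(A)
        d0 = pdist(A)
        d1 = pdist(project(A, basis, 5))
        np.testing.assert_allclose(d0, d1, atol=1e-8)


def test_basis_roundtrip(tmp_path, rng):
    basis = pod_of(rng.normal(size=(10, 4)))
    save_basis(basis, tmp_path / "basis.npz", {"iteration": 42})
    loaded, prov = load_basis(tmp_path / "basis.npz")
    np.testing.assert_array_equal(loaded.V, basis.V)
    np.testing.assert_array_equal(loaded.mu, basis.mu)
    np.testing.assert_array_equal(loaded.sigma, basis.sigma)
    assert prov == {"iteration": 42}
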