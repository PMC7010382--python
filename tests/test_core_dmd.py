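"""Core DMD: snapshot construction, spectra, mode ordering, Vandermonde."""

import numpy as np
import pytest

from wrdmd import (
    DegenerateInputError,
    FrameStack,
    InvalidInputError,
    ReconstructionConfig,
    build_snapshot_matrix,
    build_vandermonde,
    compute_dmd,
    order_modes,
    reconstruct,
)
from wrdmd.core import DMDDecomposition


def _decomp_with_eigenvalues(eigvals):
    """Minimal decomposition stub for ordering tests (only the spectrum and
    eigenvector/mode shapes matter to order_modes)."""
    eigvals = np.asarray(eigvals, dtype=np.complex128)
    d = eigvals.size
    return DMDDecomposition(
        left_singular=np.zeros((4, d)),
        singular_values=np.ones(d),
        right_singular=np.zeros((d, d)),
        reduced_operator=np.zeros((d, d)),
        eigenvalues=eigvals,
        eigenvectors=np.eye(d, dtype=np.complex128),
        modes=np.zeros((4, d), dtype=np.complex128),
        frequencies=np.log(eigvals),
        dt=1.0,
        frame_shape=(2, 2),
    )


class TestSnapshotMatrix:
    def test_shape_and_raster_order(self):
        frames = [np.array([[1.0, 2.0], [3.0, 4.0]]) + 10 * t for t in range(5)]
        sm = build_snapshot_matrix(FrameStack.from_frames(frames, dt=1.0))
        assert sm.data.shape == (4, 5)
        np.testing.assert_array_equal(sm.data[:, 0], [1.0, 2.0, 3.0, 4.0])
        for r in range(5):
            np.testing.assert_array_equal(sm.column_as_frame(r), frames[r])

    def test_clinical_frame_geometry(self):
        stack = FrameStack(np.ones((120, 240, 320)), dt=1.5)
        assert build_snapshot_matrix(stack).data.shape == (76800, 120)

    def test_mismatched_frame_sizes_rejected(self):
        with pytest.raises(InvalidInputError):
            FrameStack.from_frames([np.ones((2, 2)), np.ones((3, 2))], dt=1.0)


class TestComputeDMD:
    def test_constant_sequence_single_background_mode(self):
        v = np.arange(6.0).reshape(2, 3) + 1
        sm = build_snapshot_matrix(FrameStack(np.stack([v] * 6), dt=1.0))
        d = compute_dmd(sm)
        assert d.n_modes == 1
        assert d.eigenvalues[0] == pytest.approx(1.0, abs=1e-10)
        assert abs(d.frequencies[0]) == pytest.approx(0.0, abs=1e-10)

    def test_scalar_decay_eigenvalue(self):
        v = np.random.default_rng(0).random((3, 4)) + 0.5
        frames = np.stack([0.9**t * v for t in range(8)])
        d = compute_dmd(build_snapshot_matrix(FrameStack(frames, dt=1.0)))
        assert d.n_modes == 1
        assert abs(d.eigenvalues[0] - 0.9) < 1e-8

    def test_full_rank_mode_count(self):
        frames = np.random.default_rng(1).standard_normal((118, 12, 12))
        d = compute_dmd(build_snapshot_matrix(FrameStack(frames, dt=1.5)))
        assert d.n_modes == 117

    def test_svd_rank_cap(self):
        frames = np.random.default_rng(2).standard_normal((10, 6, 6))
        sm = build_snapshot_matrix(FrameStack(frames, dt=1.0))
        assert compute_dmd(sm, svd_rank=4).n_modes == 4
        with pytest.raises(InvalidInputError):
            compute_dmd(sm, svd_rank=10)

    def test_all_zero_frames_degenerate(self):
        sm = build_snapshot_matrix(FrameStack(np.zeros((5, 3, 3)), dt=1.0))
        with pytest.raises(DegenerateInputError):
            compute_dmd(sm)

    def test_rotation_block_spectral_recovery(self):
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        state = np.array([1.0, 0.3])
        states = [state]
        for _ in range(9):
            states.append(rot @ states[-1])
        embed = np.random.default_rng(3).standard_normal((2, 36))
        frames = np.stack([(s @ embed).reshape(6, 6) for s in states])
        d = compute_dmd(build_snapshot_matrix(FrameStack(frames, dt=1.0)))
        got = np.sort_complex(d.eigenvalues)
        expected = np.sort_complex(np.array([np.exp(1j * theta), np.exp(-1j * theta)]))
        assert np.abs(got - expected).max() < 1e-6

    def test_linearity_scaling(self):
        rng = np.random.default_rng(4)
        frames = rng.standard_normal((8, 5, 5))
        d1 = compute_dmd(build_snapshot_matrix(FrameStack(frames, dt=1.0)))
        d2 = compute_dmd(build_snapshot_matrix(FrameStack(3.5 * frames, dt=1.0)))
        np.testing.assert_allclose(
            np.sort_complex(d1.eigenvalues), np.sort_complex(d2.eigenvalues), atol=1e-9
        )
        r1 = reconstruct(d1, None, ReconstructionConfig(k=d1.n_modes))
        r2 = reconstruct(d2, None, ReconstructionConfig(k=d2.n_modes))
        np.testing.assert_allclose(3.5 * r1.data, r2.data, rtol=1e-8)

    def test_modes_satisfy_definition(self):
        # Psi = P2 V Sigma^-1 omega must hold for the returned factors
        rng = np.random.default_rng(5)
        frames = rng.standard_normal((7, 4, 4))
        sm = build_snapshot_matrix(FrameStack(frames, dt=1.0))
        d = compute_dmd(sm)
        P2 = sm.data[:, 1:]
        expected = (
            P2 @ d.right_singular / d.singular_values[np.newaxis, :]
        ) @ d.eigenvectors
        np.testing.assert_allclose(d.modes, expected, atol=1e-10)

    def test_conjugate_symmetry_of_real_data(self):
        rng = np.random.default_rng(6)
        frames = rng.standard_normal((12, 5, 5))
        d = compute_dmd(build_snapshot_matrix(FrameStack(frames, dt=1.0)))
        eig = d.eigenvalues
        nonreal = eig[np.abs(eig.imag) > 1e-10]
        for s in nonreal:
            assert np.min(np.abs(nonreal - np.conj(s))) < 1e-8 * (1 + abs(s))


class TestOrderModes:
    def test_conjugate_pair_collapses(self):
        eig = [1.0, 0.8 * np.exp(1j * np.pi / 4), 0.8 * np.exp(-1j * np.pi / 4)]
        o = order_modes(_decomp_with_eigenvalues(eig))
        assert o.n_kept == 2
        np.testing.assert_allclose(o.phase_angles, [0.0, np.pi / 4], atol=1e-12)
        assert list(o.kept_indices) == [0, 1]  # non-negative imag member kept

    def test_all_real_positive_retained_sorted_by_magnitude(self):
        o = order_modes(_decomp_with_eigenvalues([0.5, 0.9, 0.7]))
        assert o.n_kept == 3
        assert list(o.kept_indices) == [1, 2, 0]  # angle ties: descending |sigma|
        assert np.all(np.diff(o.phase_angles) >= 0)

    def test_one_real_plus_58_pairs_keeps_59(self):
        rng = np.random.default_rng(7)
        angles = rng.uniform(0.05, 3.0, 58)
        eig = np.concatenate(
            [[1.0 + 0j], 0.95 * np.exp(1j * angles), 0.95 * np.exp(-1j * angles)]
        )
        eig = eig[rng.permutation(117)]
        o = order_modes(_decomp_with_eigenvalues(eig))
        assert o.n_kept == 59
        assert np.all(eig[o.kept_indices].imag >= -1e-12)

    def test_phase_angles_non_decreasing_on_real_data(self):
        rng = np.random.default_rng(8)
        frames = rng.standard_normal((10, 4, 4))
        d = compute_dmd(build_snapshot_matrix(FrameStack(frames, dt=1.0)))
        o = order_modes(d)
        assert np.all(np.diff(o.phase_angles) >= 0)


class TestVandermonde:
    @pytest.mark.parametrize(
        "eig, f, expected",
        [
            ([2.0], 2, [[1.0, 2.0, 4.0]]),
            ([1.0, 1.0], 3, np.ones((2, 4))),
            ([2.0, 3.0], 3, [[1, 2, 4, 8], [1, 3, 9, 27]]),
        ],
    )
    def test_rows_are_powers(self, eig, f, expected):
        np.testing.assert_allclose(build_vandermonde(eig, f), expected)

    def test_shape_and_complex(self):
        eig = [0.5 * np.exp(1j * 0.3), 1.0]
        V = build_vandermonde(eig, 5)
        assert V.shape == (2, 6)
        np.testing.assert_allclose(V[0], np.asarray(eig[0]) ** np.arange(6))

    def test_negative_f_rejected(self):
        with pytest.raises(InvalidInputError):
            build_vandermonde([1.0], -1)
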