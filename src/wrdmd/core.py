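r"""SVD-based dynamic mode decomposition (DMD) of an image sequence.

DMD treats a sequence of vectorised frames
:math:`X = [\bar{x}_1, \ldots, \bar{x}_N]` as snapshots of a linear dynamical
system: an (unknown) propagator :math:`A` maps each frame to the next,
:math:`P_2 = A P_1`, where :math:`P_1` holds frames :math:`1..N-1` and
:math:`P_2` frames :math:`2..N`. For image data :math:`A` is far too large to
form (:math:`mn \times mn`), so its spectrum is approximated on the left
singular subspace of :math:`P_1`: with the thin SVD
:math:`P_1 = U \Sigma V^*`, the reduced operator

.. math:: \tilde{H} = U^* P_2 V \Sigma^{-1}

has eigenpairs :math:`(\sigma_j, \omega_j)` that approximate eigenvalues of
:math:`A`, and the dynamic modes are

.. math:: \Psi = P_2 V \Sigma^{-1} \omega .

Each mode is a spatial image pattern; its eigenvalue :math:`\sigma_j` encodes
per-frame growth/decay (magnitude) and oscillation (phase). Continuous-time
frequencies follow as :math:`\mu_j = \ln(\sigma_j) / \delta t`. Modes whose
eigenvalue phase angle is near zero vary slowly across the sequence
(background / contrast enhancement); large phase angles mark fast dynamics
(motion, noise). Ordering modes by ascending absolute phase angle, after
collapsing each complex-conjugate pair to a single representative, therefore
ranks them from most to least significant for a contrast-enhanced sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError, InvalidInputError
from .frames import FrameStack

__all__ = [
    "SnapshotMatrix",
    "DMDDecomposition",
    "ModeOrdering",
    "build_snapshot_matrix",
    "compute_dmd",
    "order_modes",
    "build_vandermonde",
]

#: Relative threshold below which singular values are treated as zero.
#: Inverting near-zero singular values would amplify noise into the modes.
SVD_TRUNCATION_RTOL = 1e-10

#: Default tolerance (radians / relative eigenvalue distance) for deciding
#: that two eigenvalues form a complex-conjugate pair.
CONJUGATE_PAIR_RTOL = 1e-8


@dataclass(frozen=True)
class SnapshotMatrix:
    """Vectorised frame sequence: column ``r`` is frame ``r`` flattened.

    Flattening is raster order (row-major / C order); reshaping any column
    with the stored ``frame_shape`` recovers the frame exactly. The same
    convention is used when modes and reconstructions are reshaped back to
    images.
    """

    data: np.ndarray  # (m*n, N)
    frame_shape: tuple[int, int]
    dt: float
    start_index: int = 0

    @property
    def n_snapshots(self) -> int:
        return self.data.shape[1]

    def column_as_frame(self, r: int) -> np.ndarray:
        return self.data[:, r].reshape(self.frame_shape)


@dataclass(frozen=True)
class DMDDecomposition:
    """All factors of one DMD run.

    ``d`` is the number of retained modes: at most ``N - 1``, reduced by SVD
    truncation and any requested ``svd_rank``.
    """

    left_singular: np.ndarray  # U, (m*n) x d
    singular_values: np.ndarray  # d, descending, strictly positive
    right_singular: np.ndarray  # V, (N-1) x d (columns orthonormal)
    reduced_operator: np.ndarray  # H~, d x d
    eigenvalues: np.ndarray  # sigma_j, d complex
    eigenvectors: np.ndarray  # omega, d x d complex (columns)
    modes: np.ndarray  # Psi, (m*n) x d complex
    frequencies: np.ndarray  # mu_j = ln(sigma_j)/dt, d complex, 1/seconds
    dt: float
    frame_shape: tuple[int, int]
    start_index: int = 0

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.shape[0]

    def mode_image(self, j: int) -> np.ndarray:
        """Complex spatial pattern of mode ``j`` reshaped to frame geometry."""
        return self.modes[:, j].reshape(self.frame_shape)


@dataclass(frozen=True)
class ModeOrdering:
    """Significance ordering: one representative per conjugate pair, sorted by
    ascending absolute phase angle of the eigenvalue."""

    kept_indices: np.ndarray  # indices into the decomposition's modes
    phase_angles: np.ndarray  # matching |angle| values, radians, non-decreasing

    @property
    def n_kept(self) -> int:
        return self.kept_indices.shape[0]


def build_snapshot_matrix(stack: FrameStack) -> SnapshotMatrix:
    """Vectorise a frame stack into an ``(m*n, N)`` snapshot matrix."""
    if stack.n_frames < 2:
        raise InvalidInputError("snapshot matrix needs at least 2 frames")
    n, m, w = stack.data.shape
    data = stack.data.reshape(n, m * w).T.copy()
    return SnapshotMatrix(
        data=data,
        frame_shape=(m, w),
        dt=stack.dt,
        start_index=stack.start_index,
    )


def compute_dmd(
    X: SnapshotMatrix,
    dt: float | None = None,
    svd_rank: int | None = None,
) -> DMDDecomposition:
    """Dynamic mode decomposition of a snapshot matrix via the SVD route.

    Parameters
    ----------
    X
        Snapshot matrix of ``N >= 2`` frames; ``P1`` / ``P2`` are its first /
        last ``N - 1`` columns.
    dt
        Inter-frame interval used for the mode frequencies
        ``mu_j = ln(sigma_j) / dt``; defaults to the interval carried by
        ``X``. Mode ordering and reconstruction do not depend on it.
    svd_rank
        Optional hard cap on the number of singular values retained (and
        hence modes). Must not exceed ``N - 1``.

    Returns
    -------
    DMDDecomposition
        With ``d = min(svd_rank, numerical rank of P1, N - 1)`` modes; for a
        full-rank ``N``-frame input ``d = N - 1``.

    Raises
    ------
    DegenerateInputError
        If ``P1`` is numerically rank zero (all-zero frames).
    """
    if dt is None:
        dt = X.dt
    N = X.n_snapshots
    if N < 2:
        raise InvalidInputError(f"DMD needs at least 2 snapshots, got {N}")
    if svd_rank is not None and not (1 <= svd_rank <= N - 1):
        raise InvalidInputError(
            f"svd_rank must be in [1, N-1] = [1, {N - 1}], got {svd_rank}"
        )

    P1 = X.data[:, :-1]
    P2 = X.data[:, 1:]

    U, s, Vh = np.linalg.svd(P1, full_matrices=False)
    if s.size == 0 or s[0] <= 0.0:
        raise DegenerateInputError("P1 has numerical rank 0 (all-zero frames?)")
    keep = s > s[0] * SVD_TRUNCATION_RTOL
    d = int(np.count_nonzero(keep))
    if svd_rank is not None:
        d = min(d, svd_rank)

    U = U[:, :d]
    s = s[:d]
    V = Vh[:d].conj().T  # (N-1) x d, orthonormal columns

    # H~ = U* P2 V Sigma^-1, formed without ever materialising A.
    H = (U.conj().T @ P2 @ V) / s[np.newaxis, :]
    eigvals, eigvecs = np.linalg.eig(H)

    modes = (P2 @ V / s[np.newaxis, :]) @ eigvecs

    with np.errstate(divide="ignore", invalid="ignore"):
        freqs = np.log(eigvals.astype(np.complex128)) / dt

    return DMDDecomposition(
        left_singular=U,
        singular_values=s,
        right_singular=V,
        reduced_operator=H,
        eigenvalues=eigvals,
        eigenvectors=eigvecs,
        modes=modes,
        frequencies=freqs,
        dt=dt,
        frame_shape=X.frame_shape,
        start_index=X.start_index,
    )


def _conjugate_pairs(
    eigvals: np.ndarray, tol_scale: float
) -> tuple[list[int], list[tuple[int, int]]]:
    """Partition eigenvalue indices into singletons and conjugate pairs.

    Two eigenvalues are a pair when ``|s_a - conj(s_b)| < tol*(1+|s_a|)`` and
    both have imaginary parts beyond the same tolerance (a numerically real
    eigenvalue is its own conjugate and never pairs, so repeated real
    eigenvalues are all retained).
    """
    n = eigvals.shape[0]
    used = np.zeros(n, dtype=bool)
    singles: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i in range(n):
        if used[i]:
            continue
        tol_i = tol_scale * (1.0 + abs(eigvals[i]))
        if abs(eigvals[i].imag) < tol_i:
            singles.append(i)
            used[i] = True
            continue
        partner = -1
        for j in range(i + 1, n):
            if used[j]:
                continue
            if abs(eigvals[i] - np.conj(eigvals[j])) < tol_i:
                partner = j
                break
        if partner >= 0:
            pairs.append((i, partner))
            used[i] = used[partner] = True
        else:
            singles.append(i)
            used[i] = True
    return singles, pairs


def order_modes(
    decomp: DMDDecomposition, uniqueness_tol: float = CONJUGATE_PAIR_RTOL
) -> ModeOrdering:
    """Collapse conjugate pairs and sort modes by ascending |phase angle|.

    For real input data, non-real eigenvalues occur in complex-conjugate
    pairs whose modes carry duplicate information; only the member with
    non-negative imaginary part is kept. The survivors are sorted by the
    absolute phase angle of their eigenvalue (stable, ties broken by
    descending eigenvalue magnitude so the dominant background-like mode
    comes first). Real positive eigenvalues have angle 0 and lead the order.

    ``uniqueness_tol`` scales both the conjugate-pair matching distance and
    the threshold below which an imaginary part counts as zero.
    """
    if decomp.n_modes < 1:
        raise InvalidInputError("decomposition has no modes to order")
    eigvals = decomp.eigenvalues
    singles, pairs = _conjugate_pairs(eigvals, uniqueness_tol)
    kept = list(singles)
    for i, j in pairs:
        kept.append(i if eigvals[i].imag >= 0 else j)

    kept.sort()  # restore input order before the stable significance sort
    angles = np.abs(np.angle(eigvals))
    kept_sorted = sorted(kept, key=lambda idx: (angles[idx], -abs(eigvals[idx])))
    kept_arr = np.asarray(kept_sorted, dtype=np.intp)
    return ModeOrdering(kept_indices=kept_arr, phase_angles=angles[kept_arr])


def build_vandermonde(eigenvalues, f: int) -> np.ndarray:
    """Temporal Vandermonde matrix: row ``j`` is ``(1, s_j, s_j^2, ..., s_j^f)``.

    Powers of the eigenvalues give each mode's amplitude trajectory over
    ``f + 1`` time steps; with ``f >= N`` the matrix extrapolates beyond the
    observed sequence.
    """
    if f < 0:
        raise InvalidInputError(f"f must be >= 0, got {f}")
    eig = np.asarray(eigenvalues, dtype=np.complex128)
    if eig.ndim != 1:
        raise InvalidInputError("eigenvalues must be a 1-D sequence")
    return np.vander(eig, f + 1, increasing=True)
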