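"""Per-timepoint phase-coherence states and the CCD matrix.

At each TR the pairwise synchrony of the N regions is summarised by the
coherence vector V(t): the cosine of the instantaneous phase difference of
every region pair (upper triangle, i < j, row-major). The coherence
connectivity dynamics (CCD) matrix is the T x T cosine similarity between
these vectors,

    CCD(t_i, t_j) = V(t_i) . V(t_j) / (|V(t_i)| |V(t_j)|),

and is the feature space on which the intrinsic manifold is built. No
temporal windowing is involved: every column of the phase track yields one
state.
"""

from __future__ import annotations

import numpy as np

from .datatypes import CCDMatrix, CoherenceState, PhaseTrack


def phase_coherence_matrix(phases_at_t: np.ndarray) -> np.ndarray:
    """N x N matrix of cos(theta_i - theta_j) for one timepoint."""
    theta = np.asarray(phases_at_t, dtype=float)
    if theta.ndim != 1:
        raise ValueError("expected a length-N phase vector")
    if not np.isfinite(theta).all():
        raise ValueError("non-finite phase value")
    return np.cos(theta[:, None] - theta[None, :])


def coherence_vector(matrix: np.ndarray, tr_index: int = 0) -> CoherenceState:
    """Vectorize the upper triangle (i < j, row-major) of a coherence matrix.

    The diagonal (constant 1) is excluded; only between-region pairs enter
    the state vector.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("coherence matrix must be square")
    if not np.allclose(m, m.T, atol=1e-9):
        raise ValueError("coherence matrix must be symmetric (tol 1e-9)")
    iu, ju = np.triu_indices(m.shape[0], k=1)
    return CoherenceState(vector=m[iu, ju], tr_index=tr_index)


def coherence_states(phases: PhaseTrack) -> np.ndarray:
    """All T coherence vectors as a (T, N(N-1)/2) array, vectorized over t."""
    iu, ju = np.triu_indices(phases.n_regions, k=1)
    # cos(theta_i - theta_j) for every pair, all timepoints at once
    return np.cos(phases.phases[iu, :] - phases.phases[ju, :]).T


def ccd(states: np.ndarray, tr_seconds: float = 1.0) -> CCDMatrix:
    """Cosine-similarity matrix between all pairs of coherence states.

    Parameters
    ----------
    states : ndarray, shape (T, n_pairs)
        One coherence vector per row (e.g. from :func:`coherence_states`),
        or a sequence of :class:`CoherenceState`.

    Raises
    ------
    ValueError
        If any state has zero norm (cosine similarity undefined; happens
        only when every pair sits exactly at +-pi/2).
    """
    if len(states) and isinstance(states[0], CoherenceState):
        states = np.stack([s.vector for s in states])
    V = np.asarray(states, dtype=float)
    if V.ndim != 2:
        raise ValueError("states must be a (T, n_pairs) array")
    norms = np.linalg.norm(V, axis=1)
    zero = np.flatnonzero(norms == 0.0)
    if zero.size:
        raise ValueError(f"zero-norm coherence state at t={int(zero[0])}")
    U = V / norms[:, None]
    m = U @ U.T
    m = np.clip((m + m.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return CCDMatrix(matrix=m, tr_seconds=tr_seconds)


def ccd_from_phases(phases: PhaseTrack) -> CCDMatrix:
    """Convenience: phase track -> coherence states -> CCD matrix."""
    return ccd(coherence_states(phases), tr_seconds=phases.tr_seconds)
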