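"""Core in-memory containers shared across the pipeline stages.

Every container validates its own invariants on construction so that a
malformed object cannot propagate silently between stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical vocabulary of brain states (wakefulness + non-REM sleep stages).
STAGE_VOCABULARY: tuple[str, ...] = ("Awake", "N1", "N2", "N3")

#: Sentinel used for TRs without a valid stage label.
UNSCORED: str = ""


@dataclass
class ParcellatedTimeseries:
    """Region-parcellated BOLD signal: ``data[i, t]`` is region ``i`` at TR ``t``.

    Parameters
    ----------
    data : ndarray, shape (n_regions, n_trs)
        Real-valued signal, no missing values.
    tr_seconds : float
        Sampling interval (repetition time) in seconds.
    region_ids : list of str, optional
        One label per region; defaults to ``["roi_0", ...]``.
    band : tuple of (float, float), optional
        (low_hz, high_hz) of a band-pass filter already applied, if any.
    """

    data: np.ndarray
    tr_seconds: float
    region_ids: list[str] | None = None
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (n_regions, n_trs) array")
        if not np.isfinite(self.data).all():
            raise ValueError("time series contains non-finite values")
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.region_ids is None:
            self.region_ids = [f"roi_{i}" for i in range(self.n_regions)]
        elif len(self.region_ids) != self.n_regions:
            raise ValueError("region_ids length does not match data rows")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_trs(self) -> int:
        return self.data.shape[1]

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.tr_seconds

    @property
    def nyquist(self) -> float:
        return 0.5 / self.tr_seconds


@dataclass
class PhaseTrack:
    """Instantaneous phases in radians, wrapped to (-pi, pi]."""

    phases: np.ndarray  # (n_regions, n_trs)
    tr_seconds: float

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if not np.isfinite(self.phases).all():
            raise ValueError("phase track contains non-finite values")
        if np.any(self.phases <= -np.pi) or np.any(self.phases > np.pi):
            raise ValueError("phases must be wrapped to (-pi, pi]")

    @property
    def n_regions(self) -> int:
        return self.phases.shape[0]

    @property
    def n_trs(self) -> int:
        return self.phases.shape[1]


@dataclass
class StageLabels:
    """Per-TR categorical stage track (a hypnogram sampled at the TR grid).

    Unscored TRs carry the empty-string sentinel and are excluded from
    decoding; ``scored_mask`` selects the valid TRs.
    """

    labels: np.ndarray  # (n_trs,) of str
    subject_id: str = "subject_0"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D array")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def scored_mask(self) -> np.ndarray:
        return np.asarray([lab != UNSCORED for lab in self.labels], dtype=bool)

    @property
    def stages(self) -> list[str]:
        """Distinct scored stages, in canonical order where applicable."""
        present = {lab for lab in self.labels if lab != UNSCORED}
        ordered = [s for s in STAGE_VOCABULARY if s in present]
        ordered += sorted(present - set(STAGE_VOCABULARY))
        return ordered

    def indices_of(self, stage: str) -> np.ndarray:
        return np.flatnonzero(self.labels == stage)


@dataclass
class CoherenceState:
    """Vectorized upper triangle of one TR's phase-coherence matrix."""

    vector: np.ndarray  # (n_pairs,) in [-1, 1]
    tr_index: int = 0

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if np.any(np.abs(self.vector) > 1 + 1e-12):
            raise ValueError("coherence entries must lie in [-1, 1]")


@dataclass
class CCDMatrix:
    """Coherence connectivity dynamics: T x T cosine similarity of states."""

    matrix: np.ndarray
    tr_seconds: float = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("CCD must be square")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("CCD must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-9):
            raise ValueError("CCD diagonal must be 1")
        if np.any(np.abs(m) > 1 + 1e-9):
            raise ValueError("CCD entries must lie in [-1, 1]")
        self.matrix = m

    @property
    def n_trs(self) -> int:
        return self.matrix.shape[0]


@dataclass
class DistanceMatrix:
    """Dissimilarity between timepoint coherence states: d = 1 - CCD."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if np.any(m < -1e-12) or np.any(m > 2 + 1e-9):
            raise ValueError("distances must lie in [0, 2]")
        np.fill_diagonal(m, 0.0)
        self.matrix = m

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ManifoldEmbedding:
    """Low-dimensional coordinates of the T timepoints.

    For Laplacian eigenmaps the columns are the eigenvectors of the graph
    Laplacian for the ``d`` smallest non-trivial eigenvalues (ascending);
    for PCA they are the top-``d`` principal-component scores.
    """

    coords: np.ndarray  # (n_trs, d)
    eigenvalues: np.ndarray  # (d,)
    method: str  # "laplacian_eigenmaps" | "pca"
    ambient_dim: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("coords must be 2-D (n_trs, d)")
        if self.eigenvalues.shape != (self.coords.shape[1],):
            raise ValueError("one eigenvalue per embedding dimension required")

    @property
    def n_trs(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]
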