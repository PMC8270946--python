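"""Procrustes alignment of per-subject manifold embeddings.

Eigenvector embeddings are defined only up to rotation, reflection, sign
and scale, so per-subject manifolds live in arbitrary orientations of the
same space. Alignment uses per-stage landmarks — for each stage the
embedded timepoints with minimum and maximum Euclidean norm — and solves
the full Procrustes problem (orthogonal transform with reflections
allowed, isotropic scale, translation) that maps a subject's landmarks
onto a reference subject's landmarks. The fitted transform is then
applied to all of the subject's timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import ManifoldEmbedding, StageLabels


@dataclass
class LandmarkSet:
    """Two landmarks (min-norm, max-norm point) per stage of one subject.

    ``points`` has one row per landmark, ordered (stage_0 min, stage_0 max,
    stage_1 min, ...) following ``stages``; rows are actual embedding
    coordinates, so correspondence across subjects is by (stage, role).
    """

    points: np.ndarray  # (2 * n_stages, d)
    stages: list[str]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape[0] != 2 * len(self.stages):
            raise ValueError("expected exactly two landmarks per stage")


@dataclass
class AlignmentTransform:
    """Similarity transform x -> scale * R x + translation (R orthogonal)."""

    rotation: np.ndarray  # (d, d), R^T R = I, reflections allowed
    scale: float
    translation: np.ndarray  # (d,)
    residual: float  # Frobenius misfit on the landmarks

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R.T @ R, np.eye(R.shape[0]), atol=1e-8):
            raise ValueError("rotation must be orthogonal to 1e-8")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        X = np.asarray(coords, dtype=float)
        if X.shape[1] != self.rotation.shape[0]:
            raise ValueError("dimension mismatch between coords and transform")
        return self.scale * X @ self.rotation.T + self.translation

    @classmethod
    def identity(cls, d: int) -> "AlignmentTransform":
        return cls(rotation=np.eye(d), scale=1.0, translation=np.zeros(d), residual=0.0)


def extract_landmarks(
    embedding: ManifoldEmbedding, labels: StageLabels
) -> LandmarkSet:
    """Min-norm and max-norm embedded point of every stage.

    Ties on the norm are broken by the smallest TR index. A stage with
    fewer than two timepoints cannot supply both landmarks and raises.
    """
    if len(labels) != embedding.n_trs:
        raise ValueError("labels and embedding length differ")
    coords = embedding.coords
    norms = np.linalg.norm(coords, axis=1)
    rows = []
    stages = labels.stages
    for stage in stages:
        idx = labels.indices_of(stage)
        if idx.size < 2:
            raise ValueError(f"stage {stage!r} has fewer than 2 timepoints")
        lo = idx[np.argmin(norms[idx])]  # argmin/argmax take the first tie
        hi = idx[np.argmax(norms[idx])]
        rows.append(coords[lo])
        rows.append(coords[hi])
    return LandmarkSet(points=np.asarray(rows), stages=stages)


def fit_alignment(source: LandmarkSet, reference: LandmarkSet) -> AlignmentTransform:
    """Full Procrustes fit of source landmarks onto reference landmarks.

    Minimises ``|| s * X_src R^T + t - X_ref ||_F`` over orthogonal R
    (reflections allowed), isotropic scale s > 0 and translation t; this
    is the classic closed-form solution via the SVD of the centred
    cross-covariance.
    """
    X, Y = source.points, reference.points
    if X.shape != Y.shape:
        raise ValueError("landmark sets must have identical shape")
    if source.stages != reference.stages:
        raise ValueError("landmark stages must correspond")
    mx, my = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - mx, Y - my
    normX = np.linalg.norm(Xc)
    if normX < 1e-12:
        raise ValueError("degenerate source landmarks (all coincident)")
    U, s, Vt = np.linalg.svd(Yc.T @ Xc)
    R = U @ Vt
    scale = float(s.sum() / normX**2)
    if scale <= 0:  # only possible for pathological rank-0 input
        raise ValueError("non-positive Procrustes scale")
    translation = my - scale * R @ mx
    residual = float(np.linalg.norm(scale * Xc @ R.T - Yc))
    return AlignmentTransform(
        rotation=R, scale=scale, translation=translation, residual=residual
    )


def apply_alignment(
    embedding: ManifoldEmbedding, transform: AlignmentTransform
) -> ManifoldEmbedding:
    """Map every timepoint of an embedding through a fitted transform."""
    return ManifoldEmbedding(
        coords=transform.apply(embedding.coords),
        eigenvalues=embedding.eigenvalues,
        method=embedding.method,
        ambient_dim=embedding.ambient_dim,
    )


def align_group(
    embeddings: list[ManifoldEmbedding],
    labels_list: list[StageLabels],
    reference_subject: int = 0,
    generalized: bool = False,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[list[ManifoldEmbedding], list[AlignmentTransform]]:
    """Align all subjects' embeddings into a common space.

    By default every subject is mapped onto ``reference_subject``'s
    landmarks. With ``generalized=True`` the reference is iteratively
    replaced by the mean landmark configuration (generalized Procrustes)
    until the total residual stabilises.
    """
    if len(embeddings) != len(labels_list):
        raise ValueError("one label track per embedding required")
    landmark_sets = [
        extract_landmarks(e, l) for e, l in zip(embeddings, labels_list)
    ]
    stages0 = landmark_sets[0].stages
    for ls in landmark_sets:
        if ls.stages != stages0:
            raise ValueError("all subjects must share the same stage set")

    if not generalized:
        ref = landmark_sets[reference_subject]
        transforms = []
        for s, ls in enumerate(landmark_sets):
            if s == reference_subject:
                transforms.append(AlignmentTransform.identity(embeddings[s].dim))
            else:
                transforms.append(fit_alignment(ls, ref))
    else:
        current = [ls.points.copy() for ls in landmark_sets]
        transforms = [AlignmentTransform.identity(embeddings[0].dim)] * len(embeddings)
        prev_resid = np.inf
        for _ in range(max_iter):
            mean_pts = np.mean(current, axis=0)
            ref = LandmarkSet(points=mean_pts, stages=stages0)
            transforms = [fit_alignment(ls, ref) for ls in landmark_sets]
            current = [t.apply(ls.points) for t, ls in zip(transforms, landmark_sets)]
            resid = sum(t.residual for t in transforms)
            if abs(prev_resid - resid) < tol:
                break
            prev_resid = resid

    aligned = [apply_alignment(e, t) for e, t in zip(embeddings, transforms)]
    return aligned, transforms
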