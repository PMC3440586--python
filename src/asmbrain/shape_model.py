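"""Point-distribution model of brain-surface shape.

A brain surface is represented by an ordered set of corresponding landmarks
(546 by default).  Training surfaces are brought into a common frame by
generalized Procrustes analysis, and the residual variability is captured by
PCA of the flattened landmark vectors: a mean shape plus a handful of
orthonormal *modes* (eigenvectors of the landmark covariance).  New plausible
surfaces are synthesized as ``similarity(mean + P @ b)`` and arbitrary
landmark sets are projected back onto the model by alternating a similarity
fit with a linear least-squares solve for the mode coefficients ``b``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

DEFAULT_N_LANDMARKS = 546


class CorrespondenceError(ValueError):
    """Landmark sets do not share count/ordering."""


class RankError(ValueError):
    """Input geometry is degenerate or too few shapes for the requested modes."""


@dataclass
class LandmarkSet:
    """Ordered 3D surface landmarks in mm; order defines correspondence."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (L, 3), got {self.points.shape}")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return self.points.shape[0]

    def flatten(self) -> np.ndarray:
        return self.points.reshape(-1)

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class ShapeParams:
    """Mode coefficients plus the similarity transform applied after synthesis."""

    b: np.ndarray
    scale: float = 1.0
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    residual: float | None = None  # sum of squared point distances at projection

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=np.float64).reshape(-1)
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if self.scale <= 0:
            raise ValueError("scale must be positive")


@dataclass
class ShapeModel:
    """Mean shape + top-K PCA modes of aligned landmark variation."""

    mean: np.ndarray              # (3L,) flattened mean shape
    modes: np.ndarray             # (K, 3L) orthonormal rows
    eigenvalues: np.ndarray       # (K,) non-increasing, >= 0
    n_training: int
    frame: dict = field(default_factory=dict)
    all_eigenvalues: np.ndarray | None = None  # full spectrum, for diagnostics
    n_theta: int | None = None    # ring layout (points per sagittal ring), if any

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64).reshape(-1)
        self.modes = np.atleast_2d(np.asarray(self.modes, dtype=np.float64))
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=np.float64).reshape(-1)
        self.validate()

    # invariants -----------------------------------------------------------
    def validate(self) -> None:
        K = self.modes.shape[0]
        if self.modes.shape[1] != self.mean.size:
            raise ValueError("mode dimension does not match mean shape")
        if self.eigenvalues.size != K:
            raise ValueError("eigenvalue count does not match mode count")
        gram = self.modes @ self.modes.T
        if not np.allclose(gram, np.eye(K), atol=1e-8):
            raise ValueError("modes are not orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-12) or np.any(self.eigenvalues < -1e-12):
            raise ValueError("eigenvalues must be non-increasing and non-negative")
        if K > self.n_training - 1:
            raise RankError("more modes than training shapes - 1")

    @property
    def n_landmarks(self) -> int:
        return self.mean.size // 3

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]

    @property
    def mean_shape(self) -> LandmarkSet:
        return LandmarkSet(self.mean.reshape(-1, 3))

    # persistence ----------------------------------------------------------
    def save(self, path: str) -> None:
        meta = dict(self.frame)
        meta["n_training"] = self.n_training
        meta["n_theta"] = self.n_theta
        np.savez(
            path,
            mean=self.mean,
            modes=self.modes,
            eigenvalues=self.eigenvalues,
            all_eigenvalues=self.all_eigenvalues
            if self.all_eigenvalues is not None
            else np.empty(0),
            meta=np.array(json.dumps(meta)),
        )

    @classmethod
    def load(cls, path: str) -> "ShapeModel":
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["meta"]))
            n_training = int(meta.pop("n_training"))
            n_theta = meta.pop("n_theta", None)
            all_ev = npz["all_eigenvalues"]
            return cls(
                mean=npz["mean"],
                modes=npz["modes"],
                eigenvalues=npz["eigenvalues"],
                n_training=n_training,
                frame=meta,
                all_eigenvalues=all_ev if all_ev.size else None,
                n_theta=int(n_theta) if n_theta is not None else None,
            )


# ---------------------------------------------------------------------------
# similarity (Procrustes) superimposition


def similarity_fit(
    source: np.ndarray,
    target: np.ndarray,
    weights: np.ndarray | None = None,
    with_scaling: bool = True,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Weighted least-squares similarity ``x -> s R x + t`` mapping source onto target.

    Returns ``(s, R, t)``; R is a proper rotation (Kabsch/Umeyama solution).
    """
    X = np.asarray(source, dtype=np.float64)
    Y = np.asarray(target, dtype=np.float64)
    if X.shape != Y.shape:
        raise CorrespondenceError(f"shape mismatch {X.shape} vs {Y.shape}")
    if weights is None:
        w = np.full(len(X), 1.0 / len(X))
    else:
        w = np.asarray(weights, dtype=np.float64)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    mu_x = w @ X
    mu_y = w @ Y
    Xc = X - mu_x
    Yc = Y - mu_y
    cov = (Xc * w[:, None]).T @ Yc
    U, S, Vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.ones(3)
    D[-1] = d
    R = Vt.T @ (D[:, None] * U.T)
    var_x = float(np.sum(w * np.einsum("ij,ij->i", Xc, Xc)))
    if var_x <= 0:
        raise RankError("degenerate source shape (zero spread)")
    s = float((S * D).sum() / var_x) if with_scaling else 1.0
    if s <= 0:
        raise RankError("degenerate similarity fit (non-positive scale)")
    t = mu_y - s * (R @ mu_x)
    return s, R, t


def apply_similarity(points: np.ndarray, s: float, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return s * points @ R.T + t


# ---------------------------------------------------------------------------
# operations


def _as_point_arrays(shapes: Sequence[LandmarkSet | np.ndarray]) -> list[np.ndarray]:
    arrays = []
    for s in shapes:
        pts = s.points if isinstance(s, LandmarkSet) else np.asarray(s, dtype=np.float64)
        arrays.append(pts)
    L = arrays[0].shape[0]
    for pts in arrays:
        if pts.shape != (L, 3):
            raise CorrespondenceError("landmark sets differ in count or dimensionality")
    return arrays


def align_shapes(
    shapes: Sequence[LandmarkSet | np.ndarray],
    with_scaling: bool = True,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[list[LandmarkSet], dict]:
    """Generalized Procrustes alignment to a common frame.

    Shapes are centred, optionally scaled to the group-mean centroid size (so
    coordinates stay in mm), and iteratively rotated onto the evolving mean
    until the mean point displacement between consecutive means drops below
    ``tol`` mm.  Returns the aligned shapes and a frame record.
    """
    arrays = _as_point_arrays(shapes)
    if len(arrays) < 2:
        raise ValueError("need at least two shapes to align")
    for pts in arrays:
        if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-9) < 2:
            raise RankError("degenerate shape: landmarks are collinear")

    sizes = [np.linalg.norm(pts - pts.mean(axis=0)) for pts in arrays]
    target_size = float(np.mean(sizes))
    aligned = [pts - pts.mean(axis=0) for pts in arrays]

    # the overall scale is pinned by the initial mean, so that re-aligning an
    # already-aligned set is a no-op (the group superimposition is a fixed point)
    mean = np.mean(aligned, axis=0)
    mean -= mean.mean(axis=0)
    # pin the mean's centroid size to its initial value: without this the
    # per-shape scale fits shrink the ensemble a little every iteration
    pinned_norm = float(np.linalg.norm(mean))
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for i, pts in enumerate(aligned):
            s, R, t = similarity_fit(pts, mean, with_scaling=with_scaling)
            aligned[i] = apply_similarity(pts, s, R, t)
        new_mean = np.mean(aligned, axis=0)
        new_mean -= new_mean.mean(axis=0)
        if with_scaling:
            new_mean *= pinned_norm / np.linalg.norm(new_mean)
        movement = float(np.linalg.norm(new_mean - mean, axis=1).mean())
        mean = new_mean
        if movement < tol:
            break

    frame = {
        "with_scaling": with_scaling,
        "target_centroid_size": target_size,
        "gpa_iterations": n_iter,
        "tolerance_mm": tol,
    }
    return [LandmarkSet(a) for a in aligned], frame


def build_shape_model(
    aligned: Sequence[LandmarkSet | np.ndarray],
    n_modes: int,
    frame: dict | None = None,
    n_theta: int | None = None,
) -> ShapeModel:
    """PCA of aligned landmark vectors: top ``n_modes`` eigenmodes of the
    sample covariance (``n - 1`` denominator)."""
    arrays = _as_point_arrays(aligned)
    n = len(arrays)
    if n < 2:
        raise ValueError("need at least two aligned shapes")
    if n_modes < 1 or n_modes > n - 1:
        raise RankError(f"n_modes={n_modes} must be in [1, n_training - 1 = {n - 1}]")
    X = np.stack([pts.reshape(-1) for pts in arrays])
    mean = X.mean(axis=0)
    Xc = X - mean
    # economy SVD: eigenvalues of cov = singular values^2 / (n - 1)
    _, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    all_eigenvalues = S**2 / (n - 1)
    modes = Vt[:n_modes].copy()
    # sign convention: largest-magnitude component of each mode is positive
    for k in range(n_modes):
        j = int(np.argmax(np.abs(modes[k])))
        if modes[k, j] < 0:
            modes[k] *= -1
    return ShapeModel(
        mean=mean,
        modes=modes,
        eigenvalues=all_eigenvalues[:n_modes],
        n_training=n,
        frame=dict(frame or {}),
        all_eigenvalues=all_eigenvalues,
        n_theta=n_theta,
    )


def synthesize_shape(model: ShapeModel, params: ShapeParams) -> LandmarkSet:
    """``similarity(mean + P @ b)``; with b = 0 and identity similarity this
    is exactly the mean shape."""
    if params.b.size != model.n_modes:
        raise ValueError(f"expected {model.n_modes} mode coefficients, got {params.b.size}")
    pts = (model.mean + model.modes.T @ params.b).reshape(-1, 3)
    return LandmarkSet(apply_similarity(pts, params.scale, params.rotation, params.translation))


def clamp_coefficients(b: np.ndarray, eigenvalues: np.ndarray, m: float) -> np.ndarray:
    """Limit each coefficient to ``m`` standard deviations of its mode."""
    bound = m * np.sqrt(np.maximum(eigenvalues, 0.0))
    return np.clip(b, -bound, bound)


def project_shape(
    model: ShapeModel,
    landmarks: LandmarkSet | np.ndarray,
    weights: np.ndarray | None = None,
    clamp_m: float | None = None,
    allow_similarity: bool = True,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> ShapeParams:
    """Find the similarity transform + mode coefficients that best explain a
    landmark set, by alternating a weighted Procrustes fit with a linear
    solve for ``b``.  The returned ``residual`` is the (weighted) sum of
    squared point distances."""
    Y = landmarks.points if isinstance(landmarks, LandmarkSet) else np.asarray(landmarks, float)
    if Y.shape[0] != model.n_landmarks:
        raise CorrespondenceError(
            f"model has {model.n_landmarks} landmarks, input has {Y.shape[0]}"
        )
    P = model.modes  # (K, 3L)
    mean = model.mean
    K = model.n_modes
    b = np.zeros(K)
    s, R, t = 1.0, np.eye(3), np.zeros(3)

    if weights is not None:
        w_pts = np.asarray(weights, dtype=np.float64)
        w_coords = np.repeat(w_pts, 3)
    else:
        w_pts = None
        w_coords = None

    prev = None
    for _ in range(max_iter):
        synth = (mean + P.T @ b).reshape(-1, 3)
        if allow_similarity:
            s, R, t = similarity_fit(synth, Y, weights=w_pts)
        # pull target into the model frame: x = R^T (y - t) / s
        Ym = ((Y - t) @ R) / s
        d = Ym.reshape(-1) - mean
        if w_coords is None:
            b = P @ d
        else:
            A = (P * w_coords) @ P.T
            b = np.linalg.solve(A, (P * w_coords) @ d)
        if clamp_m is not None:
            b = clamp_coefficients(b, model.eigenvalues, clamp_m)
        state = np.concatenate([b, [s], R.reshape(-1), t])
        if prev is not None and np.max(np.abs(state - prev)) < tol:
            break
        prev = state

    fitted = apply_similarity((mean + P.T @ b).reshape(-1, 3), s, R, t)
    sq = np.einsum("ij,ij->i", fitted - Y, fitted - Y)
    residual = float(np.sum(sq if w_pts is None else w_pts * sq))
    return ShapeParams(b=b, scale=s, rotation=R, translation=t, residual=residual)
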