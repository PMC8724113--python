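"""Point-distribution (active shape) model core.

A shape is a flat vector of corresponded landmark coordinates
``(x1, y1, z1, ..., xn, yn, zn)`` (3D), ``(x1, z1, ...)`` (2D) or plain
samples (1D, used for vessel intensity profiles).  Training shapes are
brought into a common frame by generalized Procrustes alignment, a PCA
model ``X ≈ x̄ + P·b`` is learned from the aligned cloud, and new shapes
are generated by sampling the mode coefficients ``b``.  In the normal
(3D) pipeline each ``b_i`` is limited to ``±3·sqrt(σ_i)`` so that sampled
anatomy stays close to the training population; the abnormal (DME)
pipeline removes that limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ShapeVector",
    "PointDistributionModel",
    "ModeCoefficients",
    "SimilarityTransform",
    "ShapeModelError",
    "DimensionError",
    "DegenerateShapeError",
    "InsufficientDataError",
    "align_shapes",
    "build_pdm",
    "sample_shape",
    "random_coefficients",
    "project_shape",
    "save_pdm",
    "load_pdm",
]


class ShapeModelError(ValueError):
    """Base class for shape-model failures."""


class DimensionError(ShapeModelError):
    """Landmark counts, dimensions or coefficient lengths do not match."""


class DegenerateShapeError(ShapeModelError):
    """All landmarks of a shape coincide; no similarity transform exists."""


class InsufficientDataError(ShapeModelError):
    """Fewer training shapes than the operation requires."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ShapeVector:
    """Flattened landmark cloud, landmark-major: (x, y, z) per landmark."""

    coords: np.ndarray
    n_landmarks: int
    dim: int

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float).ravel()
        object.__setattr__(self, "coords", coords)
        if self.dim not in (1, 2, 3):
            raise DimensionError(f"dim must be 1, 2 or 3, got {self.dim}")
        if self.n_landmarks <= 0:
            raise DimensionError("n_landmarks must be positive")
        if coords.size != self.dim * self.n_landmarks:
            raise DimensionError(
                f"coords length {coords.size} != dim*n_landmarks "
                f"{self.dim * self.n_landmarks}"
            )
        if not np.all(np.isfinite(coords)):
            raise ShapeModelError("shape coordinates must be finite")

    @property
    def points(self) -> np.ndarray:
        """Landmarks as an (n_landmarks, dim) array."""
        return self.coords.reshape(self.n_landmarks, self.dim)

    @classmethod
    def from_points(cls, points: np.ndarray) -> "ShapeVector":
        points = np.asarray(points, dtype=float)
        if points.ndim == 1:
            points = points[:, None]
        n, dim = points.shape
        return cls(coords=points.ravel(), n_landmarks=n, dim=dim)


@dataclass(frozen=True)
class SimilarityTransform:
    """x ↦ scale · rotation @ x + translation."""

    rotation: np.ndarray
    scale: float
    translation: np.ndarray

    def __post_init__(self):
        R = np.atleast_2d(np.asarray(self.rotation, dtype=float))
        t = np.atleast_1d(np.asarray(self.translation, dtype=float))
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if self.scale <= 0:
            raise ShapeModelError("scale must be positive")
        if not np.allclose(R.T @ R, np.eye(R.shape[0]), atol=1e-8):
            raise ShapeModelError("rotation must be orthogonal")
        if np.linalg.det(R) < 0:
            raise ShapeModelError("rotation must be proper (det=+1)")

    def apply(self, shape: ShapeVector) -> ShapeVector:
        pts = self.scale * shape.points @ self.rotation.T + self.translation
        return ShapeVector.from_points(pts)

    @classmethod
    def identity(cls, dim: int) -> "SimilarityTransform":
        return cls(rotation=np.eye(dim), scale=1.0, translation=np.zeros(dim))


@dataclass(frozen=True)
class PointDistributionModel:
    """Learned linear shape model: mean, orthonormal modes, mode variances.

    ``variances`` are the PCA eigenvalues σ_i of the 1/N-normalized training
    covariance; ``total_variance`` is their sum before truncation.
    """

    mean: ShapeVector
    modes: np.ndarray  # (t, D) orthonormal rows
    variances: np.ndarray  # (t,) descending
    total_variance: float
    n_training: int
    dim: int
    variance_fraction: float = 0.94

    def __post_init__(self):
        modes = np.atleast_2d(np.asarray(self.modes, dtype=float))
        var = np.atleast_1d(np.asarray(self.variances, dtype=float))
        object.__setattr__(self, "modes", modes)
        object.__setattr__(self, "variances", var)
        D = self.mean.coords.size
        if modes.shape[1] != D:
            raise DimensionError("mode length does not match mean shape")
        if modes.shape[0] != var.size:
            raise DimensionError("one variance per mode required")
        if np.any(var < -1e-12):
            raise ShapeModelError("variances must be non-negative")
        if np.any(np.diff(var) > 1e-12):
            raise ShapeModelError("variances must be sorted descending")
        G = modes @ modes.T
        if not np.allclose(G, np.eye(modes.shape[0]), atol=1e-8):
            raise ShapeModelError("modes must be orthonormal")
        if self.total_variance + 1e-9 < float(var.sum()):
            raise ShapeModelError("total_variance below retained variance")

    @property
    def t(self) -> int:
        """Number of retained modes."""
        return self.modes.shape[0]


@dataclass(frozen=True)
class ModeCoefficients:
    """Weights b on the retained shape modes."""

    b: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "b", np.atleast_1d(np.asarray(self.b, dtype=float)))


# --------------------------------------------------------------------------
# alignment
# --------------------------------------------------------------------------


def _procrustes_pair(source: np.ndarray, target: np.ndarray) -> SimilarityTransform:
    """Similarity transform minimizing ||s·R·source + t − target||²."""
    mu_s = source.mean(axis=0)
    mu_t = target.mean(axis=0)
    A = source - mu_s
    B = target - mu_t
    norm_a = np.linalg.norm(A)
    if norm_a < 1e-12:
        raise DegenerateShapeError("all landmarks coincide; cannot align")
    M = B.T @ A
    U, s, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.ones(len(s))
    D[-1] = d
    R = U @ np.diag(D) @ Vt
    scale = float((s * D).sum()) / float(norm_a**2)
    if scale <= 0:
        scale = 1e-12
    t = mu_t - scale * R @ mu_s
    return SimilarityTransform(rotation=R, scale=scale, translation=t)


def align_shapes(
    shapes: list[ShapeVector],
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[list[ShapeVector], list[SimilarityTransform]]:
    """Generalized Procrustes alignment (rotation + translation + scale).

    The reference starts as the first shape and is replaced by the iterated
    mean; iteration stops when the mean shape moves by less than ``tol``
    (Frobenius) or after ``max_iter`` rounds.  Returns the aligned shapes
    and the similarity transform taking each *original* shape into the
    common frame.
    """
    if len(shapes) < 2:
        raise InsufficientDataError("alignment needs at least two shapes")
    n = shapes[0].n_landmarks
    dim = shapes[0].dim
    for s in shapes:
        if s.n_landmarks != n or s.dim != dim:
            raise DimensionError("all shapes must share landmark count and dim")

    originals = [s.points for s in shapes]
    reference = originals[0].copy()
    transforms = [SimilarityTransform.identity(dim) for _ in shapes]
    aligned = [p.copy() for p in originals]
    for _ in range(max_iter):
        transforms = [_procrustes_pair(p, reference) for p in originals]
        aligned = [
            tr.scale * p @ tr.rotation.T + tr.translation
            for p, tr in zip(originals, transforms)
        ]
        new_reference = np.mean(aligned, axis=0)
        shift = np.linalg.norm(new_reference - reference)
        reference = new_reference
        if shift < tol:
            break
    return [ShapeVector.from_points(p) for p in aligned], transforms


# --------------------------------------------------------------------------
# model building
# --------------------------------------------------------------------------


def build_pdm(
    aligned: list[ShapeVector],
    variance_fraction: float = 0.94,
) -> PointDistributionModel:
    """Learn mean and principal modes from aligned shapes.

    The covariance uses the 1/N normalization
    ``S = (1/N) Σ (x̄−x_i)(x̄−x_i)ᵀ``; eigenpairs are obtained from the
    SVD of the centred data matrix (identical to eigendecomposing S).
    The mode count t is the smallest number of leading components whose
    cumulative eigenvalue share reaches ``variance_fraction``, capped at
    min(N−1, D).
    """
    if not 0 < variance_fraction <= 1:
        raise ShapeModelError("variance_fraction must lie in (0, 1]")
    if len(aligned) < 2:
        raise InsufficientDataError("PDM needs at least two training shapes")
    n = aligned[0].n_landmarks
    dim = aligned[0].dim
    for s in aligned:
        if s.n_landmarks != n or s.dim != dim:
            raise DimensionError("all shapes must share landmark count and dim")

    X = np.stack([s.coords for s in aligned])  # (N, D)
    N, D = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    # dual eigendecomposition: sing. values of Xc give eigenvalues s²/N of S
    U, sing, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = sing**2 / N
    total = float(eigvals.sum())

    max_t = max(1, min(N - 1, D))
    if total <= 1e-30:
        # identical training shapes: keep one zero-variance mode by convention
        t = 1
        modes = Vt[:1].copy()
        eig_t = np.zeros(1)
    else:
        share = np.cumsum(eigvals) / total
        t = int(np.searchsorted(share, variance_fraction - 1e-12) + 1)
        t = min(t, max_t)
        modes = Vt[:t].copy()
        eig_t = eigvals[:t].copy()

    # sign convention: first component of each mode above tolerance is positive
    for i in range(modes.shape[0]):
        nz = np.nonzero(np.abs(modes[i]) > 1e-12)[0]
        if nz.size and modes[i, nz[0]] < 0:
            modes[i] = -modes[i]

    return PointDistributionModel(
        mean=ShapeVector(coords=mean, n_landmarks=n, dim=dim),
        modes=modes,
        variances=eig_t,
        total_variance=total,
        n_training=N,
        dim=dim,
        variance_fraction=variance_fraction,
    )


# --------------------------------------------------------------------------
# sampling and inversion
# --------------------------------------------------------------------------


def sample_shape(
    model: PointDistributionModel,
    b: ModeCoefficients | np.ndarray,
    constrained: bool = True,
) -> ShapeVector:
    """Generate a shape ``x̄ + P·b``.

    With ``constrained=True`` each coefficient is clipped to ``±3·sqrt(σ_i)``
    (a warning records any clipping); unconstrained mode (DME) passes b
    through unchanged.
    """
    vec = b.b if isinstance(b, ModeCoefficients) else np.atleast_1d(np.asarray(b, float))
    if vec.size != model.t:
        raise DimensionError(f"expected {model.t} coefficients, got {vec.size}")
    if constrained:
        limit = 3.0 * np.sqrt(model.variances)
        clipped = np.clip(vec, -limit, limit)
        if not np.array_equal(clipped, vec):
            warnings.warn(
                "mode coefficients outside ±3·sqrt(σ) were clipped",
                stacklevel=2,
            )
        vec = clipped
    coords = model.mean.coords + model.modes.T @ vec
    return ShapeVector(coords=coords, n_landmarks=model.mean.n_landmarks, dim=model.dim)


def random_coefficients(
    model: PointDistributionModel,
    rng: np.random.Generator | int,
    constrained: bool = True,
) -> ModeCoefficients:
    """Draw b_i ~ Normal(0, σ_i) independently per mode.

    Constrained draws are redrawn (per-mode rejection) until every b_i lies
    within ±3·sqrt(σ_i), preserving the truncated-Gaussian shape.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    std = np.sqrt(model.variances)
    b = rng.normal(0.0, 1.0, size=model.t) * std
    if constrained:
        limit = 3.0 * std
        bad = np.abs(b) > limit
        while np.any(bad):
            b[bad] = rng.normal(0.0, 1.0, size=int(bad.sum())) * std[bad]
            bad = np.abs(b) > limit
    return ModeCoefficients(b=b)


def project_shape(
    model: PointDistributionModel, x: ShapeVector
) -> ModeCoefficients:
    """Least-squares mode coefficients ``b = Pᵀ(x − x̄)`` for a shape in the
    model frame."""
    if x.coords.size != model.mean.coords.size:
        raise DimensionError("shape length does not match model")
    return ModeCoefficients(b=model.modes @ (x.coords - model.mean.coords))


# --------------------------------------------------------------------------
# persistence: JSON header + .npz sidecar for the mode matrix
# --------------------------------------------------------------------------


def save_pdm(model: PointDistributionModel, path: str | Path, provenance: dict | None = None) -> None:
    import json

    path = Path(path)
    sidecar = path.with_suffix(".npz")
    np.savez(sidecar, modes=model.modes, mean=model.mean.coords)
    header = {
        "dim": model.dim,
        "n_landmarks": model.mean.n_landmarks,
        "n_training": model.n_training,
        "variances": model.variances.tolist(),
        "total_variance": model.total_variance,
        "variance_fraction": model.variance_fraction,
        "sidecar": sidecar.name,
        "provenance": provenance or {},
    }
    path.write_text(json.dumps(header, indent=2))


def load_pdm(path: str | Path) -> PointDistributionModel:
    import json

    path = Path(path)
    header = json.loads(path.read_text())
    arrays = np.load(path.parent / header["sidecar"])
    return PointDistributionModel(
        mean=ShapeVector(
            coords=arrays["mean"],
            n_landmarks=header["n_landmarks"],
            dim=header["dim"],
        ),
        modes=arrays["modes"],
        variances=np.asarray(header["variances"]),
        total_variance=header["total_variance"],
        n_training=header["n_training"],
        dim=header["dim"],
        variance_fraction=header.get("variance_fraction", 0.94),
    )
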