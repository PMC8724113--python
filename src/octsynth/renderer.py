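"""Rendering a sampled surface set into an intensity volume.

Layers between consecutive boundaries are filled with mean brightnesses
estimated from a (seeded) random fraction of training B-scans; the choroid
and vitreous background are composited per A-scan from a reference volume;
multiplicative speckle is added at a configurable level.  Intensities are
float in [0, 1] throughout; quantization happens only on export.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .landmarking import SurfaceSet

__all__ = [
    "OCTVolume",
    "LayerAppearance",
    "RenderError",
    "estimate_appearance",
    "render_layers",
    "composite_background",
    "add_speckle",
    "speckle_noise",
]


class RenderError(ValueError):
    pass


@dataclass
class OCTVolume:
    """B × H × W intensity stack in [0, 1] with voxel spacing metadata."""

    intensities: np.ndarray
    spacing: tuple[float, float, float] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 3:
            raise RenderError("intensities must be a (B, H, W) array")
        if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
            raise RenderError("intensities must lie in [0, 1]")
        self.intensities = np.clip(arr, 0.0, 1.0)

    @property
    def n_bscans(self) -> int:
        return self.intensities.shape[0]

    @property
    def height(self) -> int:
        return self.intensities.shape[1]

    @property
    def width(self) -> int:
        return self.intensities.shape[2]


@dataclass
class LayerAppearance:
    """Per-layer mean brightness μ_k for the K−1 retinal layers."""

    layer_brightness: np.ndarray
    reference_id: str = ""
    selected_bscans: tuple = ()

    def __post_init__(self):
        mu = np.asarray(self.layer_brightness, dtype=float)
        if np.any(mu < 0) or np.any(mu > 1):
            raise RenderError("layer brightness must lie in [0, 1]")
        self.layer_brightness = mu


def _layer_masks(surfaces: SurfaceSet, height: int) -> np.ndarray:
    """Boolean masks (K-1, B, H, W); voxel on a boundary belongs to the
    layer below it (half-open [z_k, z_{k+1}))."""
    z = surfaces.surfaces  # (K, B, W)
    rows = np.arange(height)[None, :, None]  # (1, H, 1)
    masks = []
    for k in range(surfaces.n_surfaces - 1):
        lo = z[k][:, None, :]  # (B, 1, W)
        hi = z[k + 1][:, None, :]
        masks.append((rows >= lo) & (rows < hi))
    return np.stack(masks)


def estimate_appearance(
    training_volumes: list[OCTVolume],
    training_surfaces: list[SurfaceSet],
    fraction: float = 0.5,
    rng: np.random.Generator | int = 0,
) -> LayerAppearance:
    """Average per-layer brightness over a random subset of training B-scans.

    ``ceil(fraction × total B-scans)`` B-scans are drawn without replacement
    (seeded), pooling across volumes; μ_k is the mean intensity of voxels
    between surfaces k and k+1 over the selection.  B-scans where a layer is
    empty simply contribute no voxels; a layer empty everywhere is an error.
    """
    if not 0 < fraction <= 1:
        raise RenderError("fraction must lie in (0, 1]")
    if len(training_volumes) != len(training_surfaces) or not training_volumes:
        raise RenderError("need matching, non-empty volume/surface lists")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    index = [
        (vi, b)
        for vi, vol in enumerate(training_volumes)
        for b in range(vol.n_bscans)
    ]
    n_select = math.ceil(fraction * len(index))
    chosen = rng.choice(len(index), size=n_select, replace=False)
    chosen_pairs = [index[i] for i in sorted(chosen)]

    K = training_surfaces[0].n_surfaces
    sums = np.zeros(K - 1)
    counts = np.zeros(K - 1)
    for vi, b in chosen_pairs:
        vol = training_volumes[vi]
        surf = training_surfaces[vi]
        rows = np.arange(vol.height)[:, None]
        for k in range(K - 1):
            lo = surf.surfaces[k, b][None, :]
            hi = surf.surfaces[k + 1, b][None, :]
            mask = (rows >= lo) & (rows < hi)
            sums[k] += vol.intensities[b][mask].sum()
            counts[k] += mask.sum()
    if np.any(counts == 0):
        empty = np.nonzero(counts == 0)[0] + 1
        raise RenderError(f"layer(s) {empty.tolist()} empty in every selected B-scan")
    return LayerAppearance(
        layer_brightness=sums / counts,
        selected_bscans=tuple(chosen_pairs),
    )


def render_layers(surfaces: SurfaceSet, appearance: LayerAppearance) -> OCTVolume:
    """Noise-free volume with voxels between surfaces k, k+1 set to μ_k;
    vitreous (above surface 1) and sub-retinal space stay 0 for later
    compositing."""
    mu = appearance.layer_brightness
    if mu.size != surfaces.n_surfaces - 1:
        raise RenderError(
            f"appearance has {mu.size} layers, surfaces define "
            f"{surfaces.n_surfaces - 1}"
        )
    H = surfaces.axial_depth
    vol = np.zeros((surfaces.n_bscans, H, surfaces.width))
    masks = _layer_masks(surfaces, H)
    for k in range(mu.size):
        vol[masks[k]] = mu[k]
    return OCTVolume(intensities=vol, spacing=surfaces.spacing)


def _resample_column(values: np.ndarray, new_len: int) -> np.ndarray:
    """Axially resample a 1D intensity segment to a new length (linear)."""
    if new_len <= 0:
        return np.empty(0)
    if values.size == 0:
        return np.zeros(new_len)
    if values.size == 1:
        return np.full(new_len, values[0])
    src = np.linspace(0.0, values.size - 1, new_len)
    return np.interp(src, np.arange(values.size), values)


def composite_background(
    volume: OCTVolume,
    surfaces: SurfaceSet,
    reference: OCTVolume | None,
    reference_surfaces: SurfaceSet | None,
) -> OCTVolume:
    """Fill vitreous and choroid from a reference volume, per A-scan.

    Voxels above surface 1 come from the reference's above-ILM band and
    voxels below surface K from its below-BM band, each axially resampled
    to the target extents.  Retinal voxels are untouched.
    """
    if reference is None or reference_surfaces is None:
        warnings.warn("no reference volume; background left unfilled", stacklevel=2)
        return volume

    B, H, W = volume.intensities.shape
    out = volume.intensities.copy()
    ref = reference.intensities
    rB, rH, rW = ref.shape
    for b in range(B):
        rb = min(b * rB // B, rB - 1) if rB != B else b
        for x in range(W):
            rx = min(x * rW // W, rW - 1) if rW != W else x
            # vitreous band
            top = int(np.ceil(surfaces.surfaces[0, b, x]))
            rtop = int(np.ceil(reference_surfaces.surfaces[0, rb, rx]))
            out[b, :top, x] = _resample_column(ref[rb, :rtop, rx], top)
            # choroid + deep background band
            bot = int(np.ceil(surfaces.surfaces[-1, b, x]))
            rbot = int(np.ceil(reference_surfaces.surfaces[-1, rb, rx]))
            out[b, bot:, x] = _resample_column(ref[rb, rbot:, rx], H - bot)
    return OCTVolume(
        intensities=np.clip(out, 0, 1),
        spacing=volume.spacing,
        provenance=dict(volume.provenance),
    )


def speckle_noise(
    image: np.ndarray, sigma: float, rng: np.random.Generator | int
) -> np.ndarray:
    """Multiplicative Gaussian speckle surrogate: clip(I·(1+η), 0, 1) with
    η iid Normal(0, σ²).  Works on arrays of any shape."""
    if sigma < 0:
        raise RenderError("speckle sigma must be non-negative")
    if sigma == 0:
        return np.asarray(image, dtype=float).copy()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    eta = rng.normal(0.0, sigma, size=np.shape(image))
    return np.clip(np.asarray(image, dtype=float) * (1.0 + eta), 0.0, 1.0)


def add_speckle(
    volume: OCTVolume, sigma: float, rng: np.random.Generator | int
) -> OCTVolume:
    noisy = speckle_noise(volume.intensities, sigma, rng)
    prov = dict(volume.provenance)
    prov["noise_sigma"] = sigma
    return OCTVolume(intensities=noisy, spacing=volume.spacing, provenance=prov)
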