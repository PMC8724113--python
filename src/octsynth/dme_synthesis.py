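"""Abnormal-mode (diabetic macular edema) B-scan synthesis.

DME distorts retinal boundaries far beyond the healthy range, so the 2D
shape model here samples its mode coefficients *unconstrained* — the
±3·sqrt(σ) plausibility limit of the normal pipeline is removed.  Image
content is not rendered from per-layer means: for each synthesized
boundary set the most similar training B-scan is found (mean-centred SSD
on the first boundary, the ILM) and its texture and intraretinal fluid
mask are transferred column-wise, each reference layer profile axially
resampled to the new layer's thickness.  The output is a fully labelled
scene: image, nine boundary curves (including the manually added
choroidal 9th) and a binary fluid mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .landmarking import (
    LandmarkGrid,
    extract_landmarks_2d,
    landmarks_to_curves_2d,
)
from .renderer import speckle_noise
from .shape_model import (
    InsufficientDataError,
    ModeCoefficients,
    PointDistributionModel,
    ShapeVector,
    build_pdm,
    random_coefficients,
    sample_shape,
)

__all__ = [
    "DMEReference",
    "ReferenceLibrary",
    "DMEScene",
    "build_dme_model",
    "match_reference",
    "transfer_texture",
    "transfer_fluid",
    "synthesize_dme",
]


@dataclass
class DMEReference:
    """One training B-scan: image, 9 boundary curves, binary fluid mask."""

    image: np.ndarray  # (H, W) in [0, 1]
    boundaries: np.ndarray  # (9, W) axial depth
    fluid_mask: np.ndarray  # (H, W) bool
    reference_id: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=float)
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        self.fluid_mask = np.asarray(self.fluid_mask, dtype=bool)
        if self.image.shape != self.fluid_mask.shape:
            raise ValueError("image and fluid mask shapes differ")
        if self.boundaries.shape[1] != self.image.shape[1]:
            raise ValueError("boundary width does not match image")

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]


@dataclass
class ReferenceLibrary:
    references: list[DMEReference]

    def __len__(self) -> int:
        return len(self.references)

    def __getitem__(self, i: int) -> DMEReference:
        return self.references[i]


@dataclass
class DMEScene:
    """Synthesized labelled DME B-scan."""

    image: np.ndarray
    boundaries: np.ndarray
    fluid_mask: np.ndarray
    provenance: dict = field(default_factory=dict)


def build_dme_model(
    library: ReferenceLibrary,
    points_per_curve: int = 51,
    variance_fraction: float = 0.94,
) -> tuple[PointDistributionModel, LandmarkGrid]:
    """2D PDM over 9 × points_per_curve boundary landmarks.

    References with an incomplete boundary set (NaNs) are excluded with a
    warning.  A single usable reference yields a degenerate model whose
    mean is that reference (one zero-variance mode), which still supports
    b = 0 synthesis.
    """
    shapes = []
    grid = None
    for i, ref in enumerate(library.references):
        if not np.all(np.isfinite(ref.boundaries)):
            warnings.warn(f"reference {i} has incomplete boundaries; excluded", stacklevel=2)
            continue
        vec, grid = extract_landmarks_2d(
            ref.boundaries, axial_depth=ref.height, points_per_curve=points_per_curve
        )
        shapes.append(vec)
    if not shapes:
        raise InsufficientDataError("no usable references in library")
    if len(shapes) == 1:
        sv = shapes[0]
        D = sv.coords.size
        mode = np.zeros(D)
        mode[0] = 1.0
        model = PointDistributionModel(
            mean=sv,
            modes=mode[None, :],
            variances=np.zeros(1),
            total_variance=0.0,
            n_training=1,
            dim=2,
            variance_fraction=variance_fraction,
        )
        return model, grid
    return build_pdm(shapes, variance_fraction=variance_fraction), grid


def match_reference(
    new_boundaries: np.ndarray, library: ReferenceLibrary
) -> int:
    """Index of the most similar reference: argmin of the mean squared
    difference between mean-centred first boundaries (ILM); ties go to the
    lowest index."""
    if len(library) == 0:
        raise InsufficientDataError("empty reference library")
    query = np.asarray(new_boundaries, dtype=float)[0]
    query = query - query.mean()
    best, best_cost = 0, np.inf
    for i, ref in enumerate(library.references):
        ilm = ref.boundaries[0]
        if ilm.size != query.size:
            src = np.linspace(0, ilm.size - 1, query.size)
            ilm = np.interp(src, np.arange(ilm.size), ilm)
        ilm = ilm - ilm.mean()
        cost = float(np.mean((ilm - query) ** 2))
        if cost < best_cost - 1e-15:
            best, best_cost = i, cost
    return best


def _band_edges(boundaries: np.ndarray, height: int, x: int) -> list[tuple[int, int]]:
    """Row extents of the K+1 axial bands at column x: vitreous, K−1 layers,
    sub-choroidal background (half-open row intervals)."""
    z = boundaries[:, x]
    edges = [0] + [int(np.ceil(v)) for v in z] + [height]
    edges = np.clip(edges, 0, height)
    return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def transfer_texture(
    new_boundaries: np.ndarray,
    reference: DMEReference,
    height: int | None = None,
) -> np.ndarray:
    """Column-wise texture transfer from the matched reference.

    Per column and per axial band (vitreous, each of the layers between
    consecutive boundaries, and the band below the last boundary) the
    reference's intensity profile is linearly resampled to the new band's
    thickness and written into the output.  Zero-thickness target bands
    are skipped; empty reference bands fall back to the nearest reference
    row value.
    """
    new_boundaries = np.asarray(new_boundaries, dtype=float)
    H = int(height or reference.height)
    W = new_boundaries.shape[1]
    out = np.zeros((H, W))
    for x in range(W):
        rx = x if x < reference.width else reference.width - 1
        tgt_bands = _band_edges(new_boundaries, H, x)
        ref_bands = _band_edges(reference.boundaries, reference.height, rx)
        for (t0, t1), (r0, r1) in zip(tgt_bands, ref_bands):
            if t1 <= t0:
                continue
            seg = reference.image[r0:r1, rx]
            if seg.size == 0:
                # degenerate reference band: borrow the nearest available row
                rr = min(max(r0, 0), reference.height - 1)
                out[t0:t1, x] = reference.image[rr, rx]
            elif seg.size == 1:
                out[t0:t1, x] = seg[0]
            else:
                pos = np.linspace(0.0, seg.size - 1, t1 - t0)
                out[t0:t1, x] = np.interp(pos, np.arange(seg.size), seg)
    return np.clip(out, 0.0, 1.0)


def transfer_fluid(
    new_boundaries: np.ndarray,
    reference: DMEReference,
    height: int | None = None,
) -> np.ndarray:
    """Column-wise fluid-mask transfer with the same per-column axial map as
    the texture transfer, nearest-neighbour for binary values."""
    new_boundaries = np.asarray(new_boundaries, dtype=float)
    H = int(height or reference.height)
    W = new_boundaries.shape[1]
    out = np.zeros((H, W), dtype=bool)
    for x in range(W):
        rx = x if x < reference.width else reference.width - 1
        tgt_bands = _band_edges(new_boundaries, H, x)
        ref_bands = _band_edges(reference.boundaries, reference.height, rx)
        for (t0, t1), (r0, r1) in zip(tgt_bands, ref_bands):
            if t1 <= t0 or r1 <= r0:
                continue
            seg = reference.fluid_mask[r0:r1, rx]
            if not seg.any():
                continue
            pos = np.linspace(0.0, seg.size - 1, t1 - t0)
            out[t0:t1, x] = seg[np.round(pos).astype(int)]
    return out


def synthesize_dme(
    model: PointDistributionModel,
    grid: LandmarkGrid,
    library: ReferenceLibrary,
    rng: np.random.Generator | int,
    noise_sigma: float = 0.0,
    b: np.ndarray | None = None,
) -> DMEScene:
    """Full abnormal-mode pipeline: unconstrained coefficient draw → shape →
    dense boundaries → reference matching → texture + fluid transfer →
    speckle.  ``b`` may be supplied explicitly (e.g. b = 0 for the mean)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if b is None:
        coeff = random_coefficients(model, rng, constrained=False)
    else:
        coeff = ModeCoefficients(b=np.asarray(b, dtype=float))
    shape = sample_shape(model, coeff, constrained=False)
    boundaries = landmarks_to_curves_2d(shape, grid)
    ref_idx = match_reference(boundaries, library)
    ref = library[ref_idx]
    image = transfer_texture(boundaries, ref, height=grid.axial_depth)
    mask = transfer_fluid(boundaries, ref, height=grid.axial_depth)
    if noise_sigma > 0:
        image = speckle_noise(image, noise_sigma, rng)
    # fluid can only exist inside the retina: clip to (boundary 1, boundary 8)
    rows = np.arange(image.shape[0])[:, None]
    inside = (rows > boundaries[0][None, :]) & (rows < boundaries[7][None, :])
    mask &= inside
    return DMEScene(
        image=image,
        boundaries=boundaries,
        fluid_mask=mask,
        provenance={
            "reference_id": ref.reference_id or str(ref_idx),
            "reference_index": ref_idx,
            "b": coeff.b.tolist(),
            "noise_sigma": noise_sigma,
        },
    )
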