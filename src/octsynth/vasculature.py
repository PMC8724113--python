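"""Synthetic retinal vasculature.

Vessels sit in the inner retina and cast axial shadows: columns under a
vessel brighten within the inner layers and darken from the vessel depth
down through the outer layers and choroid — the contrast that makes
vessels dark in outer-layer en-face projections and bright in inner-layer
ones.  The lateral intensity footprint of a vessel is modelled with a 1D
point-distribution model over training intensity-modulation profiles
(multiplicative factors, ≈1 at the window edges, a dip at the centre);
placements are generated from a seeded spatial model with cross-B-scan
continuity and a foveal avascular zone, since this package runs data-free
(real placements can be supplied instead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .landmarking import SurfaceSet, fovea_columns
from .renderer import OCTVolume
from .shape_model import (
    InsufficientDataError,
    PointDistributionModel,
    ShapeVector,
    build_pdm,
    random_coefficients,
    sample_shape,
)

__all__ = [
    "VesselProfile",
    "VesselPlacement",
    "PlacementError",
    "build_vessel_model",
    "sample_placements",
    "render_vessels",
]


class PlacementError(ValueError):
    pass


@dataclass(frozen=True)
class VesselProfile:
    """1D multiplicative intensity profile across a vessel window."""

    profile: np.ndarray
    center_column: int = 0

    def __post_init__(self):
        p = np.asarray(self.profile, dtype=float)
        object.__setattr__(self, "profile", p)
        if np.any(p <= 0):
            raise PlacementError("profile factors must be positive")
        if abs(p[0] - 1.0) > 0.05 or abs(p[-1] - 1.0) > 0.05:
            raise PlacementError("profile must approach 1 at window edges")

    @property
    def width(self) -> int:
        return self.profile.size


@dataclass
class VesselPlacement:
    """Per-B-scan vessel windows: list of (center_column, width) per B-scan,
    with an optional track id linking a vessel across adjacent B-scans."""

    windows: list[list[tuple[int, int]]]
    track_ids: list[list[int]] | None = None

    @property
    def n_bscans(self) -> int:
        return len(self.windows)

    def total(self) -> int:
        return sum(len(w) for w in self.windows)


def _resample_profile(profile: np.ndarray, width: int) -> np.ndarray:
    src = np.linspace(0, profile.size - 1, width)
    return np.interp(src, np.arange(profile.size), profile)


def build_vessel_model(
    training_profiles: list[VesselProfile],
    variance_fraction: float = 0.94,
) -> PointDistributionModel:
    """1D PDM over vessel intensity profiles (same PCA machinery as the
    boundary model; no Procrustes step — profiles share a fixed window)."""
    if len(training_profiles) < 2:
        raise InsufficientDataError("vessel model needs at least two profiles")
    widths = {p.width for p in training_profiles}
    target_w = max(widths)
    if len(widths) > 1:
        warnings.warn(
            f"mixed profile widths {sorted(widths)}; resampling to {target_w}",
            stacklevel=2,
        )
    shapes = [
        ShapeVector.from_points(_resample_profile(p.profile, target_w))
        for p in training_profiles
    ]
    return build_pdm(shapes, variance_fraction=variance_fraction)


def sample_placements(
    surfaces: SurfaceSet,
    n_vessels: int,
    rng: np.random.Generator | int,
    min_separation: int = 12,
    vessel_width: int = 9,
    fovea_column: float | None = None,
    foveal_radius: float = 30.0,
    max_jitter: int = 2,
) -> VesselPlacement:
    """Seeded vessel tracks: base columns avoid the foveal avascular zone and
    keep ``min_separation``; each track persists across B-scans with small
    lateral jitter, emulating vascular continuity."""
    if n_vessels < 0:
        raise PlacementError("n_vessels must be non-negative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    W, B = surfaces.width, surfaces.n_bscans
    if n_vessels == 0:
        return VesselPlacement(windows=[[] for _ in range(B)], track_ids=[[] for _ in range(B)])
    if fovea_column is None:
        fovea_column = fovea_columns(surfaces)

    margin = vessel_width // 2 + max_jitter + 1
    candidates = np.arange(margin, W - margin)
    candidates = candidates[np.abs(candidates - fovea_column) > foveal_radius + max_jitter]
    if candidates.size == 0:
        raise PlacementError("no admissible columns for vessel placement")

    bases: list[int] = []
    for _ in range(2000):
        if len(bases) == n_vessels:
            break
        c = int(rng.choice(candidates))
        if all(abs(c - b0) >= min_separation + 2 * max_jitter for b0 in bases):
            bases.append(c)
    if len(bases) < n_vessels:
        raise PlacementError(
            f"cannot place {n_vessels} vessels with separation {min_separation} "
            f"in width {W}"
        )

    windows: list[list[tuple[int, int]]] = []
    track_ids: list[list[int]] = []
    for _ in range(B):
        row: list[tuple[int, int]] = []
        ids: list[int] = []
        for tid, base in enumerate(bases):
            c = base + int(rng.integers(-max_jitter, max_jitter + 1))
            if abs(c - fovea_column) <= foveal_radius:
                c = base  # jitter may not enter the avascular zone
            row.append((c, vessel_width))
            ids.append(tid)
        windows.append(row)
        track_ids.append(ids)
    return VesselPlacement(windows=windows, track_ids=track_ids)


def render_vessels(
    volume: OCTVolume,
    surfaces: SurfaceSet,
    placements: VesselPlacement,
    vessel_model: PointDistributionModel,
    rng: np.random.Generator | int,
    vessel_surface: int = 2,
    bright_gain: float = 0.5,
) -> OCTVolume:
    """Apply sampled vessel profiles to the volume.

    Per placement a profile is drawn from the vessel PDM (constrained) and
    normalized so its edge baseline is exactly 1 — a multiplicative profile
    with unit baseline matches the host region's brightness by construction.
    Columns in the window brighten by ``1 + gain·(1 − d(x))`` between
    surface 1 and the vessel-bearing surface and attenuate by the dark
    profile ``d(x) < 1`` from the vessel depth downward.  Result clipped to
    [0, 1]; only voxels inside placement windows change.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = volume.intensities.copy()
    B, H, W = out.shape
    rows = np.arange(H)
    for b in range(min(placements.n_bscans, B)):
        for center, width in placements.windows[b]:
            half = width // 2
            lo, hi = center - half, center + half + 1
            if lo < 0 or hi > W:
                warnings.warn(
                    f"vessel window at column {center} falls outside image; skipped",
                    stacklevel=2,
                )
                continue
            coeff = random_coefficients(vessel_model, rng, constrained=True)
            prof = sample_shape(vessel_model, coeff, constrained=True).coords
            prof = _resample_profile(prof, hi - lo)
            edge = 0.5 * (prof[0] + prof[-1])
            if edge <= 0:
                continue
            dark = np.clip(prof / edge, 0.05, 1.0)
            bright = 1.0 + bright_gain * (1.0 - dark)
            for j, x in enumerate(range(lo, hi)):
                z_top = surfaces.surfaces[0, b, x]
                z_vessel = surfaces.surfaces[vessel_surface - 1, b, x]
                inner = (rows >= z_top) & (rows < z_vessel)
                outer = rows >= z_vessel
                out[b, inner, x] *= bright[j]
                out[b, outer, x] *= dark[j]
    prov = dict(volume.provenance)
    prov["n_vessels"] = placements.total()
    return OCTVolume(
        intensities=np.clip(out, 0, 1), spacing=volume.spacing, provenance=prov
    )
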