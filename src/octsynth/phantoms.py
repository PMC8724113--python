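"""Parametric phantom training data.

Every pipeline stage is testable without real scans: these generators
emit smooth non-crossing boundary surfaces with a foveal pit, layered
intensity volumes with a synthetic choroid and optional vessels, vessel
intensity profiles, and DME-style reference B-scans with ellipsoidal
fluid pockets.  The phantoms are analytic (Gaussian pit, low-order
polynomial perturbations) so ground truth is available in closed form.

Ordering of the surfaces is guaranteed by construction — layer
thicknesses are generated as positive fields and accumulated — and
verified by the SurfaceSet invariant on every output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landmarking import SurfaceSet
from .renderer import (
    LayerAppearance,
    OCTVolume,
    add_speckle,
    render_layers,
)
from .vasculature import (
    VesselPlacement,
    VesselProfile,
    build_vessel_model,
    render_vessels,
    sample_placements,
)
from .dme_synthesis import DMEReference, ReferenceLibrary

__all__ = [
    "PhantomConfig",
    "generate_surfaces",
    "generate_volume",
    "generate_vessel_profiles",
    "generate_dme_library",
]

# default per-layer mean brightness, inner → outer (8 layers between the
# 9 surfaces): bright NFL, darker nuclear layers, bright photoreceptor/RPE
DEFAULT_LAYER_BRIGHTNESS = (0.72, 0.50, 0.30, 0.48, 0.20, 0.42, 0.60, 0.85)


@dataclass
class PhantomConfig:
    """Geometry and variability of the phantom population.

    Defaults follow the Spectralis-style macular raster: 19 B-scans of
    512 × 496 voxels, nine boundary surfaces.  ``perturbation_amplitude``
    scales the smooth random fields (log-thickness units) that make
    volumes differ; ``pit_depth`` is the foveal depression of the ILM in
    voxels.
    """

    n_volumes: int = 20
    n_surfaces: int = 9
    n_bscans: int = 19
    width: int = 512
    height: int = 496
    # per-layer axial thickness in voxels at 3.87 µm/voxel, anchored to
    # normative macular anatomy (RNFL ≈ 30 µm, GCIPL ≈ 77 µm, RPE ≈ 55 µm,
    # total retina ≈ 310 µm ≈ 80 voxels)
    ilm_base: float = 150.0
    layer_thickness: tuple = (7.7, 19.8, 9.0, 7.5, 12.0, 5.0, 5.0, 14.3)
    pit_depth: float = 25.0
    pit_width_x: float = 60.0
    pit_width_b: float = 4.0
    perturbation_amplitude: float = 0.08
    base_jitter: float = 6.0
    layer_brightness: tuple = DEFAULT_LAYER_BRIGHTNESS
    noise_sigma: float = 0.0
    n_vessels: int = 0
    spacing: tuple = (11.6, 240.0, 3.87)  # µm/voxel (dx, dy, dz), Spectralis-like
    # DME mode
    n_fluid_pockets: tuple = (1, 3)
    fluid_layer: int = 5  # pockets centred in the layer between surfaces 5 and 6
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.n_volumes, self.n_surfaces, self.n_bscans, self.width, self.height) <= 0:
            raise ValueError("all phantom dimensions must be positive")
        if len(self.layer_thickness) != self.n_surfaces - 1:
            raise ValueError("need one thickness per layer (n_surfaces - 1)")

    @classmethod
    def scaled(cls, height: int = 496, width: int = 512, **kwargs) -> "PhantomConfig":
        """Config with depth/width-dependent parameters scaled from the
        default 512 × 496 geometry, so small phantoms keep realistic
        proportions."""
        sz = height / 496.0
        sx = width / 512.0
        defaults = dict(
            height=height,
            width=width,
            ilm_base=150.0 * sz,
            layer_thickness=tuple(t * sz for t in cls.layer_thickness),
            pit_depth=25.0 * sz,
            pit_width_x=60.0 * sx,
            base_jitter=6.0 * sz,
        )
        defaults.update(kwargs)
        return cls(**defaults)


def _smooth_field(rng: np.random.Generator, B: int, W: int, amplitude: float) -> np.ndarray:
    """Low-order 2D polynomial with seeded coefficients; zero-mean-ish,
    bounded by ~amplitude."""
    if amplitude == 0:
        return np.zeros((B, W))
    xn = np.linspace(-1, 1, W)[None, :]
    bn = np.linspace(-1, 1, max(B, 2))[:B, None]
    field_ = np.zeros((B, W))
    for i in range(3):
        for j in range(3):
            if i + j <= 2:
                field_ += rng.normal(0, amplitude / 3) * (xn**i) * (bn**j)
    return field_


def _pit_profile(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    x = np.arange(config.width)[None, :]
    b = np.arange(config.n_bscans)[:, None]
    # pit-centre/width jitter scales with the perturbation amplitude so a
    # zero-amplitude config produces identical volumes
    jitter = config.perturbation_amplitude / 0.08
    xf = config.width / 2 + rng.normal(0, config.width * 0.01) * jitter
    bf = (config.n_bscans - 1) / 2
    wx = config.pit_width_x * (1 + rng.normal(0, 0.05) * jitter)
    wb = config.pit_width_b
    return np.exp(-((x - xf) ** 2 / (2 * wx**2) + (b - bf) ** 2 / (2 * wb**2)))


def _single_surface_set(config: PhantomConfig, rng: np.random.Generator, vid: str) -> SurfaceSet:
    B, W, K = config.n_bscans, config.width, config.n_surfaces
    pit = _pit_profile(config, rng)
    # foveal thinning: inner layers collapse at the pit, outer layers barely;
    # scaled so the ILM pit depth matches config.pit_depth
    thinning = np.linspace(1.0, 0.0, K - 1) ** 1.5
    inner_total = sum(
        t * f for t, f in zip(config.layer_thickness, thinning)
    )
    thinning *= min(1.0, config.pit_depth / max(inner_total, 1e-9))

    thick = np.empty((K - 1, B, W))
    for k in range(K - 1):
        eps = _smooth_field(rng, B, W, config.perturbation_amplitude)
        t = config.layer_thickness[k] * np.exp(eps) * (1 - thinning[k] * pit)
        thick[k] = np.maximum(t, 0.5)

    # anchor on the outer surface (BM): smooth plane + gentle tilt, then
    # stack layer thicknesses upward; the ILM inherits the foveal pit from
    # the collapsed inner layers
    bm_base = (
        config.ilm_base
        + sum(config.layer_thickness)
        + rng.normal(0, config.base_jitter)
    )
    z = np.empty((K, B, W))
    z[K - 1] = bm_base + _smooth_field(rng, B, W, 50.0 * config.perturbation_amplitude)
    for k in range(K - 2, -1, -1):
        z[k] = z[k + 1] - thick[k]
    np.clip(z, 0, config.height - 1e-6, out=z)
    z = np.maximum.accumulate(z, axis=0)
    return SurfaceSet(surfaces=z, axial_depth=config.height, spacing=config.spacing, volume_id=vid)


def generate_surfaces(config: PhantomConfig) -> list[SurfaceSet]:
    """Seeded phantom boundary surfaces for ``config.n_volumes`` volumes."""
    rng = np.random.default_rng(config.rng_seed)
    out = []
    for v in range(config.n_volumes):
        out.append(_single_surface_set(config, rng, vid=f"phantom_{v:03d}"))
    return out


def generate_vessel_profiles(
    n_profiles: int = 20,
    width: int = 9,
    rng: np.random.Generator | int = 0,
) -> list[VesselProfile]:
    """Training vessel profiles: unit baseline with a Gaussian attenuation
    dip of randomized depth and width at the window centre."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    xs = np.linspace(-1, 1, width)
    profiles = []
    for _ in range(n_profiles):
        depth = rng.uniform(0.35, 0.65)
        sig = rng.uniform(0.25, 0.4)
        p = 1.0 - depth * np.exp(-(xs**2) / (2 * sig**2))
        p[0] = p[-1] = 1.0
        profiles.append(VesselProfile(profile=p))
    return profiles


def generate_volume(
    surfaces: SurfaceSet,
    config: PhantomConfig,
    rng: np.random.Generator | int | None = None,
    planted_vessel_columns: list[int] | None = None,
) -> tuple[OCTVolume, VesselPlacement | None]:
    """Render a phantom volume: layer fill with the config brightness,
    synthetic choroid/background, optional vessels (planted or sampled) and
    speckle.  Returns the volume and the vessel placements used (None when
    vessel-free)."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    appearance = LayerAppearance(layer_brightness=np.asarray(config.layer_brightness))
    vol = render_layers(surfaces, appearance)
    arr = vol.intensities
    B, H, W = arr.shape
    # synthetic background/choroid: dim vitreous, decaying bright choroid
    rows = np.arange(H)[None, :, None]
    z_top = surfaces.surfaces[0][:, None, :]
    z_bot = surfaces.surfaces[-1][:, None, :]
    vitreous = rows < z_top
    below = rows >= z_bot
    arr[vitreous] = 0.04
    choroid = np.clip(0.55 * np.exp(-(rows - z_bot) / 25.0), 0.03, 1.0)
    arr = np.where(below, choroid, arr)
    vol = OCTVolume(intensities=np.clip(arr, 0, 1), spacing=surfaces.spacing)

    placements = None
    if planted_vessel_columns:
        windows = [
            [(c, 9) for c in planted_vessel_columns] for _ in range(B)
        ]
        placements = VesselPlacement(windows=windows)
    elif config.n_vessels > 0:
        placements = sample_placements(
            surfaces, config.n_vessels, rng, min_separation=max(12, W // 16)
        )
    if placements is not None:
        profiles = generate_vessel_profiles(rng=rng)
        vmodel = build_vessel_model(profiles)
        vol = render_vessels(vol, surfaces, placements, vmodel, rng)
    if config.noise_sigma > 0:
        vol = add_speckle(vol, config.noise_sigma, rng)
    return vol, placements


def generate_dme_library(
    config: PhantomConfig,
    n_references: int = 8,
) -> ReferenceLibrary:
    """DME-style reference B-scans: bulged (dome) boundaries, layered
    intensities, 1–3 ellipsoidal hyporeflective fluid pockets strictly
    inside the retina, and consistent binary masks."""
    rng = np.random.default_rng(config.rng_seed + 10_000)
    W, H, K = config.width, config.height, config.n_surfaces
    refs = []
    xs = np.arange(W)
    for r in range(n_references):
        # dome instead of pit: central elevation
        xc = W / 2 + rng.normal(0, W * 0.02)
        wx = config.pit_width_x * rng.uniform(1.2, 1.8)
        dome = np.exp(-((xs - xc) ** 2) / (2 * wx**2))
        base = config.ilm_base + rng.normal(0, config.base_jitter)
        bulge = rng.uniform(20.0, 45.0)
        boundaries = np.empty((K, W))
        boundaries[0] = base - bulge * dome + 2.0 * np.polyval(
            rng.normal(0, 0.5, 3), np.linspace(-1, 1, W)
        )
        swell = 1.0 + 0.8 * dome  # edema thickens central layers
        for k in range(K - 1):
            eps = rng.normal(0, config.perturbation_amplitude)
            t = config.layer_thickness[k] * np.exp(eps) * swell
            boundaries[k + 1] = boundaries[k] + np.maximum(t, 0.5)
        boundaries = np.clip(boundaries, 0, H - 1e-6)
        boundaries = np.maximum.accumulate(boundaries, axis=0)

        img = np.zeros((H, W))
        rowcol = np.arange(H)[:, None]
        img[rowcol < boundaries[0][None, :]] = 0.04
        for k in range(K - 1):
            mask = (rowcol >= boundaries[k][None, :]) & (rowcol < boundaries[k + 1][None, :])
            img[mask] = config.layer_brightness[k]
        below = rowcol >= boundaries[-1][None, :]
        img = np.where(below, np.clip(0.5 * np.exp(-(rowcol - boundaries[-1][None, :]) / 25.0), 0.03, 1), img)

        fluid = np.zeros((H, W), dtype=bool)
        lo_n, hi_n = config.n_fluid_pockets
        n_pockets = int(rng.integers(lo_n, hi_n + 1)) if hi_n >= lo_n else 0
        kf = config.fluid_layer
        for _ in range(n_pockets):
            cx = rng.uniform(0.25 * W, 0.75 * W)
            col = int(np.clip(cx, 0, W - 1))
            top = boundaries[kf - 1, col]
            bot = boundaries[kf, col]
            cz = 0.5 * (top + bot)
            a = rng.uniform(0.06, 0.14) * W  # lateral semi-axis
            bsemi = max(1.5, 0.4 * (bot - top))  # axial semi-axis
            ell = ((xs[None, :] - cx) / a) ** 2 + ((rowcol - cz) / bsemi) ** 2 <= 1.0
            # keep pockets strictly inside the retina (between surfaces 1, 8)
            inside = (rowcol > boundaries[0][None, :] + 1) & (rowcol < boundaries[7][None, :] - 1)
            fluid |= ell & inside
        img[fluid] = 0.05  # hyporeflective
        if config.noise_sigma > 0:
            img = np.clip(img * (1 + rng.normal(0, config.noise_sigma, img.shape)), 0, 1)
        refs.append(
            DMEReference(
                image=np.clip(img, 0, 1),
                boundaries=boundaries,
                fluid_mask=fluid,
                reference_id=f"dme_ref_{r:03d}",
            )
        )
    return ReferenceLibrary(references=refs)
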