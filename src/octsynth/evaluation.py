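"""Validation statistics for synthetic OCT data.

The battery mirrors how synthetic retinal volumes are judged against real
ones: en-face thickness maps between named surface pairs, mean-intensity
projection images (vessels dark in outer-layer bands, bright in inner
ones), four gray-level co-occurrence texture features (energy, contrast,
homogeneity, correlation), and distribution comparison via Q-Q point sets
plus the two-sample Kolmogorov–Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dme_synthesis import DMEScene
from .landmarking import SurfaceSet
from .renderer import OCTVolume

__all__ = [
    "ThicknessMap",
    "GLCMFeatures",
    "KSResult",
    "EvalReport",
    "EvaluationError",
    "DEFAULT_LAYER_PAIRS",
    "thickness_map",
    "projection_image",
    "glcm_features",
    "region_features",
    "ks_two_sample",
    "compare_groups",
]


class EvaluationError(ValueError):
    pass


# layer name → (upper surface, lower surface), 1-based surface indices;
# the standard macular report layers
DEFAULT_LAYER_PAIRS: dict[str, tuple[int, int]] = {
    "total_macula": (1, 9),
    "RNFL": (1, 2),
    "GCIPL": (2, 3),
    "RPE": (8, 9),
}

FEATURE_NAMES = ("energy", "contrast", "homogeneity", "correlation")


@dataclass
class ThicknessMap:
    values: np.ndarray  # (B, W)
    surface_pair: tuple[int, int]
    layer_name: str = ""
    units: str = "voxels"


@dataclass(frozen=True)
class GLCMFeatures:
    energy: float
    contrast: float
    homogeneity: float
    correlation: float  # NaN when σx or σy is zero
    n_levels: int
    offset: tuple[int, int]

    def as_dict(self) -> dict:
        return {
            "energy": self.energy,
            "contrast": self.contrast,
            "homogeneity": self.homogeneity,
            "correlation": self.correlation,
        }


@dataclass
class KSResult:
    statistic: float
    p_value: float
    qq_points: np.ndarray  # (m, 2) matched empirical quantiles


@dataclass
class EvalReport:
    thickness: pd.DataFrame
    features: pd.DataFrame
    ks: pd.DataFrame
    qq: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# thickness and projections
# --------------------------------------------------------------------------


def thickness_map(surfaces: SurfaceSet, pair: tuple[int, int], name: str = "") -> ThicknessMap:
    """Axial distance z_k − z_j between two surfaces (1-based indices j < k),
    per (B-scan, column); in µm when voxel spacing is known."""
    j, k = pair
    if j >= k:
        raise EvaluationError(f"need j < k, got pair {pair}")
    if not (1 <= j <= surfaces.n_surfaces and 1 <= k <= surfaces.n_surfaces):
        raise EvaluationError(f"surface pair {pair} out of range")
    values = surfaces.surfaces[k - 1] - surfaces.surfaces[j - 1]
    units = "voxels"
    if surfaces.spacing is not None:
        values = values * surfaces.spacing[2]
        units = "um"
    return ThicknessMap(values=values, surface_pair=pair, layer_name=name, units=units)


def projection_image(
    volume: OCTVolume, surfaces: SurfaceSet, pair: tuple[int, int]
) -> np.ndarray:
    """En-face mean-intensity projection between two surfaces: per (b, x) the
    mean over rows z_j ≤ r < z_k; NaN where the band is empty."""
    j, k = pair
    if j >= k:
        raise EvaluationError(f"need j < k, got pair {pair}")
    B, H, W = volume.intensities.shape
    rows = np.arange(H)[None, :, None]
    lo = surfaces.surfaces[j - 1][:, None, :]
    hi = surfaces.surfaces[k - 1][:, None, :]
    band = (rows >= lo) & (rows < hi)
    counts = band.sum(axis=1)
    if not counts.any():
        raise EvaluationError("projection band is empty everywhere")
    sums = np.where(band, volume.intensities, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


# --------------------------------------------------------------------------
# GLCM texture features
# --------------------------------------------------------------------------


def _quantize(region: np.ndarray, n_levels: int, mask: np.ndarray | None) -> np.ndarray:
    vals = region[mask] if mask is not None else region.ravel()
    lo, hi = float(np.min(vals)), float(np.max(vals))
    if hi <= lo:
        return np.zeros_like(region, dtype=int)
    q = np.floor((region - lo) / (hi - lo) * n_levels).astype(int)
    return np.clip(q, 0, n_levels - 1)


def glcm_features(
    region: np.ndarray,
    n_levels: int = 8,
    offset: tuple[int, int] = (0, 1),
    mask: np.ndarray | None = None,
) -> GLCMFeatures:
    """Gray-level co-occurrence features of a 2D region.

    Intensities are quantized to ``n_levels`` equal-width bins over the
    region's range; ordered pixel pairs at ``offset`` (row, col) are counted
    and normalized to the joint probability p(i, j), from which
    energy = Σ p², contrast = Σ (i−j)² p, homogeneity = Σ p/(1+(i−j)²) and
    the normalized correlation are computed.  Correlation is NaN for a
    constant region (zero marginal variance).  ``mask`` restricts counting
    to pairs whose both pixels are inside the mask.
    """
    region = np.asarray(region, dtype=float)
    if region.ndim != 2:
        raise EvaluationError("region must be 2D")
    if n_levels < 2:
        raise EvaluationError("n_levels must be ≥ 2")
    dr, dc = offset
    H, W = region.shape
    if H <= abs(dr) or W <= abs(dc):
        raise EvaluationError("region too small for the requested offset")

    q = _quantize(region, n_levels, mask)
    r0 = slice(max(0, -dr), min(H, H - dr))
    c0 = slice(max(0, -dc), min(W, W - dc))
    r1 = slice(max(0, dr), min(H, H + dr))
    c1 = slice(max(0, dc), min(W, W + dc))
    a = q[r0, c0].ravel()
    b = q[r1, c1].ravel()
    if mask is not None:
        valid = (mask[r0, c0] & mask[r1, c1]).ravel()
        a, b = a[valid], b[valid]
    if a.size == 0:
        raise EvaluationError("no valid pixel pairs at the requested offset")

    counts = np.zeros((n_levels, n_levels))
    np.add.at(counts, (a, b), 1.0)
    p = counts / counts.sum()

    i = np.arange(n_levels)[:, None]
    j = np.arange(n_levels)[None, :]
    energy = float(np.sum(p**2))
    contrast = float(np.sum((i - j) ** 2 * p))
    homogeneity = float(np.sum(p / (1.0 + (i - j) ** 2)))
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(np.arange(n_levels) * px))
    mu_y = float(np.sum(np.arange(n_levels) * py))
    sig_x = float(np.sqrt(np.sum((np.arange(n_levels) - mu_x) ** 2 * px)))
    sig_y = float(np.sqrt(np.sum((np.arange(n_levels) - mu_y) ** 2 * py)))
    if sig_x <= 0 or sig_y <= 0:
        correlation = float("nan")
    else:
        correlation = float(
            np.sum(((i - mu_x) / sig_x) * ((j - mu_y) / sig_y) * p)
        )
    return GLCMFeatures(
        energy=energy,
        contrast=contrast,
        homogeneity=homogeneity,
        correlation=correlation,
        n_levels=n_levels,
        offset=(dr, dc),
    )


def region_features(
    scene: "DMEScene | tuple[OCTVolume, int]",
    surfaces: SurfaceSet | None = None,
    layer_indices: tuple[int, ...] = (1, 3, 5),
    n_levels: int = 8,
    offset: tuple[int, int] = (0, 1),
) -> pd.DataFrame:
    """Texture features per retinal layer region.

    Accepts either a DMEScene (its own boundaries define the regions) or a
    ``(volume, b_scan_index)`` pair with a SurfaceSet.  The default region
    set is layers 1, 3 and 5 (between boundaries 1–2, 3–4 and 5–6).  Returns
    a tidy (region, feature, value) table; empty layers yield NaN rows.
    """
    if isinstance(scene, DMEScene):
        image = scene.image
        boundaries = scene.boundaries
    else:
        volume, b = scene
        if surfaces is None:
            raise EvaluationError("surfaces required for volume input")
        image = volume.intensities[b]
        boundaries = surfaces.surfaces[:, b, :]

    H, W = image.shape
    rows = np.arange(H)[:, None]
    records = []
    for k in layer_indices:
        lo = boundaries[k - 1][None, :]
        hi = boundaries[k][None, :]
        mask = (rows >= lo) & (rows < hi)
        if mask.sum() < 2:
            feats = {name: float("nan") for name in FEATURE_NAMES}
        else:
            try:
                f = glcm_features(image, n_levels=n_levels, offset=offset, mask=mask)
                feats = f.as_dict()
            except EvaluationError:
                feats = {name: float("nan") for name in FEATURE_NAMES}
        for name, value in feats.items():
            records.append({"region": f"layer_{k}", "feature": name, "value": value})
    return pd.DataFrame.from_records(records)


# --------------------------------------------------------------------------
# distribution comparison
# --------------------------------------------------------------------------


def ks_two_sample(a, b) -> KSResult:
    """Two-sample Kolmogorov–Smirnov test with Q-Q point set.

    D is the supremum ECDF gap over the pooled sample points; the p-value
    uses the asymptotic two-sample Kolmogorov distribution.  The Q-Q points
    are matched empirical quantiles of the two samples.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise EvaluationError("each sample needs at least two values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise EvaluationError("samples must be finite")
    res = stats.ks_2samp(a, b, method="asymp")
    m = min(a.size, b.size)
    probs = (np.arange(m) + 0.5) / m
    qq = np.column_stack([np.quantile(a, probs), np.quantile(b, probs)])
    return KSResult(statistic=float(res.statistic), p_value=float(res.pvalue), qq_points=qq)


def compare_groups(
    real_surfaces: list[SurfaceSet],
    synth_surfaces: list[SurfaceSet],
    real_images: list[np.ndarray] | None = None,
    synth_images: list[np.ndarray] | None = None,
    layer_pairs: dict[str, tuple[int, int]] | None = None,
    layer_indices: tuple[int, ...] = (1, 3, 5),
    n_levels: int = 8,
) -> EvalReport:
    """Group-level comparison of real vs synthetic data.

    Thickness: per volume the mean thickness of each configured layer;
    groups summarized as mean ± SD with a Welch two-sample t-test p-value
    (p is NaN when a group has a single member).  Texture: per-image GLCM
    features in the configured layer regions (images are 2D B-scans with
    boundaries taken from the matching surface set's central B-scan when
    SurfaceSets are 3D), compared feature-wise with the K-S test and Q-Q
    point sets.
    """
    if not real_surfaces or not synth_surfaces:
        raise EvaluationError("both groups must be non-empty")
    layer_pairs = layer_pairs or DEFAULT_LAYER_PAIRS

    thickness_rows = []
    for name, pair in layer_pairs.items():
        real_means = [float(np.mean(thickness_map(s, pair, name).values)) for s in real_surfaces]
        synth_means = [float(np.mean(thickness_map(s, pair, name).values)) for s in synth_surfaces]
        if len(real_means) > 1 and len(synth_means) > 1:
            if np.var(real_means) + np.var(synth_means) == 0:
                p = 1.0
            else:
                p = float(stats.ttest_ind(real_means, synth_means, equal_var=False).pvalue)
        else:
            p = float("nan")
        thickness_rows.append(
            {
                "layer": name,
                "real_mean": float(np.mean(real_means)),
                "real_sd": float(np.std(real_means, ddof=1)) if len(real_means) > 1 else float("nan"),
                "synth_mean": float(np.mean(synth_means)),
                "synth_sd": float(np.std(synth_means, ddof=1)) if len(synth_means) > 1 else float("nan"),
                "p_value": p,
            }
        )
    thickness_df = pd.DataFrame.from_records(thickness_rows)

    ks_rows: list[dict] = []
    qq: dict = {}
    if real_images is not None and synth_images is not None:
        def _features(images, surface_sets, group):
            recs = []
            for idx, img in enumerate(images):
                surf = surface_sets[min(idx, len(surface_sets) - 1)]
                central = surf.n_bscans // 2
                boundaries = surf.surfaces[:, central, :]
                scene = DMEScene(
                    image=np.asarray(img, dtype=float),
                    boundaries=boundaries,
                    fluid_mask=np.zeros_like(np.asarray(img), dtype=bool),
                )
                tbl = region_features(scene, layer_indices=layer_indices, n_levels=n_levels)
                tbl["group"] = group
                tbl["image"] = idx
                recs.append(tbl)
            return pd.concat(recs, ignore_index=True)

        real_tbl = _features(real_images, real_surfaces, "real")
        synth_tbl = _features(synth_images, synth_surfaces, "synthetic")
        features_df = pd.concat([real_tbl, synth_tbl], ignore_index=True)
        for (region, feature), sub in features_df.groupby(["region", "feature"]):
            ra = sub[sub.group == "real"]["value"].dropna().to_numpy()
            sa = sub[sub.group == "synthetic"]["value"].dropna().to_numpy()
            if ra.size >= 2 and sa.size >= 2:
                ks = ks_two_sample(ra, sa)
                ks_rows.append(
                    {"region": region, "feature": feature, "D": ks.statistic, "p_value": ks.p_value}
                )
                qq[(region, feature)] = ks.qq_points
    else:
        features_df = pd.DataFrame(columns=["region", "feature", "value", "group", "image"])

    return EvalReport(
        thickness=thickness_df,
        features=features_df,
        ks=pd.DataFrame.from_records(ks_rows),
        qq=qq,
    )
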