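"""Readers and writers for surfaces, volumes, masks and run configuration.

Surfaces travel as long-format CSV (volume_id, surface_idx, bscan_idx,
column, z) or JSON; volumes as multi-page TIFF (one page per B-scan) or
NIfTI with a JSON provenance sidecar; masks and label images as 8-bit
PNG.  Intensities are float [0, 1] in memory and quantized only on
export, with the scaling recorded.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .landmarking import SurfaceSet
from .renderer import OCTVolume

__all__ = [
    "read_surfaces_csv",
    "write_surfaces_csv",
    "read_surfaces_json",
    "write_surfaces_json",
    "read_volume",
    "write_volume",
    "write_label_masks",
    "write_mask_png",
    "read_mask_png",
]


def write_surfaces_csv(
    surfaces: SurfaceSet, path: str | Path, one_based: bool = False
) -> None:
    off = 1 if one_based else 0
    K, B, W = surfaces.surfaces.shape
    k_idx, b_idx, x_idx = np.meshgrid(
        np.arange(K), np.arange(B), np.arange(W), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "volume_id": surfaces.volume_id,
            "surface_idx": k_idx.ravel() + off,
            "bscan_idx": b_idx.ravel() + off,
            "column": x_idx.ravel() + off,
            "z": surfaces.surfaces.ravel(),
        }
    )
    header_meta = {
        "axial_depth": surfaces.axial_depth,
        "spacing": surfaces.spacing,
        "one_based": one_based,
    }
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# {json.dumps(header_meta)}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_surfaces_csv(path: str | Path) -> SurfaceSet:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        meta = json.loads(first.lstrip("# ")) if first.startswith("#") else {}
        df = pd.read_csv(fh, float_precision="round_trip")
    off = 1 if meta.get("one_based") else 0
    k = df["surface_idx"].to_numpy() - off
    b = df["bscan_idx"].to_numpy() - off
    x = df["column"].to_numpy() - off
    K, B, W = int(k.max()) + 1, int(b.max()) + 1, int(x.max()) + 1
    z = np.full((K, B, W), np.nan)
    z[k, b, x] = df["z"].to_numpy()
    if np.any(np.isnan(z)):
        raise ValueError("surface CSV is missing grid entries")
    _check_ordering(z)
    spacing = tuple(meta["spacing"]) if meta.get("spacing") else None
    depth = int(meta.get("axial_depth", int(np.ceil(z.max())) + 1))
    vid = str(df["volume_id"].iloc[0]) if len(df) else ""
    return SurfaceSet(surfaces=z, axial_depth=depth, spacing=spacing, volume_id=vid)


def _check_ordering(z: np.ndarray) -> None:
    diff = np.diff(z, axis=0)
    if np.any(diff < -1e-9):
        k, b, x = np.unravel_index(np.argmin(diff), diff.shape)
        raise ValueError(
            f"surfaces cross in file: surface {k + 2} rises above surface "
            f"{k + 1} at B-scan {b}, column {x}"
        )


def write_surfaces_json(surfaces: SurfaceSet, path: str | Path) -> None:
    payload = {
        "volume_id": surfaces.volume_id,
        "axial_depth": surfaces.axial_depth,
        "spacing": surfaces.spacing,
        "surfaces": surfaces.surfaces.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_surfaces_json(path: str | Path) -> SurfaceSet:
    payload = json.loads(Path(path).read_text())
    z = np.asarray(payload["surfaces"], dtype=float)
    _check_ordering(z)
    spacing = tuple(payload["spacing"]) if payload.get("spacing") else None
    return SurfaceSet(
        surfaces=z,
        axial_depth=payload["axial_depth"],
        spacing=spacing,
        volume_id=payload.get("volume_id", ""),
    )


def write_volume(
    volume: OCTVolume, path: str | Path, bit_depth: int = 8
) -> None:
    """Multi-page TIFF (.tif/.tiff) or NIfTI (.nii/.nii.gz) export with a
    JSON provenance sidecar recording the quantization scale."""
    path = Path(path)
    scale = 2**bit_depth - 1
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        dtype = np.uint8 if bit_depth == 8 else np.uint16
        tifffile.imwrite(
            path,
            np.round(volume.intensities * scale).astype(dtype),
            photometric="minisblack",
        )
    elif path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.eye(4)
        if volume.spacing is not None:
            dx, dy, dz = volume.spacing
            affine = np.diag([dx, dy, dz, 1.0])
        img = nib.Nifti1Image(volume.intensities.astype(np.float32), affine)
        if volume.spacing is not None:
            img.header.set_zooms((dx, dy, dz))
        nib.save(img, path)
        scale = 1
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "shape": list(volume.intensities.shape),
                "scale": scale,
                "spacing": volume.spacing,
                "provenance": volume.provenance,
            }
        )
    )


def read_volume(path: str | Path) -> OCTVolume:
    path = Path(path)
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        raw = tifffile.imread(path).astype(float)
        scale = meta.get("scale", float(raw.max()) or 1.0)
        arr = raw / scale
    elif path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        arr = np.asarray(img.dataobj, dtype=float)
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    if arr.ndim == 2:
        arr = arr[None]
    if meta.get("shape") and list(arr.shape) != meta["shape"]:
        raise ValueError(
            f"volume shape {list(arr.shape)} does not match sidecar {meta['shape']}"
        )
    spacing = tuple(meta["spacing"]) if meta.get("spacing") else None
    return OCTVolume(
        intensities=np.clip(arr, 0, 1),
        spacing=spacing,
        provenance=meta.get("provenance", {}),
    )


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)


def read_mask_png(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(Path(path))) > 127


def write_label_masks(surfaces: SurfaceSet, out_dir: str | Path) -> list[Path]:
    """8-bit label PNG per B-scan: region k (1-based) between surfaces
    k and k+1, 0 elsewhere."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    H = surfaces.axial_depth
    rows = np.arange(H)[:, None]
    paths = []
    for b in range(surfaces.n_bscans):
        label = np.zeros((H, surfaces.width), dtype=np.uint8)
        for k in range(surfaces.n_surfaces - 1):
            lo = surfaces.surfaces[k, b][None, :]
            hi = surfaces.surfaces[k + 1, b][None, :]
            label[(rows >= lo) & (rows < hi)] = k + 1
        p = out_dir / f"labels_b{b:03d}.png"
        iio.imwrite(p, label)
        paths.append(p)
    return paths
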