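"""File I/O: TIFF stacks with voxel-spacing metadata, CSV tables.

Stacks travel as multi-page TIFF plus a JSON sidecar (same stem, ``.json``
extension) holding the voxel spacing in μm.  Reading errors out on missing
spacing rather than guessing; ImageJ-style TIFF metadata is accepted as a
fallback.  Tabular data (spectra, scans, bleach series, per-cell
measurements) is plain CSV.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from wallvol.grid import VoxelGrid
from wallvol.spectra import BleachSeries, Lambda2Scan, Spectrum

__all__ = [
    "MissingSpacingError",
    "write_stack",
    "read_stack",
    "read_roi_labels",
    "write_spectrum",
    "read_spectrum",
    "write_lambda2",
    "read_lambda2",
    "write_bleach",
    "read_bleach",
]


class MissingSpacingError(ValueError):
    """A stack was read without any voxel-spacing information."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(path: str | Path, grid: VoxelGrid) -> Path:
    """Write a multi-page TIFF and its spacing sidecar; returns the sidecar path."""
    path = Path(path)
    tifffile.imwrite(
        path, np.asarray(grid.values, dtype=np.float32), photometric="minisblack"
    )
    sidecar = _sidecar(path)
    payload = {"spacing_um": list(grid.spacing), "meta": _jsonable(grid.meta)}
    sidecar.write_text(json.dumps(payload, indent=2))
    return sidecar


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _spacing_from_imagej(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    meta = tif.imagej_metadata
    if not meta or "spacing" not in meta:
        return None
    try:
        page = tif.pages[0]
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        sx = xres[1] / xres[0]
        sy = yres[1] / yres[0]
    except (KeyError, ZeroDivisionError):
        return None
    return (float(meta["spacing"]), float(sy), float(sx))


def read_stack(path: str | Path) -> VoxelGrid:
    """Read a stack and its voxel spacing.

    Spacing comes from the JSON sidecar, falling back to ImageJ TIFF
    metadata; a stack with no spacing information is an error.  A 2D
    single-page TIFF is accepted as a one-slice stack with a warning.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        values = tif.asarray()
        ij_spacing = _spacing_from_imagej(tif)
    if values.ndim == 2:
        warnings.warn(f"{path.name} is a single 2D page; treating it as a 1-slice stack")
        values = values[np.newaxis]
    if values.ndim != 3:
        raise ValueError(f"expected a 2D or 3D TIFF, got ndim={values.ndim}")
    sidecar = _sidecar(path)
    meta: dict = {}
    if sidecar.exists():
        payload = json.loads(sidecar.read_text())
        spacing = tuple(float(s) for s in payload["spacing_um"])
        meta = payload.get("meta", {})
    elif ij_spacing is not None:
        spacing = ij_spacing
    else:
        raise MissingSpacingError(
            f"no voxel spacing found for {path}: provide a sidecar "
            f"{sidecar.name} with {{'spacing_um': [z, y, x]}}"
        )
    return VoxelGrid(values.astype(np.float64), spacing, meta=meta)


def read_roi_labels(path: str | Path) -> np.ndarray:
    """Read an integer ROI label image (2D or 3D TIFF)."""
    labels = tifffile.imread(Path(path))
    if labels.ndim not in (2, 3):
        raise ValueError("ROI label image must be 2D or 3D")
    return labels.astype(np.int32)


# ---------------------------------------------------------------------------
# tabular formats


def write_spectrum(path: str | Path, spectrum: Spectrum) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "intensity": spectrum.intensities}
    ).to_csv(path, index=False)


def read_spectrum(path: str | Path, kind: str = "absorption") -> Spectrum:
    df = pd.read_csv(path)
    return Spectrum(
        df["wavelength_nm"].to_numpy(), df["intensity"].to_numpy(), kind=kind
    )


def write_lambda2(path: str | Path, scan: Lambda2Scan) -> None:
    """Matrix CSV: first column excitation (nm), remaining columns one per
    emission band, header row carrying the band centres."""
    df = pd.DataFrame(
        scan.intensities,
        index=pd.Index(scan.excitation_nm, name="excitation_nm"),
        columns=[f"{e:g}" for e in scan.emission_nm],
    )
    df.to_csv(path)


def read_lambda2(path: str | Path) -> Lambda2Scan:
    df = pd.read_csv(path, index_col=0)
    return Lambda2Scan(
        excitation_nm=df.index.to_numpy(dtype=float),
        emission_nm=np.array([float(c) for c in df.columns]),
        intensities=df.to_numpy(dtype=float),
    )


def write_bleach(path: str | Path, series: BleachSeries) -> None:
    pd.DataFrame(
        {"frame": series.frame, "time_s": series.time_s, "intensity": series.intensity}
    ).to_csv(path, index=False)


def read_bleach(path: str | Path) -> BleachSeries:
    df = pd.read_csv(path)
    return BleachSeries(
        frame=df["frame"].to_numpy(),
        time_s=df["time_s"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
    )
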