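"""Whole-body ion-image processing for DESI mass spectrometry imaging.

Images are regular pixel grids (row 0 at top, 0-based coordinates) carrying
centroided channel intensities keyed by m/z.  The module reads imzML or an
internal tab-separated pixel-grid format, applies constant-ppm lockmass
recalibration, extracts ion images within a ppm window, normalizes each
pixel by its total ion current (TIC), and summarizes organ regions of
interest.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

DEFAULT_PIXEL_PITCH_UM: float = 150.0
#: extraction half-window; the identification tolerance is reused as default
DEFAULT_PPM_TOLERANCE: float = 10.0
MAX_LOCKMASS_OFFSET_PPM: float = 50.0


@dataclass
class IonImageGrid:
    """Pixel grid of channel intensities over a rectangular raster.

    ``intensities`` has shape (rows, cols, n_channels); ``mzs`` holds the
    channel m/z values.  ``missing`` flags pixels absent from the source
    file (kept at zero intensity).  The per-pixel TIC is the sum over
    channels by construction.
    """

    mzs: np.ndarray
    intensities: np.ndarray
    pitch_um: float = DEFAULT_PIXEL_PITCH_UM
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mzs = np.asarray(self.mzs, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be (rows, cols, channels)")
        if self.mzs.size != self.intensities.shape[2]:
            raise ValueError("channel count mismatch between mzs and intensities")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if np.any(np.diff(self.mzs) <= 0):
            order = np.argsort(self.mzs)
            self.mzs = self.mzs[order]
            self.intensities = self.intensities[..., order]

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape[:2]

    @property
    def tic(self) -> np.ndarray:
        """Total ion current per pixel: sum over all channels."""
        return self.intensities.sum(axis=2)


@dataclass(frozen=True)
class RoiMask:
    """Named organ region: boolean pixel mask on the grid."""

    organ: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not self.mask.any():
            raise ValueError(f"ROI {self.organ!r} is empty")


def write_grid_tsv(grid: IonImageGrid, path: str | os.PathLike) -> None:
    """Write the internal long-format pixel grid: row, col, mz, intensity."""
    rows, cols, nch = grid.intensities.shape
    r, c, k = np.meshgrid(np.arange(rows), np.arange(cols), np.arange(nch),
                          indexing="ij")
    df = pd.DataFrame({
        "row": r.ravel(), "col": c.ravel(),
        "mz": grid.mzs[k.ravel()],
        "intensity": grid.intensities.ravel(),
    })
    with open(path, "w") as fh:
        fh.write(f"# pitch_um={grid.pitch_um}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_grid_tsv(path: str | os.PathLike) -> IonImageGrid:
    pitch = DEFAULT_PIXEL_PITCH_UM
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# pitch_um="):
            pitch = float(first.split("=", 1)[1])
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    if df.empty:
        raise ValueError(f"empty pixel-grid table: {path}")
    mzs = np.sort(df["mz"].unique())
    rows = int(df["row"].max()) + 1
    cols = int(df["col"].max()) + 1
    inten = np.zeros((rows, cols, mzs.size))
    ch = np.searchsorted(mzs, df["mz"].to_numpy())
    inten[df["row"].to_numpy(int), df["col"].to_numpy(int), ch] = \
        df["intensity"].to_numpy(float)
    seen = np.zeros((rows, cols), dtype=bool)
    seen[df["row"].to_numpy(int), df["col"].to_numpy(int)] = True
    missing = ~seen if not seen.all() else None
    if missing is not None:
        warnings.warn(f"{int(missing.sum())} missing pixels in {path}", stacklevel=2)
    return IonImageGrid(mzs=mzs, intensities=inten, pitch_um=pitch, missing=missing)


def write_imzml(grid: IonImageGrid, path: str | os.PathLike) -> None:
    """Write a continuous-mode imzML image (plus its .ibd binary)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    rows, cols, _ = grid.intensities.shape
    with ImzMLWriter(os.fspath(path), mode="continuous") as writer:
        for r in range(rows):
            for c in range(cols):
                # imzML coordinates are 1-based (x, y)
                writer.addSpectrum(grid.mzs, grid.intensities[r, c], (c + 1, r + 1))


def _read_imzml(path: str | os.PathLike) -> IonImageGrid:
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(os.fspath(path))
    coords = np.asarray(parser.coordinates)
    if coords.size == 0:
        raise ValueError(f"imzML file has no spectra: {path}")
    cols = coords[:, 0].max()
    rows = coords[:, 1].max()
    mzs, _ = parser.getspectrum(0)
    mzs = np.asarray(mzs, dtype=float)
    inten = np.zeros((rows, cols, mzs.size))
    seen = np.zeros((rows, cols), dtype=bool)
    for idx, (x, y, *_z) in enumerate(parser.coordinates):
        spec_mzs, spec_int = parser.getspectrum(idx)
        if not np.allclose(spec_mzs, mzs):
            raise ValueError("processed-mode imzML with varying m/z axes is "
                             "not supported; expected continuous mode")
        inten[y - 1, x - 1] = spec_int
        seen[y - 1, x - 1] = True
    pitch = DEFAULT_PIXEL_PITCH_UM
    missing = ~seen if not seen.all() else None
    if missing is not None:
        warnings.warn(f"non-rectangular raster: {int(missing.sum())} missing "
                      "pixels flagged", stacklevel=2)
    return IonImageGrid(mzs=mzs, intensities=inten, pitch_um=pitch, missing=missing)


def read_image(path: str | os.PathLike, fmt: str | None = None) -> IonImageGrid:
    """Read an ion image from imzML or the internal pixel-grid TSV.

    The format is inferred from the extension unless given explicitly
    (``"imzml"`` or ``"tsv"``).
    """
    if fmt is None:
        ext = os.path.splitext(os.fspath(path))[1].lower()
        fmt = "imzml" if ext == ".imzml" else "tsv"
    if fmt == "imzml":
        return _read_imzml(path)
    if fmt == "tsv":
        return _read_grid_tsv(path)
    raise ValueError(f"unknown image format {fmt!r}")


def lockmass_correct(grid: IonImageGrid, observed_reference_mz: float,
                     true_reference_mz: float) -> IonImageGrid:
    """Recalibrate the m/z axis by the constant ppm offset of a lockmass.

    The offset implied by the observed vs true reference m/z (e.g. leucine
    enkephalin) is removed from every channel.  Offsets beyond 50 ppm
    indicate gross miscalibration and raise.
    """
    offset_ppm = (observed_reference_mz - true_reference_mz) / true_reference_mz * 1e6
    if abs(offset_ppm) > MAX_LOCKMASS_OFFSET_PPM:
        raise ValueError(f"lockmass offset {offset_ppm:.1f} ppm exceeds "
                         f"{MAX_LOCKMASS_OFFSET_PPM} ppm — miscalibrated data")
    corrected = grid.mzs * (true_reference_mz / observed_reference_mz)
    return IonImageGrid(mzs=corrected, intensities=grid.intensities.copy(),
                        pitch_um=grid.pitch_um, missing=grid.missing)


def extract_ion_image(grid: IonImageGrid, mz: float,
                      ppm: float = DEFAULT_PPM_TOLERANCE) -> np.ndarray:
    """Single-channel image: per-pixel sum of channels within ±ppm of mz.

    A query with no matching channel yields an all-zero image with a warning
    (not an error) so batch extraction stays total.
    """
    if ppm <= 0:
        raise ValueError("ppm tolerance must be positive")
    window = mz * ppm * 1e-6
    sel = np.abs(grid.mzs - mz) <= window
    if not sel.any():
        warnings.warn(f"no channel within {ppm} ppm of m/z {mz}", stacklevel=2)
        return np.zeros(grid.shape)
    return grid.intensities[..., sel].sum(axis=2)


def tic_normalize(grid: IonImageGrid) -> tuple[IonImageGrid, np.ndarray]:
    """Divide each pixel's channels by that pixel's TIC.

    Zero-TIC pixels (e.g. the swim-bladder void) become zeros and are
    returned as a flag mask, keeping downstream statistics total.  Where
    TIC > 0 the normalized channels sum to 1.
    """
    tic = grid.tic
    zero = tic <= 0
    safe = np.where(zero, 1.0, tic)
    normalized = grid.intensities / safe[..., None]
    normalized[zero] = 0.0
    out = IonImageGrid(mzs=grid.mzs.copy(), intensities=normalized,
                       pitch_um=grid.pitch_um, missing=grid.missing)
    return out, zero


def roi_statistics(image: np.ndarray, masks: Mapping[str, np.ndarray] | list[RoiMask],
                   ) -> pd.DataFrame:
    """Per-organ mean/median/max of a single-channel image, ranked by mean."""
    if isinstance(masks, Mapping):
        roi_list = [RoiMask(organ, m) for organ, m in masks.items()]
    else:
        roi_list = list(masks)
    if not roi_list:
        raise ValueError("no ROI masks supplied")
    rows = []
    for roi in roi_list:
        if roi.mask.shape != image.shape:
            raise ValueError(f"ROI {roi.organ!r} shape {roi.mask.shape} does not "
                             f"match image {image.shape}")
        vals = image[roi.mask]
        rows.append({"organ": roi.organ, "n_pixels": int(vals.size),
                     "mean": float(vals.mean()), "median": float(np.median(vals)),
                     "max": float(vals.max())})
    df = pd.DataFrame(rows).sort_values("mean", ascending=False,
                                        ignore_index=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def export_png(image: np.ndarray, path: str | os.PathLike) -> None:
    """Export a single-channel image as 16-bit grayscale PNG (max-scaled)."""
    from PIL import Image

    peak = image.max()
    scaled = (image / peak * 65535.0) if peak > 0 else np.zeros_like(image)
    Image.fromarray(scaled.astype(np.uint16)).save(os.fspath(path))


def export_image_tsv(image: np.ndarray, path: str | os.PathLike) -> None:
    """Numeric companion to the PNG export: one row per grid row."""
    np.savetxt(os.fspath(path), image, delimiter="\t", fmt="%.6g")
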