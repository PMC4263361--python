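"""Reading and writing images and tab-delimited tables."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from colonymorph.containers import PlateImage


def read_image(path: str | Path, pixel_size: float | None = None, **labels) -> PlateImage:
    """Read a grayscale PNG/TIFF as a :class:`PlateImage` (float intensities)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse RGB(A) to luminance
        arr = arr[..., :3].mean(axis=-1)
    return PlateImage(arr.astype(float), pixel_size=pixel_size, labels=labels)


def write_image(path: str | Path, intensities: np.ndarray, bits: int = 8) -> Path:
    """Write a float intensity grid as 8-bit PNG or 8/16-bit TIFF."""
    path = Path(path)
    arr = np.asarray(intensities, dtype=float)
    if bits == 8:
        out = np.clip(arr, 0, 255).astype(np.uint8)
    elif bits == 16:
        out = np.clip(arr, 0, 65535).astype(np.uint16)
    else:
        raise ValueError("bits must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)
    return path


def read_wavelength_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited wavelength table (agar_pct, glucose_pct, order, wavelength_um)."""
    df = pd.read_csv(path, sep="\t")
    required = {"agar_pct", "wavelength_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"wavelength table is missing columns: {sorted(missing)}")
    return df


def write_table(path: str | Path, df: pd.DataFrame) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path
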