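"""Core data containers shared across the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PlateImage:
    """A grayscale plate photograph with optional physical calibration.

    Parameters
    ----------
    intensities
        2D array of pixel intensities, row-major with origin at the
        top-left corner (0-based indices).
    pixel_size
        Physical length of one pixel (micrometres per pixel), if known.
    labels
        Free-form condition metadata, e.g. ``{"agar_pct": 1.5,
        "glucose_pct": 0.5, "strain": "FLO11", "time": 4.0}``.
    """

    intensities: np.ndarray
    pixel_size: float | None = None
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("PlateImage requires a non-empty 2D intensity grid")
        if not np.all(np.isfinite(arr)):
            raise ValueError("PlateImage intensities must be finite")
        if np.any(arr < 0):
            raise ValueError("PlateImage intensities must be non-negative")
        self.intensities = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclass(frozen=True)
class Disc:
    """A detected circular object (the plate) in image coordinates.

    ``circularity_cost`` is the P2A of the thresholded component the disc
    was fitted to: 1 for a perfect circle, larger for ragged components.
    """

    center: tuple[float, float]
    radius: float
    circularity_cost: float = np.nan

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("Disc radius must be positive")

    def contains(self, row: float, col: float, margin: float = 0.0) -> bool:
        r0, c0 = self.center
        return float(np.hypot(row - r0, col - c0)) <= self.radius - margin

    def interior_mask(self, shape: tuple[int, int], margin: float = 0.0) -> np.ndarray:
        """Boolean mask of pixels strictly inside the disc (minus ``margin``)."""
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        r0, c0 = self.center
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= (self.radius - margin) ** 2
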