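"""Plate detection, colony segmentation, and shape-irregularity statistics.

Two complementary, scale-invariant measures of rim irregularity are
provided.  P2A = P^2 / (4*pi*A) (the inverse isoperimetric quotient) is 1
for a perfect circle and grows as the outline roughens; it is sensitive
to fine rim fluctuations.  Boundary fluctuation BF = std(r)/mean(r) of
the boundary radius r(theta) about the colony centroid is 0 for a circle
and responds to coarse features such as petals and asymmetry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from skimage.filters import threshold_otsu

from colonymorph.containers import Disc, PlateImage
from colonymorph.masks import ColonyMask, largest_component, mask_perimeter


class PlateNotFoundError(ValueError):
    pass


class SegmentationError(ValueError):
    pass


def compute_p2a(mask: ColonyMask) -> float:
    """P2A = P^2/(4*pi*A) of a colony mask; >= 1 up to discretization."""
    if mask.area == 0:
        raise ValueError("cannot compute P2A of an empty mask")
    return float(mask.perimeter**2 / (4 * np.pi * mask.area))


def compute_bf(mask: ColonyMask, n_angular_bins: int = 360) -> float:
    """Boundary fluctuation: std/mean of the angularly binned boundary radius."""
    r = mask.boundary_radii(n_angular_bins)
    return float(np.std(r) / np.mean(r))


@dataclass(frozen=True)
class ShapeMetrics:
    area: float
    perimeter: float
    p2a: float
    bf: float
    boundary_radii: np.ndarray

    @classmethod
    def from_mask(cls, mask: ColonyMask, n_angular_bins: int = 360) -> "ShapeMetrics":
        r = mask.boundary_radii(n_angular_bins)
        return cls(
            area=float(mask.area),
            perimeter=float(mask.perimeter),
            p2a=compute_p2a(mask),
            bf=float(np.std(r) / np.mean(r)),
            boundary_radii=r,
        )


# ---------------------------------------------------------------------------
# plate detection

def detect_plate(
    image: PlateImage,
    threshold_grid: np.ndarray | None = None,
    cost_ceiling: float = 1.6,
) -> Disc:
    """Find the circular plate by scanning thresholds for the roundest component.

    Each candidate threshold binarizes the image; the largest connected
    component is scored by its P2A (the circularity cost — 1 for a perfect
    disc).  The threshold minimizing the cost wins.  If no candidate
    produces a component with cost below ``cost_ceiling`` the image is
    declared plate-free.
    """
    arr = image.intensities
    lo, hi = float(arr.min()), float(arr.max())
    if hi - lo < 1e-12:
        raise PlateNotFoundError("no plate found: image has no intensity variation")
    if threshold_grid is None:
        threshold_grid = np.linspace(lo, hi, 18)[1:-1]
    candidates: list[tuple[float, int, np.ndarray]] = []
    for thr in np.atleast_1d(threshold_grid):
        comp = largest_component(arr > thr)
        area = int(comp.sum())
        if area < 64:  # too small to be a plate
            continue
        cost = mask_perimeter(comp) ** 2 / (4 * np.pi * area)
        candidates.append((float(cost), area, comp))
    if not candidates or min(c[0] for c in candidates) > cost_ceiling:
        raise PlateNotFoundError(
            "no plate found: no threshold produced a sufficiently circular component"
        )
    # near-ties in circularity (e.g. the plate vs a circular colony inside
    # it) resolve to the larger object
    best_cost = min(c[0] for c in candidates)
    cost, _area, comp = max(
        (c for c in candidates if c[0] <= best_cost + 0.05), key=lambda c: c[1]
    )
    comp = ndimage.binary_fill_holes(comp)
    rows, cols = np.nonzero(comp)
    center = (float(rows.mean()), float(cols.mean()))
    radius = float(np.sqrt(comp.sum() / np.pi))
    return Disc(center=center, radius=radius, circularity_cost=cost)


# ---------------------------------------------------------------------------
# colony segmentation

def _histogram_threshold(values: np.ndarray, n_bins: int = 256, min_separation: int = 10):
    """Threshold from the deepest valley between the two largest histogram modes.

    Returns ``(threshold, method)`` where method is ``"valley"`` or
    ``"otsu"`` (fallback when the valley is ambiguous).  Raises
    :class:`SegmentationError` when the histogram is effectively unimodal.
    """
    counts, edges = np.histogram(values, bins=n_bins)
    smooth = np.convolve(counts.astype(float), np.ones(5) / 5, mode="same")
    # zero-pad so modes at the histogram edges are still detected as peaks
    padded = np.r_[0.0, smooth, 0.0]
    peaks, props = signal.find_peaks(padded, prominence=smooth.max() * 0.02)
    peaks = peaks - 1
    if len(peaks) < 2:
        raise SegmentationError(
            "no colony/background separation: interior intensity histogram is unimodal"
        )
    order = np.argsort(props["prominences"])[::-1]
    # the two most prominent peaks at least `min_separation` bins apart
    first = peaks[order[0]]
    second = None
    for idx in order[1:]:
        if abs(peaks[idx] - first) >= min_separation:
            second = peaks[idx]
            break
    if second is None:
        raise SegmentationError(
            "no colony/background separation: histogram modes are not distinct"
        )
    left, right = sorted((first, second))
    between = smooth[left : right + 1]
    lowest = np.nonzero(between == between.min())[0]
    valley = left + int(lowest[len(lowest) // 2])  # middle of a flat valley
    # ambiguous valley: flat bottom or barely below the smaller peak
    depth = min(smooth[left], smooth[right]) - smooth[valley]
    if depth < 0.05 * min(smooth[left], smooth[right]):
        return float(threshold_otsu(values)), "otsu"
    threshold = 0.5 * (edges[valley] + edges[valley + 1])
    return float(threshold), "valley"


def segment_colony(
    image: PlateImage,
    plate: Disc,
    perimeter_mode: str = "polygon",
    rim_margin: float = 3.0,
) -> ColonyMask:
    """Binarize the plate interior at the histogram-valley threshold.

    The threshold separates the two dominant interior modes (agar
    background vs colony); the colony is taken as the brighter side.  Only
    the largest 4-connected component within the plate interior is kept.
    """
    interior = plate.interior_mask(image.shape, margin=rim_margin)
    if not interior.any():
        raise SegmentationError("plate interior is empty")
    values = image.intensities[interior]
    threshold, _method = _histogram_threshold(values)
    fg = interior & (image.intensities > threshold)
    if not fg.any():
        raise SegmentationError("no foreground pixels above the histogram threshold")
    return ColonyMask.from_grid(fg, perimeter_mode=perimeter_mode)


# ---------------------------------------------------------------------------
# time courses

def area_timecourse(
    masks,
    times=None,
    n_angular_bins: int = 360,
) -> pd.DataFrame:
    """Per-frame shape metrics for a time-ordered sequence of colony masks.

    Returns a table with columns ``t, area, perimeter, p2a, bf``; the
    maximum area and the time it is reached are stored in ``df.attrs``.
    """
    masks = list(masks)
    if len(masks) < 2:
        raise ValueError("a time course needs at least 2 frames")
    if times is None:
        times = np.arange(len(masks), dtype=float)
    rows = []
    for t, mask in zip(times, masks):
        sm = ShapeMetrics.from_mask(mask, n_angular_bins)
        rows.append({"t": t, "area": sm.area, "perimeter": sm.perimeter, "p2a": sm.p2a, "bf": sm.bf})
    df = pd.DataFrame(rows)
    i_max = int(df["area"].idxmax())
    df.attrs["max_area"] = float(df.loc[i_max, "area"])
    df.attrs["t_max_area"] = float(df.loc[i_max, "t"])
    return df


def classify_convexity(t, area, smooth_window: int = 5) -> str:
    """Classify an area growth curve as ``"convex"`` or ``"concave"``.

    The central-difference derivative dA/dt is smoothed with a
    ``smooth_window``-point moving average; the curve is convex when the
    smoothed derivative attains its maximum strictly in the interior
    (after the 2nd smoothed point), i.e. the expansion accelerates before
    it saturates.  A saturating-exponential curve (max slope at t = 0)
    classifies as concave, a logistic as convex.
    """
    t = np.asarray(t, dtype=float)
    area = np.asarray(area, dtype=float)
    if t.size < 10:
        raise ValueError("convexity classification needs >= 10 time points")
    deriv = np.gradient(area, t)
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(deriv, kernel, mode="valid")
    return "convex" if int(np.argmax(smoothed)) > 1 else "concave"
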