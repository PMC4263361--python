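"""Polar Fourier spectroscopy of radial spoke patterns on colony surfaces.

The colony image is resampled onto polar coordinates about the colony
centroid (one row per pixel of radius, a fixed number of angle bins per
revolution).  The radius range from the centroid to the outer colony
radius is divided into contiguous sections; within each section every
row is Fourier transformed along the angle axis and the per-frequency
magnitude mean ``m_k`` and standard deviation ``sd_k`` over the
section's ``N`` rows are accumulated.

Peak height: each frequency is scored against a local spectral baseline
``b_k`` (the mean magnitude over a window of neighboring frequencies,
excluding k and its immediate neighbors).  The t-statistic of the
contrast is

    t_k = (m_k - b_k) / (sd_k / sqrt(N)),

and the reported peak height is its effect-size form

    s_k = t_k / sqrt(N) = (m_k - b_k) / sd_k,

i.e. the excess of the mean spectrum over the local baseline in units of
the row-to-row spectral spread.  On noise-only sections the height stays
well below 1 (its null spread is ~1/sqrt(N)), so the conventional
significance cutoff of 1.5 is conservative, while a genuine spoke line —
which is coherent across the rows of a section — scores far above it.
DC and the Nyquist bin are excluded from both baseline and peak search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from sklearn.mixture import GaussianMixture

from colonymorph.containers import PlateImage
from colonymorph.masks import ColonyMask, largest_component

DEFAULT_ANGLE_BINS = 1024
SIGNIFICANCE_THRESHOLD = 1.5  # conventional peak-height cutoff
DEFAULT_SCORE_CAP = 50.0


@dataclass
class PolarImage:
    """Colony intensities resampled on a (radius, angle) grid."""

    values: np.ndarray  # (n_radii, n_angle_bins)
    radii: np.ndarray  # radius of each row, px (inward -> outward)
    center: tuple[float, float]
    n_angle_bins: int
    pixel_size: float = 1.0


@dataclass
class SectionSpectrum:
    """Mean/std FFT magnitude spectra of one radial section."""

    index: int  # 1-based section number, innermost first
    r_in: float
    r_out: float
    mean: np.ndarray  # m_k for k = 1 .. n_angle_bins/2
    sd: np.ndarray
    n_rows: int  # N, number of row spectra averaged
    frequencies: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.frequencies = np.arange(1, len(self.mean) + 1)


@dataclass(frozen=True)
class PatternResult:
    """Dominant spoke frequency and wavelength of one section."""

    section: int
    r_in: float
    r_out: float
    k_star: int
    score: float
    t_statistic: float
    wavelength: float  # physical units (pixel_size * px)
    significant: bool
    saturated: bool = False


# ---------------------------------------------------------------------------
# segmentation

def gmm_segment(
    image: PlateImage,
    center: tuple[float, float] | None = None,
    max_fit_pixels: int = 50_000,
    random_state: int = 0,
) -> ColonyMask:
    """Segment the colony with a 2-component Gaussian mixture.

    Features are per-pixel brightness and distance from ``center``
    (default: the image center).  The colony is the component with the
    higher mean brightness and the lower mean radius.  When the
    components are not separable (brightness means within one pooled
    standard deviation, or the brighter component is not the inner one)
    the function falls back to histogram-valley segmentation with a
    logged warning.
    """
    arr = image.intensities
    rows, cols = arr.shape
    if center is None:
        center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    rr, cc = np.mgrid[0:rows, 0:cols]
    radius = np.hypot(rr - center[0], cc - center[1])
    X = np.column_stack([arr.ravel(), radius.ravel()])
    scale = X.std(axis=0)
    if scale[0] < 1e-12:
        return _gmm_fallback(image, "image has no intensity variation")
    Xs = X / np.where(scale > 0, scale, 1.0)
    rng = np.random.default_rng(random_state)
    fit_idx = (
        rng.choice(len(Xs), size=max_fit_pixels, replace=False)
        if len(Xs) > max_fit_pixels
        else slice(None)
    )
    gmm = GaussianMixture(n_components=2, covariance_type="diag", random_state=random_state)
    gmm.fit(Xs[fit_idx])
    means = gmm.means_
    sds = np.sqrt(gmm.covariances_)
    bright = int(np.argmax(means[:, 0]))
    pooled_sd = np.sqrt(0.5 * (sds[0, 0] ** 2 + sds[1, 0] ** 2))
    if abs(means[0, 0] - means[1, 0]) < pooled_sd:
        return _gmm_fallback(image, "mixture brightness means overlap within 1 pooled sd")
    if means[bright, 1] >= means[1 - bright, 1]:
        return _gmm_fallback(image, "brighter mixture component is not the inner one")
    labels = gmm.predict(Xs).reshape(arr.shape)
    return ColonyMask(largest_component(labels == bright))


def _gmm_fallback(image: PlateImage, reason: str) -> ColonyMask:
    from colonymorph import metrics

    warnings.warn(f"GMM segmentation not separable ({reason}); "
                  "falling back to histogram-valley segmentation", stacklevel=3)
    plate = metrics.detect_plate(image)
    return metrics.segment_colony(image, plate)


# ---------------------------------------------------------------------------
# polar transform

def to_polar(
    image: PlateImage,
    center: tuple[float, float],
    n_angle_bins: int = DEFAULT_ANGLE_BINS,
    max_radius: float | None = None,
    radial_pitch: float = 1.0,
) -> PolarImage:
    """Resample the image on rays about ``center`` (bilinear interpolation).

    One row per ``radial_pitch`` pixels of radius; the angle axis covers
    [0, 2pi) uniformly, counterclockwise from the +col axis.
    """
    arr = image.intensities
    r0, c0 = center
    if not (0 <= r0 < arr.shape[0] and 0 <= c0 < arr.shape[1]):
        raise ValueError(f"center {center} lies outside the image {arr.shape}")
    if max_radius is None:
        max_radius = min(r0, c0, arr.shape[0] - 1 - r0, arr.shape[1] - 1 - c0)
    if max_radius <= 0:
        raise ValueError("max_radius must be positive")
    radii = np.arange(1, int(max_radius / radial_pitch) + 1) * radial_pitch
    theta = np.arange(n_angle_bins) * 2 * np.pi / n_angle_bins
    R, T = np.meshgrid(radii, theta, indexing="ij")
    coords = np.array([r0 - R * np.sin(T), c0 + R * np.cos(T)])
    values = ndi.map_coordinates(arr, coords, order=1, mode="nearest")
    return PolarImage(values, radii, (r0, c0), n_angle_bins,
                      pixel_size=image.pixel_size or 1.0)


def from_polar(polar: PolarImage, shape: tuple[int, int]) -> np.ndarray:
    """Inverse resampling of a polar image back to Cartesian (for round trips)."""
    rows, cols = shape
    r0, c0 = polar.center
    rr, cc = np.mgrid[0:rows, 0:cols]
    radius = np.hypot(rr - r0, cc - c0)
    theta = np.arctan2(-(rr - r0), cc - c0) % (2 * np.pi)
    pitch = polar.radii[1] - polar.radii[0] if len(polar.radii) > 1 else 1.0
    r_idx = (radius - polar.radii[0]) / pitch
    t_idx = theta / (2 * np.pi) * polar.n_angle_bins
    wrapped = np.concatenate([polar.values, polar.values[:, :1]], axis=1)
    return ndi.map_coordinates(wrapped, [r_idx, t_idx], order=1, mode="nearest")


# ---------------------------------------------------------------------------
# sectioned spectra and peak scores

def section_spectra(polar: PolarImage, n_sections: int = 10) -> list[SectionSpectrum]:
    """Mean/std FFT magnitude spectra over ``n_sections`` contiguous radius bands.

    Each row (fixed radius) is transformed along the angle axis; the DC
    term is dropped, leaving integer frequencies 1 .. n_angle_bins/2
    (cycles per revolution).
    """
    n_rows = len(polar.radii)
    if n_rows < n_sections:
        raise ValueError(f"polar image has {n_rows} rows < {n_sections} sections")
    magnitudes = np.abs(np.fft.rfft(polar.values, axis=1))[:, 1:]  # drop DC
    sections = []
    for i, idx in enumerate(np.array_split(np.arange(n_rows), n_sections)):
        if len(idx) < 2:
            raise ValueError(f"section {i + 1} has fewer than 2 rows")
        block = magnitudes[idx]
        sections.append(
            SectionSpectrum(
                index=i + 1,
                r_in=float(polar.radii[idx[0]]),
                r_out=float(polar.radii[idx[-1]]),
                mean=block.mean(axis=0),
                sd=block.std(axis=0, ddof=1),
                n_rows=len(idx),
            )
        )
    return sections


def spectral_baseline(mean: np.ndarray, k_index: int, window: int = 16) -> float:
    """Local baseline b_k: mean magnitude over neighboring frequencies.

    Uses up to ``window`` frequencies on each side of ``k_index``,
    excluding {k-1, k, k+1} and the Nyquist bin.  A local (rather than
    global) baseline keeps the score calibrated when interpolation
    colors the noise spectrum.
    """
    n = len(mean) - 1  # exclude Nyquist (last bin)
    lo = max(0, k_index - window)
    hi = min(n, k_index + window + 1)
    idx = [j for j in range(lo, hi) if abs(j - k_index) > 1]
    return float(np.mean(mean[idx]))


def peak_scores(
    section: SectionSpectrum,
    baseline_window: int = 16,
    score_cap: float = DEFAULT_SCORE_CAP,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Peak heights ``s_k`` and t-statistics ``t_k`` for every frequency.

    Returns ``(scores, t_statistics, saturated)``.  Frequencies with zero
    row-to-row spread and no excess over baseline score 0; a nonzero
    excess with zero spread saturates at ``score_cap`` (flagged).  The
    Nyquist bin is assigned -inf so it can never be selected.
    """
    if section.n_rows < 2:
        raise ValueError("peak scores need N >= 2 row spectra per section")
    m, sd, N = section.mean, section.sd, section.n_rows
    n_freq = len(m)
    scores = np.full(n_freq, -np.inf)
    tstats = np.full(n_freq, -np.inf)
    saturated = False
    for k in range(n_freq - 1):  # exclude Nyquist
        b = spectral_baseline(m, k, baseline_window)
        excess = m[k] - b
        if sd[k] == 0:
            if excess == 0:
                s = t = 0.0
            else:
                s = np.sign(excess) * score_cap
                t = s * np.sqrt(N)
                saturated = True
        else:
            s = excess / sd[k]
            t = excess / (sd[k] / np.sqrt(N))
        scores[k] = np.clip(s, -score_cap, score_cap)
        if abs(s) >= score_cap:
            saturated = True
        tstats[k] = t
    return scores, tstats, saturated


def dominant_frequency(scores: np.ndarray) -> int:
    """Frequency k* (cycles/revolution) with the highest peak score.

    Ties break toward the lowest frequency (np.argmax picks the first),
    favoring spokes over their wrinkle harmonics.
    """
    return int(np.argmax(scores[:-1])) + 1  # index 0 <-> k = 1; Nyquist excluded


def dominant_wavelength(k_star: int, outer_radius: float, pixel_size: float = 1.0) -> float:
    """Wavelength = outer section perimeter / spoke count."""
    if k_star < 1:
        raise ValueError("spoke frequency k* must be >= 1 (DC excluded)")
    return 2 * np.pi * outer_radius * pixel_size / k_star


def analyze_pattern(
    image: PlateImage,
    mask: ColonyMask | None = None,
    n_sections: int = 10,
    n_angle_bins: int = DEFAULT_ANGLE_BINS,
    threshold: float = SIGNIFICANCE_THRESHOLD,
    pixel_size: float | None = None,
    baseline_window: int = 16,
) -> list[PatternResult]:
    """Full pipeline: segment, polar-transform, and score all sections.

    Sections partition the radius range from the centroid to the outer
    colony radius (the background beyond the mask is excluded).
    """
    if mask is None:
        mask = gmm_segment(image)
    center = mask.centroid
    outer = float(np.max(mask.boundary_radii(360)))
    polar = to_polar(image, center, n_angle_bins=n_angle_bins, max_radius=outer)
    if pixel_size is None:
        pixel_size = image.pixel_size or 1.0
    results = []
    for section in section_spectra(polar, n_sections):
        scores, tstats, saturated = peak_scores(section, baseline_window)
        k_star = dominant_frequency(scores)
        s = float(scores[k_star - 1])
        results.append(
            PatternResult(
                section=section.index,
                r_in=section.r_in,
                r_out=section.r_out,
                k_star=k_star,
                score=s,
                t_statistic=float(tstats[k_star - 1]),
                wavelength=dominant_wavelength(k_star, section.r_out, pixel_size),
                significant=s > threshold,
                saturated=saturated,
            )
        )
    return results


def percent_significant(results: list[PatternResult]) -> float:
    """Percentage of sections whose peak height exceeds the cutoff."""
    if not results:
        raise ValueError("no section results")
    return 100.0 * sum(r.significant for r in results) / len(results)


def results_table(results: list[PatternResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {"section": r.section, "r_in": r.r_in, "r_out": r.r_out, "k_star": r.k_star,
             "score": r.score, "wavelength_um": r.wavelength, "significant": r.significant}
            for r in results
        ]
    )
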