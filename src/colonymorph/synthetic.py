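"""Synthetic plate scenes, wavelength tables and area time-courses.

Every downstream stage of the pipeline is exercised against data produced
here, with ground truth computed from the *continuous* parameterization
(dense polygonal quadrature of the boundary curve), never from the raster
— so the generator acts as an oracle that is independent of the code it
tests.

A scene is a bright circular plate on a dark background holding a colony
whose boundary is a harmonic perturbation of a circle,

    r(theta) = R * (1 + sum_m eps_m * cos(m*theta + phi_m)),

and whose interior carries a multiplicative angular intensity modulation
(radial "spokes" at integer frequency k, optionally a second
shorter-wavelength "wrinkle" frequency k2), plus clipped additive
Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from colonymorph.containers import PlateImage

#: number of polygon vertices used for continuous ground-truth quadrature
GROUND_TRUTH_VERTICES = 16384


@dataclass(frozen=True)
class PetalSpec:
    """Harmonic perturbation of a circular colony boundary.

    ``harmonics`` is a sequence of ``(mode m, amplitude eps_m, phase
    phi_m)`` triples; amplitudes are dimensionless fractions of the base
    radius and must sum to < 1 so the radius stays positive.
    """

    base_radius: float
    harmonics: tuple[tuple[int, float, float], ...] = ()
    center: tuple[float, float] | None = None  # defaults to the plate center

    def __post_init__(self) -> None:
        if self.base_radius <= 0:
            raise ValueError("base_radius must be positive")
        total = 0.0
        for m, eps, _phi in self.harmonics:
            if int(m) != m or m < 1:
                raise ValueError(f"harmonic mode must be an integer >= 1, got {m}")
            if eps < 0:
                raise ValueError(f"harmonic amplitude must be >= 0, got {eps}")
            total += eps
        if total >= 1:
            raise ValueError(
                f"harmonic amplitudes sum to {total:.3f} >= 1; the boundary "
                "radius would not stay positive"
            )

    def radius(self, theta: np.ndarray) -> np.ndarray:
        """Boundary radius r(theta)."""
        r = np.full_like(np.asarray(theta, dtype=float), self.base_radius)
        for m, eps, phi in self.harmonics:
            r += self.base_radius * eps * np.cos(m * np.asarray(theta) + phi)
        return r

    def radius_derivative(self, theta: np.ndarray) -> np.ndarray:
        """dr/dtheta, used by the arc-length quadrature oracle."""
        dr = np.zeros_like(np.asarray(theta, dtype=float))
        for m, eps, phi in self.harmonics:
            dr -= self.base_radius * eps * m * np.sin(m * np.asarray(theta) + phi)
        return dr

    @property
    def max_radius(self) -> float:
        return self.base_radius * (1 + sum(eps for _m, eps, _phi in self.harmonics))


@dataclass(frozen=True)
class SpokeSpec:
    """Angular intensity modulation of the colony interior.

    ``spoke_count`` is the primary (long-wavelength) frequency, in cycles
    per revolution; ``wrinkle_count`` an optional second, higher
    frequency.  Amplitudes are fractions of the colony base intensity,
    applied multiplicatively within ``radial_band`` (pixels from the
    colony center).
    """

    spoke_count: int = 0
    spoke_amplitude: float = 0.0
    wrinkle_count: int = 0
    wrinkle_amplitude: float = 0.0
    radial_band: tuple[float, float] = (0.0, np.inf)

    def __post_init__(self) -> None:
        for name in ("spoke_count", "wrinkle_count"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        for name in ("spoke_amplitude", "wrinkle_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        r_in, r_out = self.radial_band
        if not (0 <= r_in < r_out):
            raise ValueError(f"radial_band must satisfy 0 <= r_in < r_out, got {self.radial_band}")
        if self.wrinkle_count and self.spoke_count and self.wrinkle_count <= self.spoke_count:
            raise ValueError("wrinkle_count must exceed spoke_count when both are present")

    def modulation(self, theta: np.ndarray) -> np.ndarray:
        mod = np.ones_like(np.asarray(theta, dtype=float))
        if self.spoke_count:
            mod += self.spoke_amplitude * np.cos(self.spoke_count * theta)
        if self.wrinkle_count:
            mod += self.wrinkle_amplitude * np.cos(self.wrinkle_count * theta)
        return mod


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a synthetic plate photograph."""

    shape: tuple[int, int] = (360, 360)
    plate_center: tuple[float, float] | None = None  # defaults to image center
    plate_radius: float = 165.0
    plate_intensity: float = 60.0
    background_intensity: float = 10.0
    colony_intensity: float = 180.0
    petals: PetalSpec = field(default_factory=lambda: PetalSpec(base_radius=100.0))
    spokes: SpokeSpec = field(default_factory=SpokeSpec)
    noise_sd: float = 0.0
    max_intensity: float = 255.0
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.shape
        pc = self.plate_center or ((rows - 1) / 2.0, (cols - 1) / 2.0)
        object.__setattr__(self, "plate_center", pc)
        r0, c0 = pc
        edge = min(r0, c0, rows - 1 - r0, cols - 1 - c0)
        if self.plate_radius > edge:
            raise ValueError(
                f"plate (radius {self.plate_radius}) extends beyond the image "
                f"(nearest edge at {edge} px from the plate center)"
            )
        cc = self.petals.center or pc
        object.__setattr__(self, "petals", PetalSpec(self.petals.base_radius, self.petals.harmonics, cc))
        offset = float(np.hypot(cc[0] - r0, cc[1] - c0))
        if offset + self.petals.max_radius > self.plate_radius:
            raise ValueError(
                f"colony (max radius {self.petals.max_radius:.1f} px, offset "
                f"{offset:.1f} px) exceeds the plate radius {self.plate_radius}"
            )
        for name in ("plate_intensity", "background_intensity", "colony_intensity"):
            v = getattr(self, name)
            if not (0 <= v <= self.max_intensity):
                raise ValueError(f"{name}={v} outside [0, {self.max_intensity}]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Continuous-boundary shape statistics for a scene."""

    area: float
    perimeter: float
    p2a: float
    bf: float
    spoke_count: int

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "area_px2": self.area,
                "perimeter_px": self.perimeter,
                "p2a": self.p2a,
                "bf": self.bf,
                "spoke_count": self.spoke_count,
            }
        )


def boundary_ground_truth(
    petals: PetalSpec, n_vertices: int = GROUND_TRUTH_VERTICES
) -> GroundTruth:
    """Shape statistics from dense polygonal quadrature of r(theta).

    Area by the shoelace formula, perimeter by summed chord lengths of the
    ``n_vertices``-gon, BF as std/mean of the sampled radii (which for a
    harmonic boundary equals sqrt(sum eps_m^2 / 2) by orthogonality).
    """
    if n_vertices < 10_000:
        raise ValueError("ground truth requires >= 1e4 polygon vertices")
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    r = petals.radius(theta)
    x = r * np.cos(theta)
    y = r * np.sin(theta)
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    perimeter = float(np.hypot(np.diff(np.r_[x, x[0]]), np.diff(np.r_[y, y[0]])).sum())
    p2a = perimeter**2 / (4 * np.pi * area)
    bf = float(np.std(r) / np.mean(r))
    return GroundTruth(float(area), perimeter, float(p2a), bf, 0)


def make_plate_scene(spec: SceneSpec) -> tuple[PlateImage, GroundTruth]:
    """Render a plate scene and its continuous ground truth.

    Deterministic for a fixed ``spec.seed``.
    """
    rows, cols = spec.shape
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    pr, pc = spec.plate_center
    img = np.full(spec.shape, spec.background_intensity, dtype=float)
    img[(rr - pr) ** 2 + (cc - pc) ** 2 <= spec.plate_radius**2] = spec.plate_intensity

    cr, ccol = spec.petals.center
    d_row = rr - cr
    d_col = cc - ccol
    radius = np.hypot(d_row, d_col)
    theta = np.arctan2(-d_row, d_col) % (2 * np.pi)  # CCW from +col axis
    inside = radius <= spec.petals.radius(theta)

    intensity = np.full(spec.shape, spec.colony_intensity, dtype=float)
    s = spec.spokes
    if s.spoke_count or s.wrinkle_count:
        band = (radius >= s.radial_band[0]) & (radius <= s.radial_band[1])
        intensity = np.where(band, spec.colony_intensity * s.modulation(theta), intensity)
    img[inside] = intensity[inside]

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=spec.shape)
        img = np.clip(img, 0.0, spec.max_intensity)

    truth = boundary_ground_truth(spec.petals)
    truth = GroundTruth(truth.area, truth.perimeter, truth.p2a, truth.bf, s.spoke_count)
    labels = {"synthetic": True, "seed": spec.seed}
    return PlateImage(img, labels=labels), truth


def colony_raster_truth(spec: SceneSpec) -> np.ndarray:
    """Boolean raster of the true colony footprint (for IoU-style checks)."""
    rows, cols = spec.shape
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    cr, ccol = spec.petals.center
    radius = np.hypot(rr - cr, cc - ccol)
    theta = np.arctan2(-(rr - cr), cc - ccol) % (2 * np.pi)
    return radius <= spec.petals.radius(theta)


def write_scene(
    image: PlateImage, truth: GroundTruth, out_dir: str | Path, stem: str = "scene", bits: int = 8
) -> tuple[Path, Path]:
    """Write the scene as PNG (8-bit) or TIFF (16-bit) plus a ground-truth TSV sidecar."""
    from colonymorph import io as cio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".png" if bits == 8 else ".tif"
    img_path = out_dir / f"{stem}{suffix}"
    cio.write_image(img_path, image.intensities, bits=bits)
    truth_path = out_dir / f"{stem}_truth.tsv"
    truth.to_series().to_frame("value").to_csv(truth_path, sep="\t")
    return img_path, truth_path


# ---------------------------------------------------------------------------
# wavelength tables

def make_wavelength_table(
    agar_levels,
    model: str = "thick",
    scale: float = 7700.0,
    modulus=None,
    noise_sd: float = 0.05,
    n_per_level: int = 50,
    seed: int = 0,
    glucose_pct: float = 1.0,
    order: str = "secondary",
) -> pd.DataFrame:
    """Per-condition wavelength measurements drawn from an ESVS model.

    Each wavelength is the model prediction at that agar density times a
    multiplicative lognormal(0, ``noise_sd``) factor, emulating manual
    arc-length measurements around the colony rim.  Defaults give
    secondary-wrinkle (spoke) wavelengths on the order of a couple of
    millimetres at 1.5% agar with 50 measurements per condition.

    Returns a table with columns ``agar_pct, glucose_pct, order,
    wavelength_um``.
    """
    from colonymorph.wrinkles import DEFAULT_MODULUS, ESVSModel, predict_wavelength

    agar_levels = np.atleast_1d(np.asarray(agar_levels, dtype=float))
    if np.any(agar_levels <= 0):
        raise ValueError("agar levels must be positive percentages")
    if n_per_level < 1:
        raise ValueError("n_per_level must be >= 1")
    esvs = ESVSModel(kind=model, scale=scale)  # validates the model name
    modulus = modulus or DEFAULT_MODULUS
    rng = np.random.default_rng(seed)
    frames = []
    for x in agar_levels:
        lam = predict_wavelength(esvs, x, modulus)
        noise = np.exp(rng.normal(0.0, noise_sd, size=n_per_level)) if noise_sd > 0 else 1.0
        frames.append(
            pd.DataFrame(
                {
                    "agar_pct": x,
                    "glucose_pct": glucose_pct,
                    "order": order,
                    "wavelength_um": lam * np.ones(n_per_level) * noise,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# area time-courses

def make_area_timecourse(
    kind: str,
    a_max: float = 1000.0,
    rate: float = 0.5,
    t_max: float = 20.0,
    n_points: int = 50,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """A synthetic colony-area growth curve.

    ``kind="concave"`` is a saturating exponential ``A_max (1 - e^{-kt})``
    whose slope is maximal at t = 0; ``kind="convex"`` is a logistic with
    an interior inflection.  ``noise_sd`` is additive Gaussian noise as a
    fraction of ``a_max``.
    """
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    t = np.linspace(0.0, t_max, n_points)
    if kind == "concave":
        area = a_max * (1 - np.exp(-rate * t))
    elif kind == "convex":
        area = a_max / (1 + np.exp(-rate * (t - t_max / 2)))
    else:
        raise ValueError(f"unknown time-course kind {kind!r}; use 'convex' or 'concave'")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        area = area + rng.normal(0.0, noise_sd * a_max, size=n_points)
    return pd.DataFrame({"t": t, "area": area})
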