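"""Elastic-skin / viscoelastic-substrate (ESVS) wrinkle-wavelength models.

A stiff film (the "skin" of the colony, thickness h, modulus E_y) bonded
to a compliant substrate (the agar, modulus E_a) buckles under
compressive stress with a characteristic wavelength.  Two regimes are
relevant:

* thick substrate:  lambda = h * (E_y / E_a)^(1/3)
* thin substrate:   lambda = (h * H)^(1/2) * (E_y / E_a)^(1/6),

where H is the substrate thickness.  Since h, H and E_y are not measured
independently, each model is fitted with a single scale constant C that
absorbs them: lambda = C * |E*|(x)^(-1/3) (thick), C * |E*|(x)^(-1/6)
(thin), or simply lambda = C (agar-independent control).  The agar
modulus is the magnitude |E*| = sqrt(E'^2 + E''^2) of the complex
Young's modulus, with storage and loss moduli E'(x), E''(x) given by
quadratic functions of the agar density x (%).

Goodness of fit is R^2 = 1 - SS_res/SS_tot about the mean of the
per-condition mean wavelengths; it may be negative, and is exactly 0 for
the agar-independent model (whose least-squares constant is that mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

ESVS_KINDS = ("thick", "thin", "constant")
_EXPONENTS = {"thick": -1.0 / 3.0, "thin": -1.0 / 6.0, "constant": 0.0}


@dataclass(frozen=True)
class ModulusModel:
    """Quadratic storage/loss moduli of agar as functions of density x (%).

    ``E'(x) = a2 x^2 + a1 x + a0`` (kPa) and likewise for E''.  The
    default coefficients are a synthetic placeholder (storage modulus
    growing quadratically with density, loss at 10% of storage); the
    absolute scale of the modulus cannot affect the goodness of an ESVS
    fit — rescaling |E*| by c only rescales the fitted C by c^(1/3) or
    c^(1/6) — so the placeholder is adequate everywhere except when C
    itself must be interpreted in physical units.
    """

    storage_coeffs: tuple[float, float, float] = (25.0, 0.0, 0.0)  # a2, a1, a0
    loss_coeffs: tuple[float, float, float] = (2.5, 0.0, 0.0)
    valid_range: tuple[float, float] = (0.3, 6.0)

    def storage(self, x) -> np.ndarray:
        a2, a1, a0 = self.storage_coeffs
        x = np.asarray(x, dtype=float)
        return a2 * x**2 + a1 * x + a0

    def loss(self, x) -> np.ndarray:
        a2, a1, a0 = self.loss_coeffs
        x = np.asarray(x, dtype=float)
        return a2 * x**2 + a1 * x + a0


DEFAULT_MODULUS = ModulusModel()


def agar_modulus(x, model: ModulusModel = DEFAULT_MODULUS) -> np.ndarray:
    """|E*|(x) = sqrt(E'(x)^2 + E''(x)^2), warning on extrapolation."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("agar density must be positive")
    lo, hi = model.valid_range
    if np.any((x < lo) | (x > hi)):
        warnings.warn(
            f"agar density outside the modulus model's validity range [{lo}, {hi}]%: "
            "extrapolating", stacklevel=2)
    out = np.hypot(model.storage(x), model.loss(x))
    if np.any(out <= 0):
        raise ValueError("modulus model yields non-positive |E*| on the requested range")
    return out


@dataclass(frozen=True)
class ESVSModel:
    """A wavelength model: lambda = C * |E*|^exponent(kind)."""

    kind: str
    scale: float = 1.0  # C; thick absorbs h*E_y^(1/3), thin absorbs (hH)^(1/2)*E_y^(1/6)

    def __post_init__(self) -> None:
        if self.kind not in ESVS_KINDS:
            raise ValueError(f"unknown ESVS model kind {self.kind!r}; choose from {ESVS_KINDS}")
        if self.scale <= 0:
            raise ValueError("scale constant C must be positive")

    @property
    def exponent(self) -> float:
        return _EXPONENTS[self.kind]


def predict_wavelength(model: ESVSModel, x, modulus: ModulusModel = DEFAULT_MODULUS):
    """Predicted wrinkle wavelength at agar density x (%)."""
    if model.kind == "constant":
        x = np.asarray(x, dtype=float)
        out = np.full(x.shape, model.scale)
        return float(out) if out.ndim == 0 else out
    e = agar_modulus(x, modulus)
    out = model.scale * e**model.exponent
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class FitResult:
    kind: str
    scale: float  # fitted C
    ss_res: float
    ss_tot: float
    r_squared: float
    mean_type: str
    agar_levels: tuple
    observed_means: tuple
    predictions: tuple


def _condition_means(table: pd.DataFrame, mean_type: str, order: str | None) -> pd.Series:
    if order is not None and "order" in table.columns:
        table = table[table["order"] == order]
    if table.empty:
        raise ValueError("no wavelength rows after filtering")
    if np.any(table["wavelength_um"] <= 0):
        raise ValueError("wavelengths must be positive")
    grouped = table.groupby("agar_pct")["wavelength_um"]
    if mean_type == "geometric":
        return grouped.apply(lambda v: float(np.exp(np.mean(np.log(v)))))
    if mean_type == "arithmetic":
        return grouped.mean()
    raise ValueError(f"unknown mean_type {mean_type!r}; use 'geometric' or 'arithmetic'")


def fit_esvs(
    table: pd.DataFrame,
    kind: str,
    modulus: ModulusModel = DEFAULT_MODULUS,
    mean_type: str = "geometric",
    order: str | None = None,
    scale: str = "linear",
) -> FitResult:
    """Least-squares fit of an ESVS model to per-condition mean wavelengths.

    The single scale constant C is fitted to the per-agar-level mean
    wavelengths (geometric means by default) on the linear wavelength
    scale; ``scale="log"`` fits on log wavelength instead.  R^2 is
    computed about the mean of the observed means and may be negative.
    """
    if kind not in ESVS_KINDS:
        raise ValueError(f"unknown ESVS model kind {kind!r}; choose from {ESVS_KINDS}")
    means = _condition_means(table, mean_type, order)
    x = means.index.to_numpy(dtype=float)
    y = means.to_numpy(dtype=float)
    if kind != "constant" and len(np.unique(x)) < 2:
        raise ValueError(
            f"fitting the {kind}-substrate model needs >= 2 distinct agar levels"
        )
    f = np.ones_like(x) if kind == "constant" else agar_modulus(x, modulus) ** _EXPONENTS[kind]
    if scale == "linear":
        c = float(np.dot(f, y) / np.dot(f, f)) if kind != "constant" else float(np.mean(y))
    elif scale == "log":
        c = float(np.exp(np.mean(np.log(y) - np.log(f))))
    else:
        raise ValueError("scale must be 'linear' or 'log'")
    pred = c * f
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return FitResult(
        kind=kind, scale=c, ss_res=ss_res, ss_tot=ss_tot, r_squared=r2,
        mean_type=mean_type, agar_levels=tuple(x), observed_means=tuple(y),
        predictions=tuple(pred),
    )


# ---------------------------------------------------------------------------
# manual wavelength measurement

@dataclass(frozen=True)
class ManualWavelengths:
    wavelengths_um: np.ndarray
    angles_rad: np.ndarray  # subtended angle of each arc on the measurement circle
    geometric_mean: float
    arithmetic_mean: float
    scale_um_per_px: float


def manual_wavelength(
    d_i,
    d_img: float,
    plate_diameter_img: float,
    plate_diameter_actual_um: float = 35_000.0,
) -> ManualWavelengths:
    """Convert manual arc-length measurements to physical wavelengths.

    ``d_i`` are arc distances (px) between adjacent wrinkles/spokes
    measured around a circle of diameter ``d_img`` (px) near the colony
    rim; ``plate_diameter_img`` (px) calibrates against the actual plate
    diameter (3.5 cm by default).  Each wavelength is d_i * scale with
    scale = actual/image plate diameter; the subtended angles are
    theta_i = 2 d_i / d_img (arc over radius).
    """
    d_i = np.asarray(d_i, dtype=float)
    if d_i.size == 0:
        raise ValueError("no arc distances given")
    bad = np.nonzero(d_i <= 0)[0]
    if bad.size:
        raise ValueError(f"non-positive arc distance at index {int(bad[0])}: {d_i[bad[0]]}")
    if d_img <= 0 or plate_diameter_img <= 0 or plate_diameter_actual_um <= 0:
        raise ValueError("diameters must be positive")
    if d_img > plate_diameter_img:
        raise ValueError(
            "measurement-circle diameter exceeds the plate diameter in the image"
        )
    scale = plate_diameter_actual_um / plate_diameter_img
    wavelengths = d_i * scale
    angles = 2.0 * d_i / d_img
    return ManualWavelengths(
        wavelengths_um=wavelengths,
        angles_rad=angles,
        geometric_mean=float(np.exp(np.mean(np.log(wavelengths)))),
        arithmetic_mean=float(np.mean(wavelengths)),
        scale_um_per_px=float(scale),
    )
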