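# Methods

This note documents the models, statistics, and numerical choices behind
`colonymorph`, and what the synthetic-data generator does and does not
emulate.

## Shape statistics

**P2A.** For a segmented colony with perimeter *P* and area *A* (pixel
count), P2A = *P*²/(4π*A*) — the inverse of the isoperimetric quotient.
It equals 1 for a perfect circle and grows with rim roughness.

The perimeter of a rasterized shape needs care. Counting boundary pixels,
or summing the 8-connected chain with √2-weighted diagonals, systematically
overestimates the length of a smooth boundary (by ~26% and ~5%
respectively for a disc), which would inflate a disc's P2A to 1.6 or 1.11.
The default estimator therefore traces the sub-pixel marching-squares
contour of the mask and applies a circular moving average whose window is
1.8% of the contour's vertex count (clipped to [5, 25] vertices) before
summing segment lengths. The fractional window makes the estimate
scale-invariant: a disc of radius 100 px measures P2A = 0.9995, the same
mask upscaled 2× measures within 0.2% of that, and a square of side
100 px measures 1.235 against the exact 4/π ≈ 1.273 (−3%, the cost of
corner rounding). A literal `pixel-count` mode (number of foreground
pixels with a 4-neighbor background) is available for comparability with
pipelines that used the raw counting rule; it is not suitable for
comparing P2A against the circle anchor.

**Boundary fluctuation (BF).** The traced boundary is resampled densely
along its arc length, each sample's polar angle about the mask centroid
(counterclockwise from the +col axis, row axis pointing down) is binned
into 360 one-degree bins, and the per-bin mean radius r(θ) is formed
(multi-valued boundaries average). BF = std(r)/mean(r). For a harmonic
boundary r(θ) = R(1 + Σ ε_m cos(mθ + φ_m)) the exact value is
√(Σ ε_m²/2); the pipeline recovers it within 5% for the amplitudes the
generator produces. Residual BF for a rasterized disc is a digitization
artifact that decays like 1/R (1.2·10⁻³ at R = 100, 7·10⁻⁴ at R = 150).
A mask too small or elongated to populate every angular bin is rejected
rather than silently interpolated.

**Convexity of growth curves.** dA/dt by central differences, smoothed
with a 5-point moving average; a curve is "convex" when the smoothed
derivative peaks after its second point. A saturating exponential
(maximal slope at t = 0) classifies concave, a logistic convex; at 1%
multiplicative noise the classification is stable in ≥95/100 seeded
replicates.

## Segmentation

**Plate detection.** Candidate thresholds (16 equally spaced between the
image extremes by default) each yield a largest connected component
scored by its P2A (circularity cost). The minimum-cost component wins,
with one refinement: costs within 0.05 of the minimum are treated as
ties and resolve to the larger component, so the plate beats an equally
circular colony sitting inside it. If no component scores below the
configurable ceiling (1.6), the image is declared plate-free.

**Colony segmentation.** Intensities inside the detected plate (minus a
3 px rim margin) are histogrammed into 256 bins and smoothed (5-bin
average). The two most prominent peaks at least 10 bins apart define
background and colony modes; the threshold is the middle of the deepest
valley between them. A valley whose depth is under 5% of the smaller
peak falls back to Otsu's threshold; fewer than two separated peaks is
an error ("no colony/background separation"). The colony is assumed
brighter than the agar, and the largest 4-connected component is kept.

**GMM segmentation** (used by the Fourier pipeline): a 2-component
Gaussian mixture over per-pixel (brightness, distance-from-center)
features, fitted on a 50 000-pixel subsample and applied to all pixels.
The colony is the brighter, more central component; if the brightness
means overlap within one pooled standard deviation, or the brighter
component is the outer one, the histogram method above is used instead
(with a warning).

## Reaction–diffusion colony model

Cells are a continuous surface density ρ consuming a diffusible
nutrient g:

    ∂ρ/∂t = ∇·(D(ρ,g) ∇ρ) + ε ρ g − k_e ρ Θ(ρ − ρ_e)
    ∂g/∂t = D_g ∇²g − ε ρ g
    D(ρ,g) = D₁ ρ g Θ(ρ − ρ₀) Θ(g − g₀),   Θ(0) = 0.

Growth and consumption share the rate ε; diffusion is gated off below
the density gate ρ₀ = 0.01 and nutrient gate g₀ = 0.014, producing a
sharp front whose interaction with the random inoculum seeds the
branching ("petal") instability. The sink (rate k_e, gate ρ_e) models
cells escaping vertically instead of spreading — the behavior of
adhesion-deficient colonies; k_e = 0 is the fully surface-bound case.
All variables are rescaled/dimensionless, so the unstated coefficients
default to D₁ = D_g = ε = 1. Initial-glucose presets g_init ∈ {0.1,
0.4, 0.7} cover low/mid/high nutrient sweeps; ρ_e defaults to the 60th
percentile of the inoculum density range (0.066).

**Numerics.** Explicit Euler with dt = 0.064 and Δx = 0.8 on a 160×160
lattice; zero-flux Neumann boundaries via mirror ghost cells; diffusion
in flux-conservative form with face-averaged D, so with ε = k_e = 0
both Σρ and Σg are conserved to round-off (measured drift < 10⁻¹⁰ over
10³ steps) and with k_e = 0 the per-step mass gain equals ε·dt·Σρg
exactly. Initial condition: g uniform at g_init; ρ uniform-random in
(0.03, 0.09) inside a radius-16 circle (drawn in row-major site order
from one seeded generator, so a fixed seed fixes every byte). Negative
undershoots after an update are clamped to zero with the clamped mass
accumulated on the state; a non-finite field aborts with a CFL
diagnosis. Runs stop at n_steps (default 5000, ≈5 s on one core) or
when the mass gained per step falls below 10⁻⁸ of total mass.

**Measured phenomenology** (computed by the test suite): final colony
area increases strictly with g_init across seeds; enabling escape
(k_e = 0.1) shrinks the colony at matched glucose and seed; the area
curve flips concave→convex from the low to the high preset; run to
nutrient depletion, P2A rises abruptly to ~4–5 (petal formation) and
its maximum decreases with glucose (mid ≈ 4.9 > high ≈ 4.2). One caveat:
at the lowest preset (g_init = 0.1) the colony exhausts its nutrient
near the inoculum scale and stalls at P2A ≈ 1.1 — on this lattice size
petals need at least mid-level nutrient to express, so petal-formation
properties are tested from the mid preset up.

## Polar Fourier spoke analysis

The colony image is resampled about the mask centroid onto a polar grid
(bilinear interpolation; one row per pixel of radius; 1024 angle bins
per revolution so integer frequencies are spokes per revolution). The
radius range up to the outer colony radius is split into 10 contiguous
sections; each row's FFT magnitude (DC dropped) contributes to the
section's mean spectrum m_k and row-to-row spread sd_k over its N rows.

Each frequency is contrasted with a local baseline b_k — the mean of
m over frequencies within ±16 of k, excluding {k−1, k, k+1} and the
Nyquist bin. The t-statistic of the contrast is
t_k = (m_k − b_k)/(sd_k/√N), and the reported peak height is its
effect-size form s_k = t_k/√N = (m_k − b_k)/sd_k. The effect-size
scaling is what makes the conventional cutoff of 1.5 conservative:
under pure noise the maximum of s_k across ~500 frequencies is ≈3/√N
(well below 1.5 for the N ≈ 10–30 rows of a section), whereas a true
spoke line — coherent across rows — scores far above it (scores are
capped at 50 and flagged saturated; a zero spread with zero excess
scores 0). The local (rather than global) baseline keeps the score
calibrated where polar interpolation colors the noise spectrum at
oversampled small radii. Ties in the peak search break toward the
lowest frequency, favoring spokes over wrinkle harmonics.

Measured calibration: generator spoke counts k ∈ {4, 8, 12, 16, 24}
at amplitude ≥5× noise sd are recovered as the significant dominant
frequency in 100/100 seeded runs; rotationally symmetric noisy colonies
produce significant sections at a ~4% rate.

The section wavelength is the outer section perimeter over the spoke
count, λ = 2π·r_out·pixel_size/k*.

## ESVS wrinkle-wavelength models

A stiff colony skin (thickness h, modulus E_y) on a compliant agar
substrate (modulus E_a, thickness H) wrinkles at λ = h(E_y/E_a)^{1/3}
(thick substrate) or λ = (hH)^{1/2}(E_y/E_a)^{1/6} (thin substrate).
Since h, H, E_y are not separately measured, each model is fitted with
one scale constant C absorbing them: λ = C·|E*|^{−1/3}, C·|E*|^{−1/6},
or λ = C (agar-independent control). The agar modulus is the magnitude
|E*| = √(E′² + E″²) of the complex Young's modulus with quadratic
storage/loss laws E′(x), E″(x) in agar density x (%). The default
coefficients (E′ = 25x² kPa, E″ = 0.1E′) are placeholders: rescaling
|E*| by c only rescales C by c^{1/3} or c^{1/6} and cannot change R²
(property-tested), so fit quality is independent of the absolute
modulus calibration. Physical interpretation of C requires real
coefficients, supplied via `ModulusModel`.

Fitting is unweighted least squares of the per-agar-level mean
wavelengths (geometric means by default, arithmetic selectable; log
scale optional) for the single parameter C; R² = 1 − SS_res/SS_tot
about the mean of the observed means, allowed negative. The constant
model's least-squares C is exactly that mean, so its R² is identically
0. Measured: C is recovered within 5% from 6-level tables at 5%
lognormal noise in 20/20 seeds, and thick-generated data scores higher
R² under the thick than the thin model in 20/20 seeds.

**Manual measurements.** Arc distances d_i between adjacent
wrinkles/spokes on a circle of image diameter d_img convert to physical
wavelengths via the plate calibration (3.5 cm actual plate diameter):
λ_i = d_i · (35 000 µm / plate_diameter_img); subtended angles are
θ_i = 2d_i/d_img. Geometric and arithmetic means are reported.

## Synthetic-data generator

Scenes are a bright plate disc on a dark background holding a colony
whose boundary is a harmonic perturbation of a circle and whose
interior carries multiplicative angular modulation (spokes at frequency
k, optional finer wrinkles at k₂ > k) within a radial band, plus
additive Gaussian noise clipped to the intensity range — the simplest
noise model that exercises histogram segmentation. Ground truth (area,
perimeter, P2A, BF, spoke count) is always computed from the continuous
boundary by 16 384-vertex polygonal quadrature, never from the raster,
so it is an oracle independent of the code under test. Defaults (360²
image, plate radius 165 px, colony radius ~110 px, colony/plate/
background intensities 180/60/10 of 255, noise sd 6, spoke amplitude
0.2 of base) put segmentation and spectroscopy in the comfortable
regime of a well-exposed plate photograph.

What the generator does **not** emulate: uneven illumination, specular
reflections and condensation, texture inside real colonies, partially
out-of-frame plates, multiple colonies, and the radial drift of real
spoke patterns (spokes here are perfectly straight and equally spaced).
Passing tests therefore demonstrate correctness of the statistics and
the detection machinery under controlled conditions, not robustness to
real-plate artifacts.

Wavelength tables draw each measurement as (model prediction) ×
lognormal(0, sd) with 50 measurements per agar level at sd = 0.05 by
default, matching the scale of manual arc-length measurement scatter;
area time-courses are saturating-exponential (concave) or logistic
(convex) curves with optional additive noise.

## Problem sizes

Simulation studies use the full 160×160 lattice: ordering claims at
5000 steps (t = 320) per run, petal end states at 20 000–22 500 steps;
spectral studies use 360×360 scenes with 20 seeds per spoke count; the
full test suite completes in about two minutes on one core.

## Known limitations

- The traced-contour perimeter under-measures sharp corners (~3% for a
  square); shapes dominated by corners should use independent geometry.
- The escape term is a phenomenological stand-in for vertical growth,
  not a 3D model; time stepping is explicit with fixed dt.
- The GMM fallback decision uses brightness separability only; images
  whose colony is darker than the agar are out of scope.
- Spoke significance thresholds are calibrated on the generator's noise
  model; heavy-tailed sensor noise would need re-calibration.
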