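# Methods

## Geometry and q calibration

Every detector pixel is mapped to the scattering-vector magnitude
q = (4π/λ)·sin θ with θ = ½·arctan(r/L): λ the wavelength from λ = hc/E
(hc = 1.2398419 keV·nm), r the in-plane distance of the pixel center from
the beam center, L the sample–detector distance. The full trigonometric form
is kept — at typical geometries it differs from the small-angle
approximation 2πr/(λL) by less than 10⁻⁴ relative, but the exact form makes
the q → r inverse well defined for round-trip tests. Real-space lengths are
d = 2π/q.

Conventions: detector pixel (0, 0) is the top-left corner, pixel centers at
integer + 0.5, the beam center is fractional-pixel and may lie off-frame;
azimuth is measured counter-clockwise from the +column axis (toward −row on
a displayed image), wrapped to [0, 2π). The detector is assumed flat and
normal to the beam; no solid-angle, polarization or flat-field correction is
applied, matching the plain reduction the analysis is built around.

## Forward model

A phantom is a set of non-overlapping elliptical cells on the scan grid,
each with a concentric elliptical nucleus (semi-axes scaled by a factor
drawn from U(0.35, 0.55)). Every scan point scatters as I(q) = K·q^α + B in
counts·ms⁻¹·pixel⁻¹ (K quoted at q = 1 nm⁻¹; intensities are in arbitrary
units throughout — no absolute calibration is modeled). Defaults emulate
freeze-dried fibroblasts at reduced scale:

| parameter | default | why |
|---|---|---|
| α (both regions) | N(−4.1, 0.1), truncated to (−6, −2) | slightly below Porod's −4: heterogeneous scatterers with diffuse boundaries |
| cytoplasm K | LogNormal(ln 0.05, 0.4) | ~1 count/pixel/ms at q = 0.5 nm⁻¹, single frames noisy but region averages fittable |
| nucleus K | cytoplasm K × U(1.5, 3) | nucleus thicker and denser, hence brighter |
| B | U(0.001, 0.005) | small additive constant |
| instrument background | 0.02·q⁻³ + 0.002 | smooth, 10–30% of cytoplasmic intensity inside the fit band, so background subtraction is a meaningful test |
| background anisotropy | amplitude a ∈ [0, 1), ×(1 + a·cos 2(φ − φ₀)) | all anisotropy lives in the instrument term; cell scattering is isotropic |
| exposure | 1.34 ms | fastest detector frame rate |
| scan step | 0.5 µm × 0.5 µm | raster pseudo-resolution |

Alternative K modes: `porod` sets K = c·Δρ²·S per cell (Δρ the
electron-density contrast, S a perimeter-proxy interface area), used to test
that doubling Δρ quadruples the recovered K; `inverse_area` sets
K = scale/area, an anticorrelated population for power checks of the
small-vs-large statistics.

Frames are independent Poisson draws of expectation × exposure × flux (an
optional per-scan-row flux profile models the incoming beam drifting in
time along the slow axis). Counts are uint32; masked pixels carry the
sentinel 0xFFFFFFFF (−1 cast to uint32, Eiger-style gap semantics). The
q = 0 pixel, if present, borrows the nearest positive q for its expectation;
it sits behind the beamstop mask in any realistic geometry.

The **reduced-scale default geometry** keeps 13.0 keV and 75 µm pixels but
shortens the sample–detector distance to 0.15 m so that a 128×128 frame
with a centered beam spans q up to ~2.96 nm⁻¹ — covering both the
dark-field ROI (q ≤ 2.99 nm⁻¹) and the fit band. A full-size detector
(~2070×2167 pixels at 0.9 m) covers the same band at the same angles; the
shortened distance only rescales the pixel→q mapping. The mask is a
circular beamstop of 3.5 pixels.

What the phantoms deliberately do **not** emulate: realistic cell shapes and
internal filament/chromatin structure, detector point-spread and
charge-sharing, beamstop halo, time-dependent radiation damage. Passing
tests therefore demonstrate correctness of the reduction/segmentation/fit
machinery under the stated noise model, not biological fidelity.

## Reduction

Dark-field values are per-scan-point **sums** of counts over unmasked pixels
with q ≤ q_max ("integrating" a detector ROI; the mask is fixed per scan so
the scaling is uniform). Radial profiles use linear q bins — 300 over
(0, 2.99] nm⁻¹ by default, configurable to trade discretization error
against per-bin statistics — with membership by pixel-center q (no pixel
splitting) and per-bin **means** per contributing pixel, so profiles are
invariant to detector coverage and comparable across differently masked
regions. Bins without contributing pixels are flagged invalid (NaN), never
zero. At very low counts a bin's mean is a noisy non-negative quantity;
no attempt is made to debias it, and single-pattern profiles are simply
noisier at high q where per-bin expectations fall below one count.

## Segmentation

Cell/background separation uses the bright-foreground Bradley–Roth
criterion: pixel is foreground iff v > (1 + sensitivity)·(local window
mean), the mean computed with an integral image over a square window
(side = window_fraction × max image dimension, odd, clipped at borders).
This form is invariant under positive intensity rescaling and yields an
empty mask on constant images; the window must be a few cell diameters wide
so the local mean tracks the background level (window_fraction 0.35 on a
120-px grid; 1/8 is the starting default for full-size scans). Cleanup
fills holes and removes components below `min_object_pixels` (default 20).
Components are labeled 8-connected, ids in raster order of first pixel.

Each cell's nucleus is the largest connected component above the cell's own
Otsu threshold, computed on a 256-bin histogram of the cell's min–max
rescaled intensities by exhaustive maximization of the between-class
variance (ties resolved to the lowest threshold; constant-intensity cells
yield an empty, flagged nucleus). The bright class is the nucleus because
it is thicker and denser than the cytoplasm.

A cell's **surroundings** are the background-class pixels inside its
bounding box dilated by `margin` (default 20 px), assigned to at most the
nearest cell (by distance to the nearest cell-body pixel) when boxes
overlap, so surroundings sets are disjoint. Fragment filtering keeps cells
with N_nuc ≥ 30 and N_bg ∈ [5000, 10000] by default — empirical whole-cell
conditions for full-size (~3000×3000 position) scans, kept fully
configurable and rescaled by `reduced_scale_config()` (min 5, [50, 10000])
for the 120-px phantoms; rejected cells are relabeled "disregarded".

## Fitting

Profiles are exposure-normalized and background-subtracted bin-wise
(negative differences retained — clamping would bias B̂). Three background
strategies mirror the three analysis levels: the window-wide background
ROI, the per-cell surroundings, and — for single-pattern analysis — the
surroundings restricted to the same scan row as the analyzed pattern, which
cancels beam-intensity drifts because same-row patterns are acquired close
in time.

The fit minimizes Σ(I(qᵢ) − K·qᵢ^α − B)² over valid bins in the fit band
(unweighted by default, matching a plain non-linear least-squares
reduction; per-bin σ can be supplied for Poisson-weighted fitting, in which
case the covariance uses the whitened-residual form and its 68% intervals
are calibrated). Initialization: B₀ = min(I)/2 and a log-log regression of
I − min(I) for (K₀, α₀). Bounds: K ≥ 0, α ∈ [−8, 0] (physical decays only;
configurable), B free or fixed (B = 0 for analytic form-factor fits).
Solver: trust-region reflective with tolerances 10⁻¹⁴, which recovers
in-class noiseless parameters to 10⁻⁶ relative; non-convergence is a
flagged result, not an exception, and downstream statistics exclude
non-converged fits. At least 8 valid bins are required.

Form factors for validation are the orientation-averaged sphere
[3(sin u − u cos u)/u³]², thin rod 2 Si(x)/x − 4 sin²(x/2)/x², and thin
disc (2/x²)(1 − J₁(2x)/x), all normalized to 1 at q = 0; size
polydispersity is averaged by 61-point Gauss–Hermite quadrature over a
normal size law truncated to R > 0 (deterministic — no sampling noise in
reference values).

## Dose

D = (μ/ρ)·Φ·E·T/(Δy·Δz) in Gy, with μ/ρ = 2.55 cm² g⁻¹ (mass attenuation
coefficient over mass density of the "average protein" H₅₀C₃₀N₉O₁₀S at
13 keV), Φ the photon flux (default 1.7×10¹² s⁻¹), E the photon energy,
T the exposure per scan point and Δy, Δz the scan steps. The expression is
exactly multiplicative in each factor; defaults at T = 1.34 ms give
4.84×10⁶ Gy. It assumes full absorption of the deposited energy within the
illuminated voxel and no dose fractionation effects.

## Population statistics

Cell areas (body pixel counts) are split at the empirical 25/50/75
percentiles (linear interpolation); "small" and "large" are the first and
fourth quartiles. K and α distributions per region are compared with the
two-sample Kolmogorov–Smirnov test: D is the exact sup-distance between the
ECDFs, and the p-value is the asymptotic Kolmogorov distribution at
√(n_eff)·D with n_eff = n_x·n_y/(n_x+n_y) — within 0.01 of permutation
estimates at n = 30 per group. p-values are reported raw (no
multiple-testing correction). Groups smaller than 2 mark the summary
underpowered.

Orientation/anisotropy of a pattern is the second circular moment of its
azimuthal intensity distribution: intensity in a q band is binned into 36
azimuthal sectors, m₂ = Σ w(φ)e^{2iφ}/Σ w(φ); anisotropy = |m₂| and
orientation = ½·arg m₂ ∈ [0°, 180°). For a cos 2(φ−φ₀) modulation of
amplitude a this returns |m₂| = a/2 at φ₀; it is closed-form, rotation
equivariant, and brute-force testable. When the radial weighting is steep
(e.g. q⁻³), the effective intensity concentrates on the innermost rings
where sectors hold few pixels, and the recovered angle is limited by
azimuthal discretization (a few degrees) rather than by the estimator.

## Problem sizes and numerical choices

The standard study phantom is 20 cells on a 120×120 grid with 128×128
detector frames at 1.34 ms exposure; the anticorrelation power study uses
14 cells on 110×110 grids with 64×64 frames over 40 seeds; parameter
recovery uses 200 profile-level cells averaged over 400 patterns each.
These sizes were chosen so every stage retains realistic counting
statistics while the whole suite runs on a laptop-class single core. All
randomness flows through explicit integer seeds (phantom layout, Poisson
draws, test oracles), and the pipeline itself is deterministic: rerunning
on the same file and config reproduces every CSV byte-for-byte.

Known limitations: touching cells are not watershed-split (they merge into
one component); the fragment-filter defaults are scale-dependent and must
be set per scan size; unweighted fits report covariances under an i.i.d.
residual assumption that underestimates uncertainty on strongly
heteroscedastic single-pattern profiles (use the σ option when calibrated
intervals matter); and orientation analysis of weak, isotropic cellular
signals mostly reflects the instrument background term.
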