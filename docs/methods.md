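# Methods

## Signal model and protocols

All simulation and fitting rest on the spin-echo magnitude equation

    IS = PD · (1 − exp(−TR/T1)) · exp(−TE/T2).

A **T1 protocol** varies TR at a short fixed TE so the T2 factor is a
constant close to 1 (the default schedule is TR = 500, 700, 1000, 1500,
2000, 3000, 5000, 10000, 15000 ms at TE = 3 ms; the top TR is 5–20× any T1
of interest so the recovery plateaus inside the sweep). A **T2 protocol**
varies TE at a long fixed TR (TE = 10, 20, 26.2, 42, 68, 85, 102, 130, 160,
200 ms at TR = 10 000 ms) so the T1 factor is saturated. One published
description of the T2 series quotes TR = 1000 ms in passing while the
acquisition tables give TR = 10 000 ms; the package defaults to 10 000 ms
and does not attempt to reconcile the two. TE = 0 is accepted on frames as
the idealised TE → 0 limit of a T1 protocol (used by tests and the worked
example); real acquisitions always carry TE > 0.

## Fitting and readout

Pixels are fitted after normalising each intensity series to its maximum,
because PD scales the curve per pixel while the readout fractions below are
absolute. T1 uses `a − b·exp(−(c·x)/1000)` with x in ms and c in 1/s —
coefficients directly comparable with the usual printed form. The readout is
the inverse-function rule: T1 is the TR where the fitted curve reaches
1 − 1/e of the normalised signal,

    T1 = −1000·ln((a − (1 − 1/e))/b)/c,

computed with the full-precision constant (0.632120…, not the 4-digit
literal). For a = b = 1 this is exactly 1000/c. T2 uses `a·exp(−(c·x)/1000)`
without offset — an optional additive-offset variant was considered for
noisy-floor data but left out of the default model — and its 1/e readout is
exactly 1000/c regardless of normalisation.

Scalar fits (`fit_t1`, `fit_t2`, `fit_biexponential`) run trust-region least
squares (scipy `least_squares`, analytic Jacobians, ftol = xtol = gtol =
10⁻¹⁰, max 500 evaluations) initialised at a₀ = max(I), b₀ = a₀ − min(I),
c₀ = 1000/median(x). Non-convergence, zero signal variance (R² undefined),
and readout-domain violations (a ≤ 1 − 1/e, b ≤ 0, non-positive derived
time) all yield an *invalid* result with time 0 rather than an exception, so
map loops never abort.

Map-level fitting (`fit_map`) uses `batch_fit`, a vectorised solver of the
same least-squares objective: for a fixed rate c the model is linear in its
amplitude coefficients, so the amplitudes have a closed form and c is found
by a coarse logarithmic grid (80 points over 10⁻³–10³ s⁻¹) followed by 60
golden-section iterations, all vectorised across pixels. On clean data it
agrees with the scalar solvers to ~10⁻¹⁰ relative (asserted in tests); a
128×128 map fits in about a second, where per-pixel scipy calls take
minutes because zero-signal background pixels converge slowly.

The bi-exponential option fits the two-component analogue (T1:
`a − b₁e^(−c₁x/1000) − b₂e^(−c₂x/1000)`; T2: sum of two decaying terms),
needs ≥ 5 points, is seeded from the mono fit with the rates split 3× up and
down, and reports the amplitude-dominant component's 1000/c as the map
value with both components kept. When the two rates collapse within 0.1%
the model is unidentifiable and the mono result is returned (logged). The
parameterisation is the package's own choice; no claim is made that it
matches any particular published two-pool convention.

## Masking, statistics and views

Pixels whose fit is invalid or whose R² = 1 − SS_res/SS_tot falls below the
threshold (default 0.4, configurable) are replaced with 0 and masked; the
invariant `time_ms ≠ 0 ⇔ mask` holds exactly on every map. Under the null
(pure-noise pixels) a globally optimal 3-parameter fit to 9 points reaches
R² ≥ 0.4 with probability ≈ 0.08, so roughly 92% of zero-signal background
is removed on a T1 protocol (≈ 97% on the 2-parameter T2 fit); the
threshold trades noise rejection against retention of low-SNR tissue.

ROI statistics are mean ± *population* standard deviation (divide by n, the
convention stated in every text report) over mask-true pixels only, with the
pixel count reported so the SD is auditable. Line profiles sample the
Bresenham rasterisation of the segment — one row of pixels — with distances
from the physical pixel spacing; masked pixels contribute their stored 0.
Histograms cover kept pixels only and their counts sum to the ROI pixel
count. CSV export writes the time grid at %.17g (lossless for float64);
PNG uses a documented matplotlib colormap with a colorbar and black reserved
for masked pixels; the text report echoes the schedule, all options and the
ROI statistics. A Welch two-sample t-test between the kept pixel
populations of two maps (`compare_rois`) is provided for between-map
comparisons; no multiple-testing correction is applied.

## DICOM layer

One file per 2D frame, MR Image Storage, explicit-VR little endian, carrying
RepetitionTime (0018,0080), EchoTime (0018,0081), PixelSpacing and
SliceThickness. Stored pixels are 16-bit unsigned with
RescaleSlope/Intercept applied on read; integer-valued input in range is
stored with slope 1 and round-trips bit-exactly, anything else is scaled to
the 16-bit range (relative quantisation error ≤ 8·10⁻⁶). Discovery uses a
DICOMDIR index when present and a recursive scan otherwise; files are
grouped by SeriesInstanceUID with a geometry fallback, unreadable files are
logged and skipped, and loading sorts frames by the varied timing parameter,
infers the protocol from which tag varies, and averages duplicate timing
points (the fit expects one intensity per point). Multi-frame enhanced
DICOM, vendor private tags and networking are out of scope. Bit depth and
signedness of scanner exports vary by vendor; 16-bit unsigned is assumed.

## Phantom simulator

Geometry is rasterised at pixel centres ((i + 0.5)·spacing, no
partial-volume averaging) so label and component counts are exact;
`pixel_spacing = FOV/matrix`. The capillary preset packs the requested
number of capillaries into deterministic concentric rings (outermost ring
first, 0.05 mm clearance, optional seeded jitter) and raises a geometry
error when they cannot fit. Compartment defaults: demineralised water at
PD 1, T1 2900 ms, T2 1800 ms; capillary walls and background at PD 0. The
bioreactor preset is a concentric cross-section — cell compartment
(PD 0.9, default T1 1100 ms / T2 171 ms, the early-culture values of 3D
MCF-7 breast-cancer cultures, falling to about 673/128 ms in late culture)
inside a culture-medium annulus (PD 1, T1 2500 ms, T2 900 ms) pierced by
hollow fibers of 1.3 mm outer diameter — at FOV 20 mm on a 128×128 grid,
a scale that keeps simulation-plus-fit under two seconds per protocol.

Noise is Rician: independent Gaussians of width σ (in PD units) on two
quadrature channels followed by the modulus, giving Rayleigh statistics
(mean σ√(π/2)) where PD = 0. Frames are scaled by 40 000 and rounded to
integer counts in the 16-bit range by default, as a scanner stores them,
making DICOM round-trips bit-exact; `intensity_scale=None` yields raw
floats for analytic work. The simulator does **not** model slice profiles,
B1 inhomogeneity, flow, chemical shift, or partial-volume edges, so passing
recovery tests demonstrate correctness of the fitting chain on data obeying
the signal equation — not robustness to every artefact of real scans.

## Noisy-data settings and what recovery tests show

At SNR ≈ 50 (channel σ = 0.018 against the cell compartment's peak signal
≈ 0.88) the normalise-then-readout estimator carries a small positive bias
(~2–3% for T1 ≈ 700 ms on the 9-point schedule) because the per-pixel
normaliser is itself noisy and the readout is nonlinear in the
coefficients. The package's standard noisy-data settings — the pipeline's
3×3 mean pre-smoothing step, and compartment ROIs eroded by 2 px to exclude
partial-volume edge pixels — reduce this to well under 1% for T1 and under
2.5% for T2, which is what the acceptance-style recovery checks exercise
(128×128, early- and late-culture parameter sets, seeded). Fitting
unnormalised unit-scale data avoids the normaliser noise entirely and is
used where PD is known to be uniform.

## GAG chain

T1 enters in ms and is converted to seconds internally; relaxivity is
implemented as 3.9 L·mmol⁻¹·s⁻¹ (the standard unit, required for the rate
difference to come out in mmol/L). The Donnan fixed-charge-density formula
is used in its square-root form,
`FCD = −2·[Na⁺]·(√(r) − 1/√(r))` with r the cells/media concentration
ratio; its leading minus sign makes FCD positive when cells exclude the
anionic agent, and the GAG formula consumes |FCD| so the sign convention
cannot change the result. The GAG conversion divides by 2 charges per GAG
monomer, multiplies by 502.5 g/mol (→ mg/L) and by 10⁻³ (→ mg/mL); this is
the only dimensional reading that places physiologic FCD (tens of mM) at
the mg/mL scale observed in 3D cultures. The bracket is monotone in r, so a
closed-form inverse exists (`fcd_to_gd_ratio`) and is used for round-trip
validation. The module operates on compartment-level scalar panels; per-pixel
FCD maps and contrast-diffusion kinetics are out of scope.

## Known limitations

* The T1 readout formula applies the absolute fraction 1 − 1/e to
  max-normalised data; when the largest TR does not fully recover the
  plateau (TR_max ≲ 5·T1) this biases T1 low by up to ~1%. The schedules in
  use keep TR_max ≥ 5·T1 for the tissues of interest.
* The R² threshold (0.4) is an empirical noise gate, not a significance
  level; ~8% of pure-noise pixels pass it on a 9-point T1 protocol.
* Bi-exponential component recovery is reliable only with dense sampling
  and well-separated rates (demonstrated at 40 points, rates 10× apart).
* The simulator's geometry is 2D and axial; 3D volumes and non-axial
  orientations are not modelled.
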