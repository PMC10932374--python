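# relaxmap

Quantitative T1/T2 relaxometry for small-sample MRI — bioreactor cell
cultures and resolution phantoms imaged on a clinical 1.5 T scanner — with a
digital phantom simulator so every processing stage can be validated without
scanner time, plus dGEMRIC-style glycosaminoglycan (GAG) quantification from
pre-/post-contrast T1.

## What it computes

A 2D spin-echo magnitude image depends on three tissue parameters (proton
density PD, longitudinal relaxation time T1, transverse relaxation time T2)
and two sequence parameters (repetition time TR, echo time TE):

    IS = PD · (1 − e^(−TR/T1)) · e^(−TE/T2)

**T1 mapping (saturation recovery).** Acquire the slice at several TR with a
short fixed TE, normalise each pixel's intensity series to 1, and fit

    IS(TR) = a − b·e^(−(c·TR)/1000)        (c in 1/s, TR in ms)

T1 is the TR at which the recovery reaches 1 − 1/e ≈ 0.6321 of the
normalised signal, read out through the inverse function
`T1 = −1000·ln((a − (1 − 1/e))/b)/c`, which is exactly `1000/c` for the
ideal a = b = 1.

**T2 mapping.** Acquire at several TE with a long fixed TR and fit
`IS(TE) = a·e^(−(c·TE)/1000)`; T2 is the TE at which the curve drops to
1/e ≈ 0.3679 of its maximum, i.e. `1000/c`.

Each pixel also gets a coefficient of determination R²; pixels with R² below
0.4 (default) are treated as noise, replaced with 0 and excluded from all
statistics — the solid-black background of a typical relaxation map.

**GAG quantification.** The anionic contrast agent Gd-DTPA²⁻ partitions
between cell mass and culture medium according to the fixed negative charge
carried by GAG. From pre-/post-contrast T1 of each compartment:

    [Gd]     = (1/R)·(1/T1_post − 1/T1_pre)                 R = 3.9 L·mmol⁻¹·s⁻¹ at 1.5 T
    FCD      = −2·[Na⁺]·(√([Gd]_cells/[Gd]_media) − √([Gd]_media/[Gd]_cells))
    GAG      = |FCD|/2 · 502.5 · 10⁻³   mg/mL

with [Na⁺]_media = 154 mM, GAG molar mass 502.5 g/mol and 2 mol charge per
mol GAG.

The package also ships a digital phantom generator: a capillary resolution
phantom (16 capillaries of 2.3 mm outer diameter / 0.4 mm wall in a 13.8 mm
test tube, FOV 5 cm on a 512×512 matrix → 0.098 mm/pixel) and a hollow-fiber
bioreactor cross-section (a cell compartment inside a culture-medium annulus),
rendered through the signal equation with Rician magnitude noise and written
as standard DICOM series.

## Worked example

The 9-point saturation-recovery series of a T1 = 2250 ms sample
(TR = 500 … 15 000 ms, normalised intensities):

```python
import relaxmap as rm

tr    = [500, 700, 1000, 1500, 2000, 3000, 5000, 10000, 15000]
is_t1 = [0.1993, 0.2674, 0.3588, 0.4866, 0.5889, 0.7364, 0.8916, 0.9883, 0.9987]
fit = rm.fit_t1(tr, is_t1)
print(f"T1 = {fit.time_ms:.1f} ms,  R^2 = {fit.r_squared:.6f}")
print(f"a = {fit.a:.4f}, b = {fit.b:.4f}, c = {fit.c:.5f} 1/s")
```

prints

```
T1 = 2250.0 ms,  R^2 = 1.000000
a = 1.0000, b = 1.0000, c = 0.44441 1/s
```

i.e. the fit recovers the generating relaxation time exactly (1000/0.44441 ≈
2250 ms) with a perfect fit on noiseless data.

End-to-end from the shell — simulate a noisy bioreactor acquisition, write
it as DICOM, map it back:

```sh
relaxmap simulate --preset bioreactor --protocol T1 --noise-sigma 0.018 --seed 1 --out dcm/
relaxmap t1map --input dcm/ --roi circle:64,64,20 --smooth mean3 --out t1demo
```

```
wrote 9 frames to dcm/
T1 = 1246.8 ± 392.1 ms over 1257 pixels (R^2 >= 0.4)
```

The circular ROI spans both the cell compartment (ground truth T1 = 1100 ms)
and the medium-filled fiber lumina (T1 = 2500 ms), hence the intermediate
mean and large pixel spread; selecting the cell compartment alone (e.g. via
`RoiSelection.from_mask` on the simulator's label grid) recovers
1109.7 ± 16.4 ms over 916 pixels. Outputs are a colormapped PNG (masked
pixels black), a lossless CSV grid and a plain-text report with the ROI
statistics and every option used. `relaxmap gag --panel panels.csv --out
report.csv` runs the contrast-to-GAG chain over a table of T1 panels.

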