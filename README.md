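# oeot — oxygen-enhanced optoacoustic tomography analysis

`oeot` analyses multispectral optoacoustic (photoacoustic) tomography scans
acquired under a breathing-gas challenge. Switching the breathing gas from
medical air (21 % O2) to pure oxygen perturbs the vascular oxygen
saturation; how strongly, how fast and *where* a tumour responds reports on
the functionality of its vasculature — information that the usual static
oxygenation snapshot cannot provide, because poorly perfused and well
perfused tumours can look identical at baseline.

The package is aimed at preclinical imaging groups who have a multispectral
image time series, region-of-interest masks and a gas schedule, and want
the standard oxygen-enhanced (OE-OT) metric panel together with the
accompanying histology and MRI quantifications.

## What it computes

**Spectral unmixing.** Per pixel (or per ROI-averaged spectrum), the signal
at wavelengths λ₁…λₙ (default: 15 wavelengths, 700–880 nm) is modelled as
`s(λ) ≈ ε_HbO2(λ)·c_HbO2 + ε_Hb(λ)·c_Hb` and inverted by pseudoinverse
least squares. From the component weights: `THb = c_HbO2 + c_Hb` and the
apparent saturation `SO2^MSOT = c_HbO2 / (c_HbO2 + c_Hb)` (apparent,
because light fluence is not corrected; only ratios and changes are
meaningful).

**Challenge kinetics.** From the smoothed SO2^MSOT trace of each region:
baseline `SO2(Air)`, post-challenge plateau `SO2(O2)`, amplitude
`ΔSO2 = SO2(O2) − SO2(Air)`, and time to half-maximum `T1/2` (first
linearly interpolated crossing of the half-amplitude level after the
air→O2 switch; undefined when the amplitude does not exceed twice the
baseline noise). On a coarse 225 µm grid, pixels with `ΔSO2 > 0.03` are
classified as *responding*; the **Responding Fraction (RF)** is their share
of valid tumour pixels.

**Spatial analysis.** Concentric 0.5 mm depth shells from the Euclidean
distance transform of the tumour mask; rim = outer two shells (1 mm), core
= the rest; depth profiles of any metric map; tumour area; and a
heterogeneity statistic `η = J / (2p(1−p))`, where `J` is the fraction of
discordant 4-neighbour pixel pairs and `p` the responding fraction — `η ≈ 1`
for spatially random response, `η ≪ 1` for a compact rim–core pattern,
independent of tumour size and resolution.

**Histology.** From two-channel fluorescence fields (endothelial CD31 +
Hoechst 33342): vessel segmentation, CD31 Vascular area Fraction (VF),
Perfused Area (PA; tissue within 100 µm of a vessel, the approximate oxygen
diffusion distance) and mean Hoechst Intensity (HI).

**MRI.** Pixel-wise monoexponential relaxometry (T1/T2*) and Tofts–Kermode
DCE fitting, `Ct(t) = Ktrans ∫ Cp(τ) e^{−kep(t−τ)} dτ`, for the transfer
constant `Ktrans`.

**Digital phantoms.** A generator of two-compartment (rim/core) tumour
phantoms with known ground truth for every quantity above, including two
preset phenotypes: a poorly perfused, rim-responding tumour ("PC3-like")
and a blood-rich, heterogeneously responding one ("LNCaP-like"). All tests
run on these phantoms; no animal data are required.

## Worked example

```python
from oeot import pc3_like_spec, build_truth, render_msot, run_oeot

spec = pc3_like_spec(seed=7)          # poorly perfused phenotype + noise
truth = build_truth(spec)             # ground-truth maps and SO2 kinetics
series = render_msot(truth)           # 15-wavelength signal stack, 75 um
report = run_oeot(series, truth.tumour_mask, spec.schedule,
                  healthy_mask=truth.healthy_mask, scan_id="pc3_demo")
print(report.table.round(3).to_string())
```

prints

```
         so2_air  so2_o2  delta_so2  t_half_s     rf     thb
region
tumour      0.27   0.314      0.044   276.798  0.537  23.468
healthy     0.49   0.587      0.097    76.488  1.000  60.024
rim         0.27   0.326      0.055   275.269  0.755  25.435
core        0.27   0.276      0.006   284.588  0.044  18.745
shell_1     0.27   0.344      0.073   277.079  0.974  26.956
shell_2     0.27   0.299      0.029   270.973  0.466  23.472
shell_3     0.27   0.278      0.008   200.398  0.067  19.890
shell_4     0.27   0.272      0.001       NaN  0.000  16.479
```

Reading the table: tumour and healthy tissue share neither baseline
(`so2_air` 0.27 vs 0.49) nor speed (`t_half_s` ≈ 277 s vs 76 s); the
response is concentrated in the rim (`delta_so2` 0.055 vs 0.006 in the
core; `rf` 0.76 vs 0.04), and the 0.5 mm shell rows resolve the monotone
decay of the response with depth. `report.eta` (here 0.22) quantifies how
compact that response pattern is, and
`report.depth_profiles["delta_so2"]` (`[0.070, 0.028, 0.009, −0.000]`)
gives the per-shell amplitude profile on the 225 µm analysis grid. The
`shell_4` half-time is undefined (NaN) because its residual amplitude falls
below the noise gate — exactly how weak responders are treated in region
analyses.

A command-line interface wraps the same pipeline for on-disk data
(`oeot run -c config.yaml`, `oeot phantom`, `oeot histo`, `oeot mri`).

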