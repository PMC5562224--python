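# Methods

This note records the models implemented in `oeot`, the defaults and why
they were chosen, what the digital phantoms emulate, and the known limits
of the approach.

## Spectral unmixing

The forward model treats the reconstructed optoacoustic image value at
wavelength λ as proportional to the local absorbed energy of a two-absorber
mixture, `s(λ) = ε_HbO2(λ)·c_HbO2 + ε_Hb(λ)·c_Hb`. Weights are estimated by
unconstrained least squares via the pseudoinverse of the (n_wavelengths × 2)
design matrix. Scope is fixed at two chromophores: in the 700–880 nm window
haemoglobin dominates tissue absorption, and adding water/lipid columns to
a 15-wavelength design mainly inflates variance.

* **Extinction spectra.** The packaged table
  (`data/hb_extinction_synthetic.csv`) is a *synthetic* compilation
  approximating the standard tabulated haemoglobin spectra: deoxy-Hb peak
  near 760 nm, isosbestic crossing near 798 nm, oxy-Hb rising beyond
  800 nm. Unmixing is invariant to an overall rescaling of the table, so
  only this spectral shape matters; users with a preferred compilation can
  supply their own CSV (`wavelength_nm,eps_hbo2,eps_hb`).
* **Negative weights.** The unconstrained estimator can return negative
  weights under noise. Raw weights are retained for diagnostics; negatives
  are clipped to zero only when forming THb and SO2, which keeps SO2 in
  [0, 1] without changing the linear estimator.
* **Validity.** Pixels (or frames) whose clipped THb falls below 10⁻⁶ ×
  the median THb are flagged invalid instead of producing 0/0 saturations.
* **Grids.** Per-pixel analysis runs on a coarser grid (default 225 µm from
  75 µm native, i.e. a 3×3 block mean) to gain spectral SNR per pixel. The
  block mean is applied to the *signal* images before unmixing; since
  unmixing is linear the two orders coincide exactly in the noiseless case
  and the chosen order is the better-conditioned one under noise.
* **Ill-posedness.** Wavelength sets that cannot separate the chromophores
  (one wavelength, repeated isosbestic wavelengths) are rejected via a
  condition-number check on the design matrix.
* **Fluence.** No fluence correction is applied anywhere; SO2^MSOT is an
  apparent metric. The phantom can impose a wavelength-dependent fluence to
  demonstrate the resulting bias, and the test suite verifies that flat
  fluence leaves SO2 unbiased while spectrally varying fluence does not.

## Challenge kinetics

The gas schedule is an explicit input (JSON); the phantom default is
300 s air / 1200 s O2 / 300 s air at one frame per 11.5 s.

* **Smoothing:** centred moving average over valid samples, default window
  5 frames (~58 s) — wide enough to suppress frame noise, narrow enough to
  leave half-times of one frame-interval scale resolvable. Edges use
  shrinking windows; invalid samples neither receive nor contribute values.
* **Plateaus:** `SO2(Air)` is the mean of the last 5 valid samples before
  the air→O2 switch, `SO2(O2)` the mean of the last 5 valid samples of the
  O2 segment (both counts configurable; the plateau is defined by segment
  end because no canonical count exists).
* **T1/2:** first crossing of `SO2(Air) + ΔSO2/2` after the switch,
  linearly interpolated between frames and measured from the switch; ties
  broken by the earliest crossing. T1/2 is reported as undefined when
  `|ΔSO2| ≤ 2 × SD(baseline samples)` — the analogue of excluding regions
  whose change does not rise above background noise. Two estimator
  properties are worth knowing: (i) because the plateau is averaged before
  full saturation, the half-amplitude target sits slightly low, giving a
  modest negative bias for half-times that are long relative to the O2
  segment; (ii) under frame noise the *first*-crossing convention is
  early-biased. The acceptance suite quantifies both via median recovery
  error on seeded cohorts.
* **Response classification:** per-pixel ΔSO2 on the coarse grid, computed
  with the same baseline/plateau logic after per-pixel smoothing (whether
  smoothing precedes thresholding is not canonical; it is on by default and
  configurable). Responding = ΔSO2 > 0.03; pixels below −0.03 are reported
  in a separate negative mask and never counted in RF, which is one-sided
  by definition. No drift detrending is applied.

## Shells, rim/core and η

Depth shells come from the Euclidean distance transform (not iterated
erosion): shell k holds pixels with boundary depth in ((k−1)·0.5, k·0.5]
mm. The EDT measures distance to the nearest background pixel *centre*;
the true boundary lies between 0 px (smooth oblique contours) and 0.5 px
(axis-aligned edges) inside that distance, so depths are offset by 0.25 px
— the compromise that keeps shell areas of discretised convex masks within
a few percent of the analytic values. Rim = shells 1–2 (outer 1 mm); depth
analyses use the outer 4 shells individually. Masks too thin for the
requested shells return fewer shells with a `truncated` flag.

**η is a reconstruction.** The original supplementary definition of the
heterogeneity parameter was not available, so `oeot` adopts a normalised
join-count discordance statistic: with `p` the responding fraction in the
ROI and `J` the fraction of 4-neighbour in-ROI pixel pairs with discordant
response class, `η = J / (2p(1−p))` (0 when p ∈ {0,1}). This satisfies
every stated property of the original statistic — bounded, ≈ 1 for
spatially random response at any p, ≪ 1 for compact rim–core patterns,
higher for scattered than compact response at equal p, and insensitive to
tumour size and rendering resolution — but it is a stand-in, not a claim
about the original formula. Connectivity is configurable (4 or 8).

## Histology

Vessel identification details were likewise not available; the
implementation is a conventional fluorescence pipeline, all parameters
exposed: rolling-ball background subtraction (radius 0.05 mm), Otsu
threshold, removal of components below 50 µm², hole filling. Perfused Area
uses an exact Euclidean dilation (distance transform ≤ 100 µm), so
overlapping halos count once; PA(0) = VF identically and PA is monotone in
the radius. HI is the plain mean of the Hoechst channel over the tumour
mask.

## MRI

Relaxometry fits `S(t) = S0·e^(−t/τ)` per pixel by Levenberg–Marquardt
initialised from a log-linear regression; degenerate pixels (constant
signal, non-positive decay, non-convergence) yield NaN, never an error.
The DCE fitter implements the Tofts–Kermode convolution by trapezoidal
quadrature on the sample grid and estimates (Ktrans, kep) by bounded
least squares (Ktrans ∈ [0, 1] s⁻¹, kep ∈ (0, 1] s⁻¹) with a 3-point
multi-start over kep to avoid local minima. The plasma input Cp is data —
any arterial input function can be supplied; a classical bi-exponential
population AIF is provided for the phantoms. Conversion from MR signal to
concentration is out of scope; the fitter operates on concentration
curves directly.

## Digital phantoms

The generator emulates the *statistical* structure of a gas-challenge scan,
not its physics: per-pixel haemoglobin and saturation maps, exponential or
step relaxation toward the segment target after each gas switch
(`v(t) = target + (v0 − target)·2^(−Δt/T1/2)`), a linear spectral forward
model with optional per-wavelength fluence, and additive Gaussian signal
noise (SD relative to the mean tumour signal, default 5 %). It does **not**
simulate acoustic wave propagation, reconstruction artefacts, speckle,
breathing motion or anaesthesia drift — so passing tests demonstrate
correctness of the analysis chain under its own forward model, not
robustness to those real-data effects.

Preset phenotypes (both ellipses ~2.3 × 2.1 mm on a 7.2 mm, 75 µm grid,
with a healthy-tissue background at SO2 0.488, ΔSO2 0.10, T1/2 74 s):

* **PC3-like** (poorly perfused): THb 28.7 (relative units) decreasing
  inward (−25 %/mm), baseline SO2 0.27, response amplitude 0.12 at the
  boundary decaying with depth (e^(−d/0.6 mm)) plus a spatially correlated
  heterogeneity field (SD 0.02, correlation length 0.3 mm), T1/2 300 s.
  The correlated field makes the responding mask compact → low η, and the
  decay produces the monotone rim→core profiles of ΔSO2 and RF.
* **LNCaP-like** (blood-rich): THb 149 not decreasing with depth
  (+10 %/mm), the same baseline SO2 0.27 — the two phenotypes are
  deliberately indistinguishable at baseline — amplitude 0.13/0.12
  (rim/core) with a mild depth decay (2.5 mm), T1/2 353 s, and a
  *scattered* core response: 0.225 mm cells respond independently with
  probability 0.6, giving high η and a high RF.

Amplitude defaults are centred so that the recovered cohort means of ΔSO2
(~0.05 vs ~0.09) and RF bracket the characteristic in vivo contrast of
these phenotypes. Cohort generation adds between-tumour variability:
baseline jitter SD 0.05 (the biological spread implied by reported group
SEMs at their sample sizes), lognormal amplitude scatter (20 %) and THb
scatter (15 %). Kinetic-recovery cohorts use region-trace noise of SD 0.02
per frame and amplitudes 0.08–0.12 — responders strong enough for T1/2 to
be defined under the noise gate, matching how weak responders are excluded
from half-time analysis. THb is static by default; an optional step change
at the gas switch (vasoconstriction) can be enabled.

Histology phantoms place Poisson-distributed vessel disks (default
10 mm⁻², radius 20 µm) in a 1.02 mm field at 2 µm sampling and build the
Hoechst channel as a saturating exponential distance decay from the
vessels. MRI phantoms generate 8-echo decays and 5 s-resolution DCE curves
at the phenotype-scale truths (T2* 0.0095 / 0.0024 s; Ktrans 0.0014 /
0.0030 s⁻¹).

## Reporting

`run_oeot` is deterministic given inputs and configuration; each report
embeds a configuration hash and package version, and repeated runs write
byte-identical CSV/JSON. Test–retest repeatability uses Pearson
correlation by default ("rank" conventions differ between tools; Spearman
is available by flag). Group contrasts use Welch's t-test; these are
standard annotations, not contributions of the package.

## Problem sizes

Phantom scans are 96×96 pixels × 15 wavelengths × 157 frames; acceptance
cohorts use 8–10 phantoms per phenotype; kinetic cohorts 20 region traces;
the η Monte-Carlo reference 200×200 pixels; histology fields 510×510.
These sizes keep every property measurable with comfortable statistical
margins while a full run of the suite plus the acceptance script stays in
the minutes range on a single CPU.

## Known limitations

* SO2^MSOT is fluence-uncorrected; absolute oxygenation is out of scope.
* η is a documented reconstruction (above), and whether the original
  statistic used the binary response class or continuous ΔSO2 is unknown;
  the binary class is used here.
* T1/2 from first crossing is noise-sensitive for weak responders; the
  noise gate reports such half-times as undefined rather than guessing.
* Shells are 2-D (single-slice analysis); no 3-D geometry.
* The vessel-segmentation defaults are plausible but not validated against
  the original quantification pipeline.
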