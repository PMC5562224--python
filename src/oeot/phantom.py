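"""Digital tumour phantoms for oxygen-enhanced optoacoustic analysis.

The generator builds 2-D two-compartment (rim/core) tumour phantoms inside
healthy tissue, with known ground truth for every quantity the pipeline
estimates: per-pixel haemoglobin content, baseline oxygen saturation,
challenge response amplitude and half-time, plus the resulting multispectral
signal stack (optionally with per-wavelength fluence bias and additive
Gaussian noise).  It also renders synthetic fluorescence histology fields
and MRI relaxometry/DCE curves, so the whole pipeline is testable without
any animal data.

Two preset tumour phenotypes mirror the qualitative contrast between a
poorly vascularised, rim-perfused xenograft ("PC3-like") and a blood-rich,
heterogeneously responding one ("LNCaP-like"):

* both share the same baseline SO2 distribution (~0.27), so the static
  metric cannot separate them;
* the PC3-like tumour responds essentially only in its rim, with a
  response amplitude that decays smoothly with depth (spatially *compact*
  pattern, low heterogeneity eta) and haemoglobin content decreasing
  inward;
* the LNCaP-like tumour has ~5x higher total haemoglobin, responds in both
  rim and core, but its core response is *scattered* (high eta), and THb
  does not decrease with depth.

Default kinetic and amplitude parameters are centred on typical in vivo
values for these phenotypes (baseline SO2 ~0.27 tumour vs ~0.49 healthy;
half-times ~300-350 s tumour vs ~74-84 s healthy; mean response amplitudes
~0.04 vs ~0.09; THb ~29 vs ~149 relative units).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .kinetics import GasSchedule, KineticTrace
from .mri import RelaxSeries, biexponential_aif, tofts_forward
from .spatial import boundary_depth_mm, make_shells, rim_core_split
from .unmixing import ExtinctionTable, MultispectralSeries, load_extinction_table

__all__ = [
    "CompartmentSpec",
    "PhantomSpec",
    "PhantomTruth",
    "build_truth",
    "render_msot",
    "simulate_region_trace",
    "pc3_like_spec",
    "lncap_like_spec",
    "spec_cohort",
    "HistoPhantomSpec",
    "render_histology",
    "MRIPhantomSpec",
    "render_mri_curves",
    "DEFAULT_WAVELENGTHS",
    "FRAME_INTERVAL_S",
]

#: acquisition frame interval, s (one multispectral slice).
FRAME_INTERVAL_S = 11.5

#: default 15-wavelength acquisition, 700-880 nm.
DEFAULT_WAVELENGTHS = np.linspace(700.0, 880.0, 15)


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompartmentSpec:
    """Ground-truth parameters of one tissue compartment.

    ``respond_fraction`` < 1 scatters the response: square cells of side
    ``scatter_cell_mm`` respond independently with this probability (the
    rest get zero amplitude), producing a spatially random response
    pattern.  ``kinetic_shape`` is 'exp' (half-time ``t_half_s``) or 'step'
    (instantaneous).
    """

    thb_level: float
    so2_air: float
    delta_so2: float
    t_half_s: float
    kinetic_shape: str = "exp"
    respond_fraction: float = 1.0
    scatter_cell_mm: float = 0.225

    def __post_init__(self) -> None:
        if not 0.0 <= self.so2_air <= 1.0:
            raise ValueError("so2_air must lie in [0, 1]")
        if not 0.0 <= self.so2_air + self.delta_so2 <= 1.0:
            raise ValueError("so2_air + delta_so2 must lie in [0, 1]")
        if self.t_half_s < 0:
            raise ValueError("t_half_s must be >= 0")
        if self.kinetic_shape not in ("exp", "step"):
            raise ValueError("kinetic_shape must be 'exp' or 'step'")
        if not 0.0 <= self.respond_fraction <= 1.0:
            raise ValueError("respond_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class PhantomSpec:
    """Full specification of a two-compartment tumour phantom.

    The tumour is an ellipse (centre/semi-axes in mm); its rim is the outer
    ``n_rim_shells`` x ``shell_step_mm`` band and the remainder is core.
    ``delta_depth_decay_mm`` multiplies the compartment response amplitude
    by exp(-depth/decay); ``delta_noise_sd`` adds a spatially correlated
    (Gaussian-filtered, correlation length ``delta_noise_corr_mm``)
    zero-mean field to the amplitude map; ``thb_depth_slope`` scales THb as
    ``1 + slope * depth_mm`` (floored at 0.2).  ``noise_sd`` is the
    additive signal-domain noise SD, relative to the mean tumour signal.
    """

    rows: int = 96
    cols: int = 96
    spacing: float = 0.075  # mm / pixel
    tumour_centre_mm: tuple[float, float] = (4.3, 3.6)
    tumour_axes_mm: tuple[float, float] = (2.3, 2.1)
    rim: CompartmentSpec = CompartmentSpec(28.7, 0.27, 0.12, 300.0)
    core: CompartmentSpec = CompartmentSpec(28.7, 0.27, 0.12, 300.0)
    healthy: CompartmentSpec = CompartmentSpec(60.0, 0.488, 0.10, 74.0)
    healthy_roi_centre_mm: tuple[float, float] = (1.3, 1.3)
    healthy_roi_radius_mm: float = 0.8
    shell_step_mm: float = 0.5
    n_rim_shells: int = 2
    delta_depth_decay_mm: float | None = None
    delta_noise_sd: float = 0.0
    delta_noise_corr_mm: float = 0.3
    thb_depth_slope: float = 0.0
    schedule: GasSchedule = field(default_factory=GasSchedule.default_challenge)
    noise_sd: float = 0.0
    fluence: np.ndarray | None = None
    seed: int = 0


@dataclass
class PhantomTruth:
    """Ground truth for one phantom: per-pixel parameter maps, the SO2
    stack on the acquisition frame grid, and region masks."""

    spec: PhantomSpec
    frame_times: np.ndarray
    so2_stack: np.ndarray        # (frames, rows, cols)
    thb_map: np.ndarray
    so2_air_map: np.ndarray
    delta_map: np.ndarray
    t_half_map: np.ndarray
    step_mask: np.ndarray
    tumour_mask: np.ndarray
    healthy_mask: np.ndarray
    rim_mask: np.ndarray
    core_mask: np.ndarray

    @property
    def spacing(self) -> float:
        return self.spec.spacing

    def coarse_tumour_mask(self, factor: int = 3, min_coverage: float = 0.5) -> np.ndarray:
        """Tumour mask on the block-averaged grid (block coverage >= min_coverage)."""
        return _downsample_mask(self.tumour_mask, factor, min_coverage)

    def coarse_delta_map(self, factor: int = 3) -> np.ndarray:
        """THb-weighted block mean of the truth amplitude map: the response
        amplitude an ideal unmixing of block-averaged signals would see."""
        w = _block_sum(self.thb_map, factor)
        wd = _block_sum(self.thb_map * self.delta_map, factor)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(w > 0, wd / w, 0.0)

    def truth_rf(self, threshold: float = 0.03, factor: int = 3) -> float:
        """Ground-truth responding fraction on the coarse analysis grid."""
        roi = self.coarse_tumour_mask(factor)
        delta = self.coarse_delta_map(factor)
        return float(np.count_nonzero(roi & (delta > threshold)) / np.count_nonzero(roi))


def _block_sum(image: np.ndarray, factor: int) -> np.ndarray:
    n_r, n_c = image.shape
    r, c = n_r // factor, n_c // factor
    return image[: r * factor, : c * factor].reshape(r, factor, c, factor).sum(axis=(1, 3))


def _downsample_mask(mask: np.ndarray, factor: int, min_coverage: float = 0.5) -> np.ndarray:
    cov = _block_sum(mask.astype(float), factor) / factor ** 2
    return cov >= min_coverage


# ---------------------------------------------------------------------------
# Truth construction
# ---------------------------------------------------------------------------

def _ellipse_mask(rows, cols, spacing, centre_mm, axes_mm) -> np.ndarray:
    rr = (np.arange(rows) + 0.5) * spacing
    cc = (np.arange(cols) + 0.5) * spacing
    y = (rr[:, None] - centre_mm[0]) / axes_mm[0]
    x = (cc[None, :] - centre_mm[1]) / axes_mm[1]
    return y ** 2 + x ** 2 <= 1.0


def _disk_mask(rows, cols, spacing, centre_mm, radius_mm) -> np.ndarray:
    return _ellipse_mask(rows, cols, spacing, centre_mm, (radius_mm, radius_mm))


def _scatter_field(shape, spacing, cell_mm, p, rng) -> np.ndarray:
    """Bernoulli(p) per square cell of side cell_mm, rendered per pixel."""
    m = max(1, int(round(cell_mm / spacing)))
    n_cr = -(-shape[0] // m)
    n_cc = -(-shape[1] // m)
    cells = rng.random((n_cr, n_cc)) < p
    return np.kron(cells, np.ones((m, m), dtype=bool))[: shape[0], : shape[1]]


def _correlated_field(shape, spacing, corr_mm, sd, rng) -> np.ndarray:
    """Zero-mean Gaussian field with spatial correlation length corr_mm
    and pointwise SD ``sd``."""
    white = rng.standard_normal(shape)
    sigma_px = corr_mm / spacing
    f = gaussian_filter(white, sigma=sigma_px, mode="reflect")
    s = f.std()
    return f * (sd / s) if s > 0 else np.zeros(shape)


def so2_timecourse(
    times: np.ndarray,
    schedule: GasSchedule,
    so2_air,
    delta,
    t_half,
    is_step,
) -> np.ndarray:
    """Evaluate the ground-truth SO2 relaxation kinetics at ``times``.

    After each gas switch SO2 relaxes from its current value toward the
    segment target (baseline + amplitude on O2, baseline on air) with
    half-time ``t_half``: ``v(t) = target + (v0 - target) * 2**(-dt/t_half)``;
    'step' pixels jump instantaneously.  Inputs broadcast over pixels; the
    result is stacked along a leading time axis.
    """
    so2_air = np.asarray(so2_air, dtype=float)
    delta = np.asarray(delta, dtype=float)
    t_half = np.asarray(t_half, dtype=float)
    is_step = np.asarray(is_step, dtype=bool)
    times = np.asarray(times, dtype=float)

    shape = np.broadcast_shapes(so2_air.shape, delta.shape, t_half.shape, is_step.shape)
    v0 = np.broadcast_to(so2_air, shape).astype(float).copy()
    out = np.empty((times.size,) + shape, dtype=float)
    tau = np.where((t_half > 0) & ~is_step, t_half, np.inf)

    for gas, a, b in schedule.segments:
        target = so2_air + delta if gas == "o2" else so2_air
        target = np.broadcast_to(target, shape)
        last = abs(b - schedule.segments[-1][2]) < 1e-9
        sel = (times >= a) & ((times < b) | (last & (times <= b)))
        for i in np.flatnonzero(sel):
            dt = times[i] - a
            decay = np.power(2.0, -dt / tau)
            v = target + (v0 - target) * decay
            v = np.where(is_step, target, v)
            out[i] = v
        decay_end = np.power(2.0, -(b - a) / tau)
        v0 = np.where(is_step, target, target + (v0 - target) * decay_end)
    return out


def build_truth(spec: PhantomSpec) -> PhantomTruth:
    """Construct all ground-truth maps and the per-frame SO2 stack."""
    rng = np.random.default_rng(spec.seed)
    rows, cols, sp = spec.rows, spec.cols, spec.spacing

    tumour = _ellipse_mask(rows, cols, sp, spec.tumour_centre_mm, spec.tumour_axes_mm)
    if not tumour.any():
        raise ValueError("tumour ellipse lies outside the grid")
    healthy_roi = _disk_mask(rows, cols, sp, spec.healthy_roi_centre_mm,
                             spec.healthy_roi_radius_mm)
    if (healthy_roi & tumour).any():
        raise ValueError("healthy ROI overlaps the tumour")

    shells = make_shells(tumour, sp, spec.shell_step_mm,
                         n_shells=spec.n_rim_shells)
    rim, core = rim_core_split(shells, spec.n_rim_shells)
    depth = boundary_depth_mm(tumour, sp)

    # --- parameter maps -------------------------------------------------
    thb = np.full((rows, cols), spec.healthy.thb_level, dtype=float)
    so2_air = np.full((rows, cols), spec.healthy.so2_air, dtype=float)
    delta = np.full((rows, cols), spec.healthy.delta_so2, dtype=float)
    t_half = np.full((rows, cols), spec.healthy.t_half_s, dtype=float)
    step = np.full((rows, cols), spec.healthy.kinetic_shape == "step")

    for comp, mask in ((spec.rim, rim), (spec.core, core)):
        thb[mask] = comp.thb_level
        so2_air[mask] = comp.so2_air
        delta[mask] = comp.delta_so2
        t_half[mask] = comp.t_half_s
        step[mask] = comp.kinetic_shape == "step"
        if comp.respond_fraction < 1.0:
            scatter = _scatter_field((rows, cols), sp, comp.scatter_cell_mm,
                                     comp.respond_fraction, rng)
            delta[mask & ~scatter] = 0.0

    if spec.thb_depth_slope != 0.0:
        factor = np.maximum(1.0 + spec.thb_depth_slope * np.maximum(depth, 0.0), 0.2)
        thb[tumour] *= factor[tumour]
    if spec.delta_depth_decay_mm is not None:
        decay = np.exp(-np.maximum(depth, 0.0) / spec.delta_depth_decay_mm)
        delta[tumour] *= decay[tumour]
    if spec.delta_noise_sd > 0:
        bump = _correlated_field((rows, cols), sp, spec.delta_noise_corr_mm,
                                 spec.delta_noise_sd, rng)
        delta[tumour] += bump[tumour]
    np.clip(delta, -so2_air, 1.0 - so2_air, out=delta)

    total_s = spec.schedule.segments[-1][2]
    frame_times = np.arange(0.0, total_s, FRAME_INTERVAL_S)
    so2_stack = so2_timecourse(frame_times, spec.schedule, so2_air, delta, t_half, step)

    return PhantomTruth(
        spec=spec,
        frame_times=frame_times,
        so2_stack=so2_stack,
        thb_map=thb,
        so2_air_map=so2_air,
        delta_map=delta,
        t_half_map=t_half,
        step_mask=step,
        tumour_mask=tumour,
        healthy_mask=healthy_roi,
        rim_mask=rim,
        core_mask=core,
    )


# ---------------------------------------------------------------------------
# Forward signal model
# ---------------------------------------------------------------------------

def render_msot(
    truth: PhantomTruth,
    table: ExtinctionTable | None = None,
    wavelengths: Sequence[float] = DEFAULT_WAVELENGTHS,
    noise_sd: float | None = None,
    fluence: np.ndarray | None = None,
    seed: int | None = None,
) -> MultispectralSeries:
    """Render the multispectral signal stack from ground truth.

    The per-pixel signal at wavelength ``w`` is
    ``fluence[w] * (eps_hbo2[w] * THb * SO2 + eps_hb[w] * THb * (1 - SO2))``
    plus additive Gaussian noise whose SD is ``noise_sd`` times the mean
    tumour signal.  With unit fluence and zero noise, per-pixel unmixing of
    the result recovers the truth SO2 to machine precision.
    """
    if table is None:
        table = load_extinction_table()
    spec = truth.spec
    wl = np.asarray(wavelengths, dtype=float)
    E = table.design_matrix(wl)  # (n_wl, 2)
    if noise_sd is None:
        noise_sd = spec.noise_sd
    if fluence is None:
        fluence = spec.fluence
    phi = np.ones(wl.size) if fluence is None else np.asarray(fluence, dtype=float)
    if phi.shape != wl.shape:
        raise ValueError("fluence must have one multiplier per wavelength")

    c_hbo2 = truth.thb_map[None] * truth.so2_stack           # (f, r, c)
    c_hb = truth.thb_map[None] * (1.0 - truth.so2_stack)
    # data[f, w] = phi_w * (E[w,0] c_hbo2 + E[w,1] c_hb)
    data = (
        phi[None, :, None, None] * (
            E[None, :, 0, None, None] * c_hbo2[:, None]
            + E[None, :, 1, None, None] * c_hb[:, None]
        )
    )
    if noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
        scale = noise_sd * data[0][:, truth.tumour_mask].mean()
        data = data + rng.normal(0.0, scale, size=data.shape)
    return MultispectralSeries(
        data=data,
        wavelengths=wl,
        frame_times=truth.frame_times,
        pixel_spacing=spec.spacing,
        meta={"phantom_seed": spec.seed},
    )


def simulate_region_trace(
    so2_air: float,
    delta_so2: float,
    t_half_s: float,
    schedule: GasSchedule,
    kinetic_shape: str = "exp",
    noise_sd: float = 0.0,
    frame_interval_s: float = FRAME_INTERVAL_S,
    rng: np.random.Generator | None = None,
) -> KineticTrace:
    """Simulate a single region-level SO2 trace with per-frame Gaussian
    noise of SD ``noise_sd`` in the SO2 domain (clipped to [0, 1])."""
    total_s = schedule.segments[-1][2]
    times = np.arange(0.0, total_s, frame_interval_s)
    vals = so2_timecourse(times, schedule, np.float64(so2_air), np.float64(delta_so2),
                          np.float64(t_half_s), kinetic_shape == "step")
    vals = np.asarray(vals, dtype=float).reshape(times.size)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        vals = np.clip(vals + rng.normal(0.0, noise_sd, size=vals.shape), 0.0, 1.0)
    return KineticTrace(times=times, values=vals)


# ---------------------------------------------------------------------------
# Preset phenotypes
# ---------------------------------------------------------------------------

def pc3_like_spec(seed: int = 0, noise_sd: float = 0.05) -> PhantomSpec:
    """Poorly perfused phenotype: response confined to the rim and decaying
    with depth, compact response pattern, low THb decreasing inward."""
    comp = CompartmentSpec(thb_level=28.7, so2_air=0.27, delta_so2=0.12,
                           t_half_s=300.0)
    return PhantomSpec(
        rim=comp,
        core=comp,
        delta_depth_decay_mm=0.6,
        delta_noise_sd=0.02,
        delta_noise_corr_mm=0.3,
        thb_depth_slope=-0.25,
        noise_sd=noise_sd,
        seed=seed,
    )


def lncap_like_spec(seed: int = 0, noise_sd: float = 0.05) -> PhantomSpec:
    """Blood-rich phenotype: same baseline SO2, larger response amplitude
    in rim and (scattered) core, high THb not decreasing with depth."""
    rim = CompartmentSpec(thb_level=149.0, so2_air=0.27, delta_so2=0.13,
                          t_half_s=353.0)
    core = CompartmentSpec(thb_level=149.0, so2_air=0.27, delta_so2=0.12,
                           t_half_s=353.0, respond_fraction=0.6,
                           scatter_cell_mm=0.225)
    return PhantomSpec(
        rim=rim,
        core=core,
        delta_depth_decay_mm=2.5,
        thb_depth_slope=0.10,
        noise_sd=noise_sd,
        seed=seed,
    )


def spec_cohort(
    base: PhantomSpec,
    n: int,
    seed: int,
    so2_air_jitter_sd: float = 0.05,
    delta_scale_sd: float = 0.2,
    thb_scale_sd: float = 0.15,
) -> list[PhantomSpec]:
    """A cohort of phantoms with biological between-tumour variability:
    additive baseline jitter, lognormal amplitude and THb scaling."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        d_air = rng.normal(0.0, so2_air_jitter_sd)
        s_delta = float(np.exp(rng.normal(0.0, delta_scale_sd)))
        s_thb = float(np.exp(rng.normal(0.0, thb_scale_sd)))

        def jig(c: CompartmentSpec) -> CompartmentSpec:
            so2_air = float(np.clip(c.so2_air + d_air, 0.02, 0.9))
            delta = float(np.clip(c.delta_so2 * s_delta, 0.0, 1.0 - so2_air))
            return replace(c, so2_air=so2_air, delta_so2=delta,
                           thb_level=c.thb_level * s_thb)

        out.append(replace(
            base,
            rim=jig(base.rim),
            core=jig(base.core),
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        ))
    return out


# ---------------------------------------------------------------------------
# Histology phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HistoPhantomSpec:
    """Synthetic fluorescence field: Poisson-placed vessel disks in the
    CD31 channel; Hoechst as a saturating distance-decay from vessels."""

    field_mm: float = 1.02
    spacing: float = 0.002  # mm / pixel (2 um)
    vessel_density_per_mm2: float = 10.0
    vessel_radius_mm: float = 0.02
    cd31_amplitude: float = 100.0
    cd31_background: float = 5.0
    hoechst_max: float = 50.0
    hoechst_background: float = 2.0
    hoechst_decay_mm: float = 0.05
    noise_sd: float = 2.0
    seed: int = 0


def render_histology(spec: HistoPhantomSpec):
    """Render a two-channel field and its ground truth.

    Returns ``(HistoField, truth)`` where ``truth`` holds the exact vessel
    mask, centre list, the noiseless Hoechst field and the true VF/PA/HI.
    """
    from scipy.ndimage import distance_transform_edt

    from .histology import HistoField

    rng = np.random.default_rng(spec.seed)
    n_px = int(round(spec.field_mm / spec.spacing))
    shape = (n_px, n_px)
    area = spec.field_mm ** 2
    n_vessels = rng.poisson(spec.vessel_density_per_mm2 * area)
    centres = rng.uniform(0.0, spec.field_mm, size=(n_vessels, 2))

    yy = (np.arange(n_px) + 0.5) * spec.spacing
    vessel_mask = np.zeros(shape, dtype=bool)
    for cy, cx in centres:
        d2 = (yy[:, None] - cy) ** 2 + (yy[None, :] - cx) ** 2
        vessel_mask |= d2 <= spec.vessel_radius_mm ** 2

    cd31 = np.where(vessel_mask, spec.cd31_amplitude, spec.cd31_background).astype(float)
    if vessel_mask.any():
        dist = distance_transform_edt(~vessel_mask) * spec.spacing
    else:
        dist = np.full(shape, np.inf)
    hoechst_clean = spec.hoechst_background + (
        (spec.hoechst_max - spec.hoechst_background)
        * np.exp(-dist / spec.hoechst_decay_mm)
    )
    cd31_noisy = cd31 + rng.normal(0.0, spec.noise_sd, shape)
    hoechst = hoechst_clean + rng.normal(0.0, spec.noise_sd, shape)

    tumour_mask = np.ones(shape, dtype=bool)
    halo = (dist <= 0.1) if vessel_mask.any() else np.zeros(shape, dtype=bool)
    truth = {
        "vessel_mask": vessel_mask,
        "centres_mm": centres,
        "hoechst_clean": hoechst_clean,
        "vf": float(vessel_mask.sum() / vessel_mask.size),
        "pa": float(halo.sum() / halo.size),
        "hi": float(hoechst_clean.mean()),
        "n_vessels": int(n_vessels),
    }
    return HistoField(cd31=cd31_noisy, hoechst=hoechst,
                      spacing=spec.spacing, tumour_mask=tumour_mask), truth


# ---------------------------------------------------------------------------
# MRI phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MRIPhantomSpec:
    """Synthetic relaxometry and DCE curves with known truths.

    Default truths span the phenotype contrast: long T2* for the poorly
    vascularised tumour (0.0095 s) vs short for the haemorrhagic one
    (0.0024 s); Ktrans 0.0014 vs 0.0030 1/s.
    """

    t2star_truths_s: tuple[float, ...] = (0.0095, 0.0024)
    echo_times_s: tuple[float, ...] = tuple(np.linspace(0.002, 0.030, 8))
    s0: float = 100.0
    ktrans_truths_per_s: tuple[float, ...] = (0.0014, 0.0030)
    kep_truth_per_s: float = 0.005
    dce_duration_s: float = 600.0
    dce_dt_s: float = 5.0
    noise_sd_rel: float = 0.0
    seed: int = 0


def render_mri_curves(spec: MRIPhantomSpec):
    """Generate monoexponential decays and Tofts DCE curves.

    Returns a dict with ``relax`` (list of (RelaxSeries, tau_truth)),
    ``dce`` (list of (times, ct, cp, ktrans_truth, kep_truth)).
    Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    te = np.asarray(spec.echo_times_s, dtype=float)
    relax = []
    for tau in spec.t2star_truths_s:
        sig = spec.s0 * np.exp(-te / tau)
        if spec.noise_sd_rel > 0:
            sig = np.clip(sig + rng.normal(0, spec.noise_sd_rel * spec.s0, te.shape), 0, None)
        relax.append((RelaxSeries(te, sig, kind="t2star"), tau))

    t = np.arange(0.0, spec.dce_duration_s + spec.dce_dt_s / 2, spec.dce_dt_s)
    cp = biexponential_aif(t, onset_s=t[1])
    dce = []
    for kt in spec.ktrans_truths_per_s:
        ct = tofts_forward(t, cp, kt, spec.kep_truth_per_s)
        if spec.noise_sd_rel > 0:
            ct = ct + rng.normal(0, spec.noise_sd_rel * max(ct.max(), 1e-12), t.shape)
        dce.append((t, ct, cp, kt, spec.kep_truth_per_s))
    return {"relax": relax, "dce": dce}
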