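"""End-to-end OE-OT orchestration and reporting.

``run_oeot`` composes the full analysis for one scan:

1. region-level unmixing and kinetic metrics (tumour, healthy, rim, core,
   individual 0.5 mm depth shells) from the spectrum averaged over each
   region;
2. per-pixel unmixing on the coarse (default 225 um) grid, response
   classification (threshold 0.03) and Responding Fraction per region;
3. spatial heterogeneity eta of the responding-pixel map;
4. depth profiles of response amplitude, RF and THb over the outer shells;
5. tumour size.

The report is a tidy per-region table plus profile and provenance blocks;
two runs with identical inputs and configuration produce byte-identical
CSV output.  ``repeatability`` computes test-retest correlations between
two matched report sets.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .kinetics import (
    DEFAULT_BASELINE_FRAMES,
    DEFAULT_NOISE_K,
    DEFAULT_PLATEAU_FRAMES,
    DEFAULT_RESPONSE_THRESHOLD,
    DEFAULT_SMOOTH_WINDOW,
    GasSchedule,
    KineticTrace,
    ResponseMap,
    extract_metrics,
    responding_fraction,
    response_map,
    smooth_trace,
)
from .spatial import (
    DEFAULT_N_DEPTH_SHELLS,
    DEFAULT_N_RIM_SHELLS,
    DEFAULT_SHELL_STEP_MM,
    depth_profile,
    heterogeneity_eta,
    make_shells,
    rim_core_split,
    tumour_size,
)
from .unmixing import (
    ExtinctionTable,
    MultispectralSeries,
    load_extinction_table,
    unmix_pixelwise,
    unmix_roi_series,
)

__all__ = ["AnalysisParams", "MetricReport", "run_oeot", "repeatability", "compare_groups"]


@dataclass(frozen=True)
class AnalysisParams:
    """All tunable analysis parameters with their reference defaults."""

    target_spacing_mm: float = 0.225
    smooth_window: int = DEFAULT_SMOOTH_WINDOW
    baseline_frames: int = DEFAULT_BASELINE_FRAMES
    plateau_frames: int = DEFAULT_PLATEAU_FRAMES
    noise_k: float = DEFAULT_NOISE_K
    response_threshold: float = DEFAULT_RESPONSE_THRESHOLD
    shell_step_mm: float = DEFAULT_SHELL_STEP_MM
    n_rim_shells: int = DEFAULT_N_RIM_SHELLS
    n_depth_shells: int = DEFAULT_N_DEPTH_SHELLS
    eta_connectivity: int = 4
    mask_min_coverage: float = 0.5

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class MetricReport:
    """Per-region OE-OT metrics for one scan.

    ``table`` has one row per region (tumour, healthy, rim, core,
    shell_1..n) with columns so2_air, so2_o2, delta_so2, t_half_s, rf and
    thb.  ``depth_profiles`` holds shell-ordered lists for delta_so2, rf
    and thb; ``provenance`` embeds the configuration hash and version.
    """

    scan_id: str
    table: pd.DataFrame
    tumour_area_mm2: float
    eta: float
    depth_profiles: dict
    response: ResponseMap | None
    provenance: dict = field(default_factory=dict)

    def region(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def to_csv(self, path: str | Path) -> None:
        df = self.table.copy()
        df.insert(0, "scan_id", self.scan_id)
        df.insert(1, "config_hash", self.provenance.get("config_hash", ""))
        df.to_csv(path, float_format="%.10g")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "scan_id": self.scan_id,
            "tumour_area_mm2": self.tumour_area_mm2,
            "eta": self.eta,
            "regions": json.loads(self.table.to_json(orient="index")),
            "depth_profiles": self.depth_profiles,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _config_hash(params: AnalysisParams, schedule: GasSchedule) -> str:
    blob = json.dumps(
        {"params": params.as_dict(), "schedule": schedule.segments},
        sort_keys=True,
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _block_mask(mask: np.ndarray, factor: int, min_coverage: float) -> np.ndarray:
    n_r, n_c = mask.shape
    r, c = n_r // factor, n_c // factor
    cov = (
        mask[: r * factor, : c * factor]
        .reshape(r, factor, c, factor)
        .mean(axis=(1, 3))
    )
    return cov >= min_coverage


def _region_metrics(series, mask, schedule, table, params):
    """ROI-averaged unmixing + kinetic metric extraction for one region."""
    df = unmix_roi_series(series, mask, table=table)
    trace = KineticTrace(df["time_s"].to_numpy(), df["so2"].to_numpy(),
                         df["valid"].to_numpy())
    trace = smooth_trace(trace, params.smooth_window)
    m = extract_metrics(trace, schedule,
                        baseline_frames=params.baseline_frames,
                        plateau_frames=params.plateau_frames,
                        noise_k=params.noise_k)
    t_switch = schedule.challenge_switch_s
    base = df[(df["time_s"] < t_switch) & df["valid"]].tail(params.baseline_frames)
    thb = float(base["thb"].mean())
    return m, thb


def run_oeot(
    series: MultispectralSeries,
    tumour_mask: np.ndarray,
    schedule: GasSchedule,
    healthy_mask: np.ndarray | None = None,
    table: ExtinctionTable | None = None,
    params: AnalysisParams | None = None,
    scan_id: str = "scan",
    out_dir: str | Path | None = None,
) -> MetricReport:
    """Run the full OE-OT analysis for one multispectral scan.

    Masks are on the native (fine) grid of ``series``.  When ``out_dir`` is
    given, ``metrics.csv``, ``report.json`` and float32 TIFF maps of the
    response are written there.  Deterministic given inputs and parameters.
    """
    if params is None:
        params = AnalysisParams()
    if table is None:
        table = load_extinction_table()
    tumour_mask = np.asarray(tumour_mask, dtype=bool)

    # --- region-level kinetics on the fine grid -------------------------
    fine_shells = make_shells(tumour_mask, series.pixel_spacing,
                              params.shell_step_mm, params.n_depth_shells)
    rim_f, core_f = rim_core_split(fine_shells, params.n_rim_shells)
    regions: dict[str, np.ndarray] = {"tumour": tumour_mask}
    if healthy_mask is not None:
        regions["healthy"] = np.asarray(healthy_mask, dtype=bool)
    regions["rim"] = rim_f
    if core_f.any():
        regions["core"] = core_f
    for k in range(1, fine_shells.n_shells + 1):
        sh = fine_shells.shell_mask(k)
        if sh.any():
            regions[f"shell_{k}"] = sh

    rows = {}
    thb_by_region = {}
    for name, mask in regions.items():
        m, thb = _region_metrics(series, mask, schedule, table, params)
        rows[name] = m.as_dict()
        thb_by_region[name] = thb

    # --- per-pixel response on the coarse grid --------------------------
    maps = unmix_pixelwise(series, params.target_spacing_mm, table=table)
    factor = int(round(params.target_spacing_mm / series.pixel_spacing))
    so2_stack = np.stack([m.so2 for m in maps])
    rmap = response_map(
        so2_stack, series.frame_times, schedule,
        pixel_spacing=maps[0].pixel_spacing,
        threshold=params.response_threshold,
        baseline_frames=params.baseline_frames,
        plateau_frames=params.plateau_frames,
        smooth_window=params.smooth_window,
    )

    coarse_masks = {
        name: _block_mask(mask, factor, params.mask_min_coverage)
        for name, mask in regions.items()
    }
    for name, cmask in coarse_masks.items():
        if cmask.any() and (rmap.valid_mask & cmask).any():
            rows[name]["rf"] = responding_fraction(rmap, cmask)
        rows[name]["thb"] = thb_by_region[name]

    het = heterogeneity_eta(rmap.responding_mask, coarse_masks["tumour"],
                            connectivity=params.eta_connectivity)

    # --- depth profiles on the coarse grid ------------------------------
    coarse_tumour = coarse_masks["tumour"]
    coarse_shells = make_shells(coarse_tumour, maps[0].pixel_spacing,
                                params.shell_step_mm, params.n_depth_shells)
    t_switch = schedule.challenge_switch_s
    base_idx = np.flatnonzero(series.frame_times < t_switch)[-params.baseline_frames:]
    thb_map = np.nanmean(np.stack([maps[i].thb for i in base_idx]), axis=0)
    rf_profile = depth_profile(rmap.responding_mask.astype(float), coarse_shells)
    delta_profile = depth_profile(rmap.delta_so2_map, coarse_shells)
    thb_profile = depth_profile(np.where(coarse_tumour, thb_map, np.nan), coarse_shells)

    order = [r for r in ["tumour", "healthy", "rim", "core"] if r in rows]
    order += [r for r in rows if r.startswith("shell_")]
    df = pd.DataFrame.from_dict(rows, orient="index").loc[order]
    df.index.name = "region"

    report = MetricReport(
        scan_id=scan_id,
        table=df,
        tumour_area_mm2=tumour_size(tumour_mask, series.pixel_spacing),
        eta=het.eta,
        depth_profiles={
            "delta_so2": delta_profile,
            "rf": rf_profile,
            "thb": thb_profile,
            "shells_truncated": coarse_shells.truncated,
        },
        response=rmap,
        provenance={
            "config_hash": _config_hash(params, schedule),
            "oeot_version": __version__,
            "n_frames": int(series.n_frames),
            "pixel_spacing_mm": float(series.pixel_spacing),
        },
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_csv(out_dir / "metrics.csv")
        report.to_json(out_dir / "report.json")
        import tifffile

        maps_dir = out_dir / "maps"
        maps_dir.mkdir(exist_ok=True)
        tifffile.imwrite(maps_dir / "delta_so2.tif",
                         rmap.delta_so2_map.astype(np.float32))
        tifffile.imwrite(maps_dir / "responding.tif",
                         rmap.responding_mask.astype(np.uint8))
        tifffile.imwrite(maps_dir / "thb.tif", thb_map.astype(np.float32))
        tifffile.imwrite(maps_dir / "shells.tif",
                         coarse_shells.label_image.astype(np.int32))
    return report


# ---------------------------------------------------------------------------
# Test-retest repeatability and group comparison
# ---------------------------------------------------------------------------

DEFAULT_REPEATABILITY_METRICS = ("so2_air", "so2_o2", "delta_so2", "t_half_s", "rf")


def repeatability(
    reports_a: Sequence[MetricReport],
    reports_b: Sequence[MetricReport],
    region: str = "tumour",
    metrics: Sequence[str] = DEFAULT_REPEATABILITY_METRICS,
    method: str = "pearson",
) -> pd.DataFrame:
    """Test-retest correlations between two matched report sets.

    ``reports_a[i]`` and ``reports_b[i]`` must refer to the same tumour
    (matched by ``scan_id``).  Returns one row per metric with the
    correlation coefficient r, the two-sided p-value and the pair count;
    r is NaN for metrics with fewer than 3 complete pairs or no variance.
    """
    if len(reports_a) != len(reports_b):
        raise ValueError("report lists must be paired")
    ids_a = [r.scan_id for r in reports_a]
    ids_b = [r.scan_id for r in reports_b]
    if ids_a != ids_b:
        raise ValueError("scan_id sequences do not match between sessions")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr

    out = []
    for metric in metrics:
        a = np.array([r.region(region)[metric] for r in reports_a], float)
        b = np.array([r.region(region)[metric] for r in reports_b], float)
        ok = np.isfinite(a) & np.isfinite(b)
        n = int(ok.sum())
        if n < 3 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
            out.append({"metric": metric, "r": np.nan, "p": np.nan, "n": n})
            continue
        res = corr(a[ok], b[ok])
        out.append({"metric": metric, "r": float(res.statistic),
                    "p": float(res.pvalue), "n": n})
    return pd.DataFrame(out).set_index("metric")


def compare_groups(a: Sequence[float], b: Sequence[float],
                   alternative: str = "two-sided") -> tuple[float, float]:
    """Welch t-test between two metric samples; returns (t, p)."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                          equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
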