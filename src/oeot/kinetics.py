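"""Oxygen gas-challenge kinetics: from SO2 time courses to OE-OT metrics.

During an oxygen-enhanced optoacoustic (OE-OT) scan the breathing gas is
switched from medical air (21 % O2) to pure oxygen and back.  The apparent
oxygen saturation SO2^MSOT responds with a rise whose plateau level,
amplitude and speed carry information about vascular function.  This module
extracts the standard metric set from a smoothed SO2 trace:

* ``so2_air``  - baseline plateau before the air->O2 switch,
* ``so2_o2``   - plateau at the end of the O2 segment,
* ``delta_so2``- amplitude of the response, ``so2_o2 - so2_air``,
* ``t_half_s`` - time from the switch to the first crossing of the
  half-maximal level (linearly interpolated between frames), undefined when
  the amplitude does not exceed ``noise_k`` baseline standard deviations,
* responding-pixel classification (``delta > threshold``, default 0.03) on
  a per-pixel SO2 stack, and the region Responding Fraction (RF).

Pixels whose response is *below* ``-threshold`` are reported in a separate
negative mask and never counted in RF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "GasSchedule",
    "KineticTrace",
    "OEOTMetricSet",
    "ResponseMap",
    "smooth_trace",
    "extract_metrics",
    "response_map",
    "responding_fraction",
]

DEFAULT_RESPONSE_THRESHOLD = 0.03
DEFAULT_SMOOTH_WINDOW = 5
DEFAULT_BASELINE_FRAMES = 5
DEFAULT_PLATEAU_FRAMES = 5
DEFAULT_NOISE_K = 2.0


# ---------------------------------------------------------------------------
# Schedule and trace containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GasSchedule:
    """Ordered breathing-gas segments ``(gas, start_s, end_s)``.

    Segments must be contiguous, start with air, and contain at least one
    air->O2 switch (e.g. the default challenge 300 s air / 1200 s O2 /
    300 s air).
    """

    segments: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        segs = tuple((str(g), float(a), float(b)) for g, a, b in self.segments)
        if not segs:
            raise ValueError("schedule has no segments")
        for g, a, b in segs:
            if g not in ("air", "o2"):
                raise ValueError(f"unknown gas {g!r} (expected 'air' or 'o2')")
            if not b > a:
                raise ValueError("each segment must have end_s > start_s")
        for (_, _, b0), (_, a1, _) in zip(segs, segs[1:]):
            if abs(b0 - a1) > 1e-9:
                raise ValueError("segments must be contiguous and non-overlapping")
        if segs[0][0] != "air":
            raise ValueError("first segment must be air")
        if not any(g0 == "air" and g1 == "o2"
                   for (g0, _, _), (g1, _, _) in zip(segs, segs[1:])):
            raise ValueError("schedule needs at least one air->o2 switch")
        object.__setattr__(self, "segments", segs)

    @property
    def switch_times(self) -> list[float]:
        """All gas-change times, in order."""
        return [a for (_, a, _) in self.segments[1:]]

    @property
    def challenge_switch_s(self) -> float:
        """Start time of the first O2 segment (the air->O2 switch)."""
        for (g0, _, b0), (g1, _, _) in zip(self.segments, self.segments[1:]):
            if g0 == "air" and g1 == "o2":
                return b0
        raise AssertionError("unreachable: validated schedule has a switch")

    @property
    def challenge_end_s(self) -> float:
        """End time of the first O2 segment."""
        t0 = self.challenge_switch_s
        for g, a, b in self.segments:
            if g == "o2" and abs(a - t0) < 1e-9:
                return b
        raise AssertionError("unreachable")

    def gas_at(self, t: float) -> str:
        for g, a, b in self.segments:
            if a <= t < b:
                return g
        return self.segments[-1][0]

    # -- I/O --------------------------------------------------------------
    @classmethod
    def from_json(cls, path: str | Path) -> "GasSchedule":
        """Read ``[{"gas": "air", "start_s": 0, "end_s": 300}, ...]``."""
        items = json.loads(Path(path).read_text())
        return cls(tuple((d["gas"], d["start_s"], d["end_s"]) for d in items))

    def to_json(self, path: str | Path) -> None:
        items = [{"gas": g, "start_s": a, "end_s": b} for g, a, b in self.segments]
        Path(path).write_text(json.dumps(items, indent=1))

    @classmethod
    def default_challenge(cls, air_s: float = 300.0, o2_s: float = 1200.0,
                          recovery_s: float = 300.0) -> "GasSchedule":
        return cls((
            ("air", 0.0, air_s),
            ("o2", air_s, air_s + o2_s),
            ("air", air_s + o2_s, air_s + o2_s + recovery_s),
        ))


@dataclass
class KineticTrace:
    """An SO2^MSOT time course with per-sample validity flags."""

    times: np.ndarray
    values: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.times.shape == self.values.shape == self.valid.shape):
            raise ValueError("times, values and valid must have equal shape")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class OEOTMetricSet:
    """Scalar OE-OT metrics for one region and scan.

    ``t_half_s`` is NaN when the response amplitude does not rise above the
    baseline noise.  ``rf`` is populated only for region-level analyses that
    had a per-pixel response map available.
    """

    so2_air: float
    so2_o2: float
    delta_so2: float
    t_half_s: float
    rf: float = np.nan
    n_frames_used: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "so2_air": self.so2_air,
            "so2_o2": self.so2_o2,
            "delta_so2": self.delta_so2,
            "t_half_s": self.t_half_s,
            "rf": self.rf,
        }


@dataclass
class ResponseMap:
    """Per-pixel challenge response on the coarse (225 um) grid."""

    delta_so2_map: np.ndarray
    responding_mask: np.ndarray
    negative_mask: np.ndarray
    valid_mask: np.ndarray
    threshold: float
    pixel_spacing: float


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def smooth_trace(trace: KineticTrace, window_frames: int = DEFAULT_SMOOTH_WINDOW) -> KineticTrace:
    """Centred moving average over valid samples.

    ``window_frames`` must be odd; at the trace edges the window shrinks
    symmetrically.  Invalid samples neither contribute to nor receive
    smoothed values; validity flags are preserved.
    """
    if window_frames < 1 or window_frames % 2 == 0:
        raise ValueError("window_frames must be an odd positive count")
    if window_frames > len(trace):
        raise ValueError("smoothing window exceeds trace length")
    if window_frames == 1:
        return KineticTrace(trace.times.copy(), trace.values.copy(), trace.valid.copy())

    half = window_frames // 2
    n = len(trace)
    out = np.full(n, np.nan)
    vals = np.where(trace.valid, trace.values, 0.0)
    cnts = trace.valid.astype(float)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    ccnt = np.concatenate([[0.0], np.cumsum(cnts)])
    for i in np.flatnonzero(trace.valid):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        m = ccnt[hi] - ccnt[lo]
        if m > 0:
            out[i] = (csum[hi] - csum[lo]) / m
    return KineticTrace(trace.times.copy(), out, trace.valid.copy())


def _moving_average_stack(stack: np.ndarray, valid: np.ndarray, window: int):
    """Vectorised centred moving average along axis 0 of a (frames, ...) stack."""
    if window == 1:
        return stack.copy()
    half = window // 2
    n = stack.shape[0]
    vals = np.where(valid, stack, 0.0)
    cnts = valid.astype(float)
    csum = np.concatenate([np.zeros((1,) + stack.shape[1:]), np.cumsum(vals, axis=0)])
    ccnt = np.concatenate([np.zeros((1,) + stack.shape[1:]), np.cumsum(cnts, axis=0)])
    out = np.full_like(stack, np.nan, dtype=float)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        m = ccnt[hi] - ccnt[lo]
        with np.errstate(invalid="ignore"):
            out[i] = np.where(m > 0, (csum[hi] - csum[lo]) / np.where(m > 0, m, 1.0), np.nan)
    out[~valid] = np.nan
    return out


# ---------------------------------------------------------------------------
# Metric extraction
# ---------------------------------------------------------------------------

def _plateau_stats(times, values, valid, t_end, n_frames):
    """Mean/SD of the last ``n_frames`` valid samples at times < t_end."""
    sel = np.flatnonzero(valid & (times < t_end))
    if sel.size == 0:
        raise ValueError("no valid samples in requested segment")
    sel = sel[-n_frames:]
    v = values[sel]
    return float(np.mean(v)), float(np.std(v, ddof=0)), sel.size


def extract_metrics(
    trace: KineticTrace,
    schedule: GasSchedule,
    baseline_frames: int = DEFAULT_BASELINE_FRAMES,
    plateau_frames: int = DEFAULT_PLATEAU_FRAMES,
    noise_k: float = DEFAULT_NOISE_K,
) -> OEOTMetricSet:
    """Extract the OE-OT metric set from one (already smoothed) SO2 trace.

    ``so2_air`` is the mean of the last ``baseline_frames`` valid samples
    before the air->O2 switch; ``so2_o2`` the mean of the last
    ``plateau_frames`` valid samples of the O2 segment.  ``t_half_s`` is the
    linearly interpolated first crossing of ``so2_air + delta/2`` after the
    switch, measured from the switch, and is NaN when
    ``|delta| <= noise_k * SD(baseline samples)`` (insufficient change over
    the background noise).
    """
    t_switch = schedule.challenge_switch_s
    t_end = schedule.challenge_end_s
    times, values, valid = trace.times, trace.values, trace.valid

    so2_air, base_sd, n_base = _plateau_stats(times, values, valid, t_switch, baseline_frames)
    o2_sel = valid & (times >= t_switch) & (times < t_end)
    if not o2_sel.any():
        raise ValueError("trace has no valid samples in the O2 segment")
    idx_o2 = np.flatnonzero(o2_sel)[-plateau_frames:]
    so2_o2 = float(np.mean(values[idx_o2]))
    delta = so2_o2 - so2_air

    t_half = np.nan
    if abs(delta) > noise_k * base_sd:
        target = so2_air + delta / 2.0
        post = np.flatnonzero(valid & (times >= t_switch))
        sign = 1.0 if delta > 0 else -1.0
        prev_t, prev_v = t_switch, so2_air
        for i in post:
            v, t = values[i], times[i]
            if sign * (v - target) >= 0:
                if v != prev_v:
                    frac = (target - prev_v) / (v - prev_v)
                else:
                    frac = 0.0
                t_half = (prev_t + frac * (t - prev_t)) - t_switch
                break
            prev_t, prev_v = t, v
    return OEOTMetricSet(
        so2_air=so2_air,
        so2_o2=so2_o2,
        delta_so2=delta,
        t_half_s=t_half,
        n_frames_used={"baseline": n_base, "plateau": len(idx_o2)},
    )


# ---------------------------------------------------------------------------
# Per-pixel response classification
# ---------------------------------------------------------------------------

def response_map(
    so2_stack: np.ndarray,
    frame_times: Sequence[float],
    schedule: GasSchedule,
    pixel_spacing: float,
    threshold: float = DEFAULT_RESPONSE_THRESHOLD,
    baseline_frames: int = DEFAULT_BASELINE_FRAMES,
    plateau_frames: int = DEFAULT_PLATEAU_FRAMES,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> ResponseMap:
    """Classify responding pixels from a per-pixel SO2 stack.

    ``so2_stack`` is ``(frames, rows, cols)`` with NaN marking invalid
    samples (typically the SO2 maps of per-pixel unmixing on the 225 um
    grid).  Each pixel trace is smoothed with a centred moving average, then
    the region baseline/plateau logic is applied pixel-wise to obtain a
    signed delta map.  ``responding_mask`` holds ``delta > threshold``,
    ``negative_mask`` holds ``delta < -threshold``.  A pixel is valid when
    it has at least one valid baseline frame and one valid plateau frame.
    """
    so2_stack = np.asarray(so2_stack, dtype=float)
    times = np.asarray(frame_times, dtype=float)
    if so2_stack.shape[0] != times.size:
        raise ValueError("frame_times length must match stack frames")
    valid = np.isfinite(so2_stack)
    if smooth_window > 1:
        if smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd")
        so2_stack = _moving_average_stack(so2_stack, valid, smooth_window)
        valid = np.isfinite(so2_stack)

    t_switch = schedule.challenge_switch_s
    t_end = schedule.challenge_end_s
    base_idx = np.flatnonzero(times < t_switch)[-baseline_frames:]
    o2_idx = np.flatnonzero((times >= t_switch) & (times < t_end))[-plateau_frames:]
    if base_idx.size == 0 or o2_idx.size == 0:
        raise ValueError("fewer than baseline+plateau usable frames")

    with np.errstate(invalid="ignore"):
        base = np.nanmean(so2_stack[base_idx], axis=0)
        plat = np.nanmean(so2_stack[o2_idx], axis=0)
    pix_valid = valid[base_idx].any(axis=0) & valid[o2_idx].any(axis=0)
    delta = np.where(pix_valid, plat - base, np.nan)
    responding = pix_valid & (delta > threshold)
    negative = pix_valid & (delta < -threshold)
    return ResponseMap(
        delta_so2_map=delta,
        responding_mask=responding,
        negative_mask=negative,
        valid_mask=pix_valid,
        threshold=threshold,
        pixel_spacing=pixel_spacing,
    )


def responding_fraction(rmap: ResponseMap, roi: np.ndarray) -> float:
    """Responding Fraction: responding pixels over valid pixels within ROI."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != rmap.valid_mask.shape:
        raise ValueError("ROI shape must match response map")
    if not roi.any():
        raise ValueError("ROI is empty")
    n_valid = int(np.count_nonzero(rmap.valid_mask & roi))
    if n_valid == 0:
        raise ValueError("no valid pixels in ROI")
    n_resp = int(np.count_nonzero(rmap.responding_mask & roi))
    return n_resp / n_valid
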