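"""MRI quantification: monoexponential relaxometry and Tofts-Kermode DCE.

Two fitting problems accompany the optoacoustic read-outs:

* **Relaxometry** - multi-echo (T2*) or inversion/saturation (T1) signal
  decays fitted pixel-by-pixel to ``S(t) = S0 exp(-t / tau)``; tau is the
  relaxation time in seconds.  T2* is sensitive to deoxyhaemoglobin and
  shortens with haemorrhage.

* **DCE** - dynamic contrast-enhanced tissue concentration curves fitted
  with the Tofts-Kermode compartment model

      Ct(t) = Ktrans * int_0^t Cp(tau) exp(-kep (t - tau)) dtau

  where ``Ktrans`` (1/s) is the plasma-to-tissue transfer constant
  (perfusion/permeability), ``kep`` the efflux rate and ``ve = Ktrans/kep``
  the extravascular extracellular volume fraction.  The fitter takes the
  plasma input function Cp as data, so any arterial input model can be
  supplied; a configurable bi-exponential population AIF is provided.

Non-convergent pixels are flagged (NaN), never raised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "RelaxSeries",
    "DCEFit",
    "fit_monoexponential",
    "fit_relaxometry_map",
    "tofts_forward",
    "fit_tofts",
    "biexponential_aif",
]

# Optimizer bounds for the Tofts fit; generous for the tumour ranges seen
# with low-molecular-weight gadolinium agents.
KTRANS_BOUNDS = (0.0, 1.0)     # 1/s
KEP_BOUNDS = (1e-6, 1.0)       # 1/s
_KEP_STARTS = (1e-3, 5e-3, 2e-2)  # multi-start grid for kep


@dataclass
class RelaxSeries:
    """A single-pixel relaxation decay: sample times (s) and signals."""

    sample_times: np.ndarray
    signals: np.ndarray
    kind: str = "t2star"  # or "t1"

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.sample_times.size < 3:
            raise ValueError("need at least 3 samples")
        if self.sample_times.shape != self.signals.shape:
            raise ValueError("times and signals must have equal length")
        if np.any(np.diff(self.sample_times) <= 0):
            raise ValueError("sample_times must be strictly increasing")
        if np.any(self.signals < 0):
            raise ValueError("signals must be non-negative")


@dataclass
class DCEFit:
    """Tofts-Kermode fit result; ``ve_in_range`` flags 0 < ve <= 1."""

    ktrans: float
    kep: float
    ve: float
    rss: float
    converged: bool

    @property
    def ve_in_range(self) -> bool:
        return bool(np.isfinite(self.ve) and 0.0 < self.ve <= 1.0)


# ---------------------------------------------------------------------------
# Relaxometry
# ---------------------------------------------------------------------------

def fit_monoexponential(series: RelaxSeries) -> tuple[float, float]:
    """Fit ``S(t) = s0 exp(-t/tau)`` by nonlinear least squares.

    Initialised from a log-linear regression on the positive samples.
    Returns ``(s0, tau)``; both NaN for degenerate input (constant signal,
    non-positive decay estimate) or non-convergence.
    """
    t, s = series.sample_times, series.signals
    if np.ptp(s) == 0:
        return float("nan"), float("nan")
    pos = s > 0
    if np.count_nonzero(pos) < 2:
        return float("nan"), float("nan")
    slope, intercept = np.polyfit(t[pos], np.log(s[pos]), 1)
    if slope >= 0:
        return float("nan"), float("nan")
    s0_0, tau_0 = float(np.exp(intercept)), float(-1.0 / slope)
    try:
        popt, _ = curve_fit(
            lambda tt, s0, tau: s0 * np.exp(-tt / tau),
            t, s, p0=[s0_0, tau_0], maxfev=2000,
        )
    except RuntimeError:
        return float("nan"), float("nan")
    s0_hat, tau_hat = float(popt[0]), float(popt[1])
    if s0_hat <= 0 or tau_hat <= 0:
        return float("nan"), float("nan")
    return s0_hat, tau_hat


def fit_relaxometry_map(
    stack: np.ndarray,
    sample_times: np.ndarray,
    kind: str = "t2star",
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Pixel-by-pixel monoexponential tau map from a (time, row, col) stack.

    Pixels outside ``mask`` or with failed fits are NaN.
    """
    stack = np.asarray(stack, dtype=float)
    times = np.asarray(sample_times, dtype=float)
    if stack.ndim != 3 or stack.shape[0] != times.size:
        raise ValueError("stack must be (time, row, col) matching sample_times")
    if mask is None:
        mask = np.ones(stack.shape[1:], dtype=bool)
    tau_map = np.full(stack.shape[1:], np.nan)
    for i, j in zip(*np.nonzero(mask)):
        sig = stack[:, i, j]
        if np.any(sig < 0) or np.ptp(sig) == 0:
            continue
        _, tau = fit_monoexponential(RelaxSeries(times, sig, kind=kind))
        tau_map[i, j] = tau
    return tau_map


# ---------------------------------------------------------------------------
# Tofts-Kermode DCE
# ---------------------------------------------------------------------------

def tofts_forward(
    times: np.ndarray,
    cp: np.ndarray,
    ktrans: float,
    kep: float,
) -> np.ndarray:
    """Tissue concentration from the Tofts-Kermode convolution.

    ``Ct(t_i) = Ktrans * int_0^{t_i} Cp(tau) exp(-kep (t_i - tau)) dtau``
    evaluated by trapezoidal quadrature on the sample grid.
    """
    t = np.asarray(times, dtype=float)
    cp = np.asarray(cp, dtype=float)
    if t.shape != cp.shape:
        raise ValueError("times and cp must have equal length")
    # integrand for all (i, j): cp[j] * exp(-kep (t_i - t_j)), j <= i
    dt_mat = t[:, None] - t[None, :]
    with np.errstate(over="ignore"):
        kern = np.exp(-kep * np.clip(dt_mat, 0.0, None))
    integ = cp[None, :] * kern
    ct = np.empty_like(t)
    for i in range(t.size):
        ct[i] = np.trapezoid(integ[i, : i + 1], t[: i + 1]) if i > 0 else 0.0
    return ktrans * ct


def biexponential_aif(
    times: np.ndarray,
    dose: float = 0.1,
    a1: float = 3.99,
    a2: float = 4.78,
    m1: float = 0.144 / 60.0,
    m2: float = 0.0111 / 60.0,
    onset_s: float = 0.0,
) -> np.ndarray:
    """Bi-exponential population plasma input function.

    ``Cp(t) = dose * (a1 exp(-m1 (t-t0)) + a2 exp(-m2 (t-t0)))`` for
    ``t >= onset_s``, zero before.  Defaults are the classical population
    amplitudes (kg/L) and rates (converted to 1/s) for a standard
    gadolinium dose (mmol/kg).
    """
    t = np.asarray(times, dtype=float)
    dt = t - onset_s
    cp = dose * (a1 * np.exp(-m1 * dt) + a2 * np.exp(-m2 * dt))
    return np.where(dt >= 0, cp, 0.0)


def fit_tofts(
    times: np.ndarray,
    ct: np.ndarray,
    cp: np.ndarray,
) -> DCEFit:
    """Fit (Ktrans, kep) of the Tofts-Kermode model by bounded nonlinear
    least squares with a small multi-start over kep.

    ``times`` must be a common, strictly increasing grid for the tissue
    curve ``ct`` and the plasma input ``cp``.  A zero tissue curve returns
    Ktrans = 0; degenerate (all-zero) Cp is an error; non-convergence is
    flagged, not raised.
    """
    t = np.asarray(times, dtype=float)
    ct = np.asarray(ct, dtype=float)
    cp = np.asarray(cp, dtype=float)
    if not (t.shape == ct.shape == cp.shape):
        raise ValueError("times, ct and cp must share one grid")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(cp < 0):
        raise ValueError("cp must be non-negative")
    if not np.any(cp > 0):
        raise ValueError("degenerate plasma input: cp is identically zero")
    if not np.any(np.abs(ct) > 0):
        return DCEFit(ktrans=0.0, kep=float("nan"), ve=float("nan"),
                      rss=0.0, converged=True)

    def residuals(theta):
        return tofts_forward(t, cp, theta[0], theta[1]) - ct

    # crude Ktrans scale from the curve areas for the starts
    area_cp = np.trapezoid(cp, t)
    area_ct = np.trapezoid(ct, t)
    k0 = abs(area_ct) / area_cp if area_cp > 0 else 1e-3
    k0 = min(max(k0 / max(t[-1], 1.0), 1e-6), KTRANS_BOUNDS[1])

    best = None
    for kep0 in _KEP_STARTS:
        try:
            res = least_squares(
                residuals,
                x0=[max(k0, 1e-6), kep0],
                bounds=([KTRANS_BOUNDS[0], KEP_BOUNDS[0]],
                        [KTRANS_BOUNDS[1], KEP_BOUNDS[1]]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return DCEFit(float("nan"), float("nan"), float("nan"), float("nan"), False)
    ktrans, kep = float(best.x[0]), float(best.x[1])
    ve = ktrans / kep if kep > 0 else float("nan")
    return DCEFit(ktrans=ktrans, kep=kep, ve=ve,
                  rss=float(2 * best.cost), converged=bool(best.success))
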