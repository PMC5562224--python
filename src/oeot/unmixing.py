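"""Linear spectral unmixing of multispectral optoacoustic images.

Multispectral optoacoustic (photoacoustic) tomography records, at each
wavelength, an image whose intensity is proportional to the locally absorbed
optical energy.  In the 700-880 nm window the dominant tissue absorbers are
oxy- and deoxy-haemoglobin, so the per-pixel spectrum is modelled as a
non-negative linear combination

    s(lambda) ~= eps_HbO2(lambda) * c_HbO2 + eps_Hb(lambda) * c_Hb

and the component weights are recovered by a pseudoinverse (ordinary least
squares) inversion.  From the weights we form the total haemoglobin signal
THb = c_HbO2 + c_Hb and the apparent oxygen saturation
SO2 = c_HbO2 / (c_HbO2 + c_Hb).  Because the light fluence is *not*
corrected, SO2 here is an apparent, relative metric (often written
SO2^MSOT): ratios and changes are meaningful, absolute calibration is not.

Component weights are kept in arbitrary (relative) units; negative weights
that the unconstrained least-squares estimator can produce under noise are
retained for diagnostics and clipped to zero only when SO2 and THb are
formed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ExtinctionTable",
    "MultispectralSeries",
    "ChromophoreMaps",
    "IllPosedUnmixingError",
    "load_extinction_table",
    "unmix_spectrum",
    "unmix_roi_series",
    "unmix_pixelwise",
]

#: relative THb level below which a pixel is declared invalid (fraction of
#: the median THb over the unmixed field); avoids 0/0 in the SO2 ratio.
DEFAULT_THB_EPSILON_REL = 1e-6

#: condition-number limit above which the spectral design matrix is treated
#: as rank deficient (e.g. a single wavelength, or isosbestic-only sets).
MAX_CONDITION_NUMBER = 1e8


class IllPosedUnmixingError(ValueError):
    """Raised when the spectral design matrix cannot separate HbO2 from Hb."""


# ---------------------------------------------------------------------------
# Extinction spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction spectra of oxy- and deoxy-haemoglobin.

    Units are arbitrary but must be consistent between the two chromophores;
    the unmixing result is invariant to an overall rescaling of the table.
    A valid table brackets the near-infrared isosbestic point (~800 nm)
    where the two spectra cross.
    """

    wavelengths: np.ndarray
    eps_hbo2: np.ndarray
    eps_hb: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        e1 = np.asarray(self.eps_hbo2, dtype=float)
        e2 = np.asarray(self.eps_hb, dtype=float)
        if not (wl.shape == e1.shape == e2.shape) or wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelengths/eps_hbo2/eps_hb must be 1-D, equal length, >= 2 rows")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly ascending")
        if np.any(e1 <= 0) or np.any(e2 <= 0):
            raise ValueError("extinction coefficients must be positive")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "eps_hbo2", e1)
        object.__setattr__(self, "eps_hb", e2)

    def interp(self, wavelengths: Sequence[float]) -> np.ndarray:
        """Linearly interpolated extinctions at ``wavelengths``.

        Returns an ``(n, 2)`` design matrix with columns (eps_hbo2, eps_hb).
        Extrapolation outside the tabulated range is refused.
        """
        wl = np.atleast_1d(np.asarray(wavelengths, dtype=float))
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if np.any(wl < lo) or np.any(wl > hi):
            raise ValueError(
                f"requested wavelength outside tabulated range [{lo:g}, {hi:g}] nm"
            )
        e1 = np.interp(wl, self.wavelengths, self.eps_hbo2)
        e2 = np.interp(wl, self.wavelengths, self.eps_hb)
        return np.column_stack([e1, e2])

    def design_matrix(self, wavelengths: Sequence[float]) -> np.ndarray:
        """Alias of :meth:`interp`; the spectral forward operator ``E``."""
        return self.interp(wavelengths)

    def isosbestic_wavelength(self, near_nm: float = 800.0, tol: float = 0.05) -> float:
        """Tabulated wavelength closest to ``near_nm`` where the two spectra
        agree to within ``tol`` (relative to eps_hb).  Raises if none exists.
        """
        rel = np.abs(self.eps_hbo2 - self.eps_hb) / self.eps_hb
        ok = np.flatnonzero(rel < tol)
        if ok.size == 0:
            raise ValueError("table has no isosbestic wavelength at the requested tolerance")
        best = ok[np.argmin(np.abs(self.wavelengths[ok] - near_nm))]
        return float(self.wavelengths[best])


def load_extinction_table(path: str | Path | None = None) -> ExtinctionTable:
    """Load an extinction table from CSV (header ``wavelength_nm,eps_hbo2,eps_hb``).

    With ``path=None`` the packaged haemoglobin compilation is used: a
    *synthetic* table approximating the standard tabulated oxy/deoxy
    haemoglobin molar extinction spectra (deoxy peak near 760 nm, isosbestic
    crossing near 798 nm).  Only the spectral shape matters for unmixing.
    """
    if path is None:
        ref = resources.files("oeot.data") / "hb_extinction_synthetic.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = ["wavelength_nm", "eps_hbo2", "eps_hb"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"extinction CSV must have header {','.join(required)}")
    return ExtinctionTable(
        wavelengths=df["wavelength_nm"].to_numpy(float),
        eps_hbo2=df["eps_hbo2"].to_numpy(float),
        eps_hb=df["eps_hb"].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class MultispectralSeries:
    """A multispectral optoacoustic image time series.

    ``data`` is indexed ``(frame, wavelength, row, col)``; ``frame_times``
    are seconds from scan start and ``pixel_spacing`` is the isotropic pixel
    size in mm (75 um in the reference acquisition).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    frame_times: np.ndarray
    pixel_spacing: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (frame, wavelength, row, col)")
        if self.data.shape[0] != self.frame_times.size:
            raise ValueError("frame_times length must match frame axis")
        if self.data.shape[1] != self.wavelengths.size:
            raise ValueError("wavelengths length must match wavelength axis")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if not self.pixel_spacing > 0:
            raise ValueError("pixel_spacing must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    # -- I/O ---------------------------------------------------------------
    def to_tiff(self, path: str | Path) -> None:
        """Write a frame-major multi-page float32 TIFF plus a JSON sidecar
        (``<path>.json``) declaring page ordering, wavelengths, frame times
        and pixel spacing."""
        path = Path(path)
        n_f, n_w, n_r, n_c = self.data.shape
        pages = self.data.reshape(n_f * n_w, n_r, n_c).astype(np.float32)
        tifffile.imwrite(path, pages)
        sidecar = {
            "page_order": "frame_major",
            "n_frames": n_f,
            "n_wavelengths": n_w,
            "wavelengths_nm": self.wavelengths.tolist(),
            "frame_times_s": self.frame_times.tolist(),
            "pixel_spacing_mm": self.pixel_spacing,
            "meta": self.meta,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tiff(cls, path: str | Path) -> "MultispectralSeries":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        pages = np.asarray(tifffile.imread(path), dtype=float)
        n_f, n_w = sidecar["n_frames"], sidecar["n_wavelengths"]
        data = pages.reshape(n_f, n_w, *pages.shape[-2:])
        return cls(
            data=data,
            wavelengths=np.asarray(sidecar["wavelengths_nm"], float),
            frame_times=np.asarray(sidecar["frame_times_s"], float),
            pixel_spacing=float(sidecar["pixel_spacing_mm"]),
            meta=sidecar.get("meta", {}),
        )

    def to_nifti(self, path: str | Path) -> None:
        """Write as NIfTI-1 with dims (row, col, wavelength, frame); spacing
        in the header, wavelengths/times in a JSON sidecar."""
        import nibabel as nib

        vol = np.transpose(self.data, (2, 3, 1, 0)).astype(np.float32)
        affine = np.diag([self.pixel_spacing, self.pixel_spacing, 1.0, 1.0])
        nib.save(nib.Nifti1Image(vol, affine), str(path))
        sidecar = {
            "wavelengths_nm": self.wavelengths.tolist(),
            "frame_times_s": self.frame_times.tolist(),
            "meta": self.meta,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "MultispectralSeries":
        import nibabel as nib

        img = nib.load(str(path))
        sidecar = json.loads(Path(str(path) + ".json").read_text())
        vol = np.asarray(img.dataobj, dtype=float)  # (row, col, wavelength, frame)
        data = np.transpose(vol, (3, 2, 0, 1))
        spacing = float(img.header.get_zooms()[0])
        return cls(
            data=data,
            wavelengths=np.asarray(sidecar["wavelengths_nm"], float),
            frame_times=np.asarray(sidecar["frame_times_s"], float),
            pixel_spacing=spacing,
            meta=sidecar.get("meta", {}),
        )


@dataclass
class ChromophoreMaps:
    """Per-frame haemoglobin component maps.

    ``c_hbo2``/``c_hb`` hold the raw (possibly negative) least-squares
    weights; ``thb`` and ``so2`` are formed after clipping negatives to
    zero.  ``so2`` is defined only where ``valid_mask`` is true (NaN
    elsewhere).
    """

    c_hbo2: np.ndarray
    c_hb: np.ndarray
    thb: np.ndarray
    so2: np.ndarray
    valid_mask: np.ndarray
    pixel_spacing: float


# ---------------------------------------------------------------------------
# Unmixing operations
# ---------------------------------------------------------------------------

def _pinv_operator(table: ExtinctionTable, wavelengths: Sequence[float]) -> np.ndarray:
    """Pseudoinverse of the (n_wavelengths, 2) design matrix; raises
    :class:`IllPosedUnmixingError` when HbO2/Hb are not separable."""
    E = table.design_matrix(wavelengths)
    if E.shape[0] < 2:
        raise IllPosedUnmixingError("at least 2 wavelengths are required")
    if np.linalg.cond(E) > MAX_CONDITION_NUMBER:
        raise IllPosedUnmixingError(
            "spectral design matrix is (numerically) rank deficient; "
            "wavelength set cannot separate HbO2 from Hb"
        )
    return np.linalg.pinv(E)


def unmix_spectrum(
    spectrum: Sequence[float],
    table: ExtinctionTable,
    wavelengths: Sequence[float],
) -> tuple[float, float]:
    """Least-squares unmixing of one optoacoustic spectrum.

    Solves ``spectrum ~= E @ (c_hbo2, c_hb)`` by pseudoinverse and returns
    the raw weights (negative values are possible under noise and are *not*
    clipped here).
    """
    s = np.asarray(spectrum, dtype=float)
    wl = np.atleast_1d(np.asarray(wavelengths, float))
    if s.shape != wl.shape:
        raise ValueError("spectrum and wavelengths must have equal length")
    pinv = _pinv_operator(table, wl)
    c = pinv @ s
    return float(c[0]), float(c[1])


def _so2_from_weights(c_hbo2: np.ndarray, c_hb: np.ndarray, eps: float):
    """SO2 and THb from raw weights: clip negatives, guard the denominator."""
    p = np.clip(c_hbo2, 0.0, None)
    q = np.clip(c_hb, 0.0, None)
    thb = p + q
    valid = thb > eps
    so2 = np.full(np.shape(thb), np.nan, dtype=float)
    np.divide(p, thb, out=so2, where=valid)
    return thb, so2, valid


def unmix_roi_series(
    series: MultispectralSeries,
    roi: np.ndarray,
    table: ExtinctionTable | None = None,
    thb_epsilon: float | None = None,
) -> pd.DataFrame:
    """Region-level unmixing: average the spectrum over the ROI, then unmix.

    For each frame the optoacoustic spectrum is averaged across all ROI
    pixels and unmixed; SO2 is then formed from the clipped weights.  Frames
    whose clipped THb falls below ``thb_epsilon`` (default: 1e-6 x median
    THb over frames) are flagged invalid and carry NaN SO2.

    Returns a DataFrame with columns
    ``time_s, c_hbo2, c_hb, thb, so2, valid``.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != series.data.shape[2:]:
        raise ValueError("ROI shape must match image shape")
    if not roi.any():
        raise ValueError("ROI is empty")
    if table is None:
        table = load_extinction_table()

    spectra = series.data[:, :, roi].mean(axis=2)  # (frame, wavelength)
    pinv = _pinv_operator(table, series.wavelengths)
    c = spectra @ pinv.T  # (frame, 2)
    c_hbo2, c_hb = c[:, 0], c[:, 1]

    thb_raw = np.clip(c_hbo2, 0, None) + np.clip(c_hb, 0, None)
    if thb_epsilon is None:
        med = np.median(thb_raw)
        thb_epsilon = DEFAULT_THB_EPSILON_REL * med if med > 0 else np.inf
    thb, so2, valid = _so2_from_weights(c_hbo2, c_hb, thb_epsilon)
    if not valid.any():
        raise ValueError("all frames invalid: ROI carries no haemoglobin signal")
    return pd.DataFrame(
        {
            "time_s": series.frame_times,
            "c_hbo2": c_hbo2,
            "c_hb": c_hb,
            "thb": thb,
            "so2": so2,
            "valid": valid,
        }
    )


def block_downsample(image: np.ndarray, factor: int) -> np.ndarray:
    """Non-overlapping ``factor x factor`` block mean over the last two axes;
    trailing rows/cols that do not fill a block are discarded."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return image
    *lead, n_r, n_c = image.shape
    r, c = n_r // factor, n_c // factor
    trimmed = image[..., : r * factor, : c * factor]
    return trimmed.reshape(*lead, r, factor, c, factor).mean(axis=(-1, -3))


def unmix_pixelwise(
    series: MultispectralSeries,
    target_spacing: float = 0.225,
    table: ExtinctionTable | None = None,
    thb_epsilon: float | None = None,
) -> list[ChromophoreMaps]:
    """Per-pixel unmixing on a coarser grid.

    Signal images are first block-averaged down to ``target_spacing`` (the
    reference pipeline maps 75 um reconstructions onto a 225 um grid, a 3x3
    block mean) and each coarse pixel's spectrum is unmixed independently.
    Downsampling happens on the signal images *before* unmixing.

    Returns one :class:`ChromophoreMaps` per frame.
    """
    ratio = target_spacing / series.pixel_spacing
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"target_spacing {target_spacing} mm is not an integer multiple of "
            f"pixel_spacing {series.pixel_spacing} mm"
        )
    if table is None:
        table = load_extinction_table()
    pinv = _pinv_operator(table, series.wavelengths)

    coarse = block_downsample(series.data, factor)  # (frame, wl, r, c)
    n_f, n_w, n_r, n_c = coarse.shape
    flat = coarse.reshape(n_f, n_w, n_r * n_c)
    c = np.einsum("kw,fwp->fkp", pinv, flat)  # (frame, 2, pix)
    c_hbo2 = c[:, 0].reshape(n_f, n_r, n_c)
    c_hb = c[:, 1].reshape(n_f, n_r, n_c)

    out: list[ChromophoreMaps] = []
    for f in range(n_f):
        eps = thb_epsilon
        if eps is None:
            thb_raw = np.clip(c_hbo2[f], 0, None) + np.clip(c_hb[f], 0, None)
            med = np.median(thb_raw[thb_raw > 0]) if (thb_raw > 0).any() else 0.0
            eps = DEFAULT_THB_EPSILON_REL * med if med > 0 else np.inf
        thb, so2, valid = _so2_from_weights(c_hbo2[f], c_hb[f], eps)
        out.append(
            ChromophoreMaps(
                c_hbo2=c_hbo2[f],
                c_hb=c_hb[f],
                thb=thb,
                so2=so2,
                valid_mask=valid,
                pixel_spacing=series.pixel_spacing * factor,
            )
        )
    return out
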