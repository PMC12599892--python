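"""Brillouin microscopy: VIPA spectral calibration and shift extraction.

Brillouin light scattering measures the GHz frequency shift of photons that
have interacted with acoustic phonons; in backscattering the shift is
``Omega = 2 n v / lambda`` (refractive index n, acoustic velocity v, vacuum
wavelength lambda), and a larger shift generally indicates a stiffer
material.  A two-stage VIPA spectrometer disperses the scattered light onto
a camera, producing periodic spectral orders separated by the free spectral
range (FSR, ~30 GHz here); within each order an anti-Stokes and a Stokes
peak flank the (suppressed) laser line.

Peak-separation convention
--------------------------
Adjacent anti-Stokes/Stokes peaks *within one order* are separated by

    d_px = (FSR - 2 Omega) / dispersion        [pixels]

symmetric about the order center.  Decoding inverts this:
``Omega = (FSR - dispersion * d_px) / 2``.  The synthetic generator uses the
identical convention, so round trips are exact.  Calibration with >= 2
reference materials of known shift is linear in this separation domain:

    d_px(Omega) = FSR/dispersion - (2/dispersion) * Omega

so a straight-line fit of separation against known shift yields dispersion
(GHz/pixel) from the slope and the FSR from the intercept, in closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal

from .errors import (
    CalibrationError,
    ConfigurationError,
    FitConvergenceError,
    MapError,
    OrderAmbiguityError,
    PeakDetectionError,
)

__all__ = [
    "BrillouinSpectrum",
    "PeakFit",
    "SpectralCalibration",
    "ShiftMeasurement",
    "BrillouinMap",
    "ROISummary",
    "theoretical_shift",
    "fit_spectral_peaks",
    "calibrate",
    "shift_from_spectrum",
    "map_shifts",
]

MIN_PIXELS = 64


@dataclass
class BrillouinSpectrum:
    """One camera readout: intensity (counts) versus pixel."""

    intensity: np.ndarray
    exposure_s: float | None = None
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 1:
            raise ConfigurationError("intensity must be 1-D")
        if self.intensity.size < MIN_PIXELS:
            raise ConfigurationError(f"need >= {MIN_PIXELS} pixels")
        if not np.all(np.isfinite(self.intensity)):
            raise ConfigurationError("intensity must be finite")
        if np.any(self.intensity < 0):
            raise ConfigurationError("intensity must be non-negative counts")

    @property
    def n_pixels(self) -> int:
        return self.intensity.size


@dataclass
class PeakFit:
    """One fitted Lorentzian line."""

    center_px: float
    fwhm_px: float
    amplitude: float
    center_stderr_px: float
    fwhm_stderr_px: float
    rmse: float


@dataclass
class SpectralCalibration:
    """Pixel -> GHz mapping derived from reference materials."""

    dispersion_ghz_per_px: float
    free_spectral_range_ghz: float
    order_anchor_px: float
    residuals_ghz: dict
    materials_used: list
    residual_rms_ghz: float
    high_residual_warning: bool = False

    def __post_init__(self):
        if self.dispersion_ghz_per_px <= 0:
            raise CalibrationError("dispersion must be positive")
        if self.free_spectral_range_ghz <= 0:
            raise CalibrationError("free spectral range must be positive")


@dataclass
class ShiftMeasurement:
    shift_ghz: float
    shift_stderr_ghz: float
    linewidth_ghz: float
    fit_rmse: float
    peaks_used: int


@dataclass
class ROISummary:
    mean_ghz: float
    sd_ghz: float
    n_valid: int
    invalid_fraction: float


@dataclass
class BrillouinMap:
    """Per-point shift over a 2-D scan; invalid points are flagged, not dropped."""

    shift_ghz: np.ndarray
    stderr_ghz: np.ndarray
    valid: np.ndarray
    pixel_size_um: float
    roi_mask: np.ndarray | None = None


def theoretical_shift(refractive_index: float, acoustic_velocity_mps: float, wavelength_nm: float) -> float:
    """Backscattering Brillouin shift Omega = 2 n v / lambda, in GHz.

    With v in m/s and lambda in nm the expression 2*n*v/lambda_nm already
    lands in GHz (1e9 Hz cancels 1e-9 m).
    """
    if refractive_index <= 0 or wavelength_nm <= 0:
        raise ConfigurationError("refractive index and wavelength must be positive")
    if acoustic_velocity_mps < 0:
        raise ConfigurationError("acoustic velocity must be non-negative")
    return 2.0 * refractive_index * acoustic_velocity_mps / wavelength_nm


def _lorentzian(x, amplitude, center, hwhm, offset):
    return amplitude * hwhm**2 / ((x - center) ** 2 + hwhm**2) + offset


def fit_spectral_peaks(
    spectrum: BrillouinSpectrum,
    n_peaks: int,
    *,
    baseline_window_px: int = 51,
    prominence_fraction: float = 0.05,
    min_peak_distance_px: int = 10,
    fit_halfwidth_px: int | None = None,
) -> list[PeakFit]:
    """Locate and fit ``n_peaks`` Lorentzian lines, centers sorted ascending.

    A running-median baseline (``baseline_window_px``) is subtracted before
    peak seeding, which makes the result invariant to constant offsets.
    Seeds closer than ``min_peak_distance_px`` are merged (shot noise can
    split a single line top into neighboring local maxima; lines within a
    linewidth are unresolvable regardless).  Each peak is then fit by
    Lorentzian least squares in a local window around its seed.
    """
    if n_peaks < 1:
        raise ConfigurationError("n_peaks must be >= 1")
    y = spectrum.intensity
    baseline = ndimage.median_filter(y, size=baseline_window_px, mode="nearest")
    ys = y - baseline
    top = float(ys.max())
    if top <= 0:
        raise PeakDetectionError("no peaks found: spectrum has no excursion above baseline")

    peaks, props = signal.find_peaks(
        ys, prominence=prominence_fraction * top, distance=min_peak_distance_px
    )
    if len(peaks) < n_peaks:
        raise PeakDetectionError(
            f"found {len(peaks)} peak(s), need {n_peaks}", found=list(map(int, peaks))
        )
    order = np.argsort(props["prominences"])[::-1][:n_peaks]
    seeds = np.sort(peaks[order])
    widths = signal.peak_widths(ys, seeds, rel_height=0.5)[0]

    x = np.arange(spectrum.n_pixels, dtype=float)
    out: list[PeakFit] = []
    for seed, w in zip(seeds, widths):
        w = max(float(w), 2.0)
        half = fit_halfwidth_px if fit_halfwidth_px is not None else max(int(round(3 * w)), 10)
        lo, hi = max(0, seed - half), min(spectrum.n_pixels, seed + half + 1)
        xs, ysec = x[lo:hi], y[lo:hi]
        p0 = (float(ys[seed]), float(seed), w / 2.0, float(baseline[seed]))
        bounds = (
            [0.0, float(lo), 0.3, -np.inf],
            [np.inf, float(hi - 1), float(hi - lo), np.inf],
        )
        try:
            popt, pcov = optimize.curve_fit(_lorentzian, xs, ysec, p0=p0, bounds=bounds, maxfev=20000)
        except RuntimeError as exc:
            resid = ysec - _lorentzian(xs, *p0)
            raise FitConvergenceError(
                f"Lorentzian fit failed near px {seed}: {exc}; seed residual RMS "
                f"{np.sqrt(np.mean(resid**2)):.3g}"
            ) from exc
        perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        resid = ysec - _lorentzian(xs, *popt)
        out.append(
            PeakFit(
                center_px=float(popt[1]),
                fwhm_px=float(2 * popt[2]),
                amplitude=float(popt[0]),
                center_stderr_px=float(perr[1]),
                fwhm_stderr_px=float(2 * perr[2]),
                rmse=float(np.sqrt(np.mean(resid**2))),
            )
        )
    out.sort(key=lambda p: p.center_px)
    return out


def _pair_separations(peaks: list[PeakFit]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Intra-order separations from 4 sorted peaks: pairs (0,1) and (2,3)."""
    if len(peaks) != 4:
        raise ConfigurationError("expected 4 peaks (two orders, anti-Stokes/Stokes each)")
    c = np.array([p.center_px for p in peaks])
    v = np.array([p.center_stderr_px for p in peaks]) ** 2
    seps = np.array([c[1] - c[0], c[3] - c[2]])
    sep_vars = np.array([v[0] + v[1], v[2] + v[3]])
    midpoints = np.array([(c[0] + c[1]) / 2, (c[2] + c[3]) / 2])
    if np.any(seps <= 0):
        raise PeakDetectionError("degenerate peak ordering: non-positive intra-order separation")
    return seps, sep_vars, midpoints


def calibrate(
    calib_spectra: list[tuple[BrillouinSpectrum, float]],
    *,
    residual_tolerance_ghz: float = 0.05,
    **peak_kwargs,
) -> SpectralCalibration:
    """Solve for dispersion and FSR from reference materials of known shift.

    For each material the mean intra-order anti-Stokes/Stokes separation is
    measured; the model ``d_px = FSR/dispersion - (2/dispersion) * Omega`` is
    linear in the known shifts, so a least-squares line gives
    ``dispersion = -2/slope`` and ``FSR = intercept * dispersion``.  With
    exactly two materials the 2x2 system is determined and residuals vanish.
    """
    if len(calib_spectra) < 2:
        raise CalibrationError("need at least 2 calibration materials")
    shifts = np.array([s for _, s in calib_spectra], dtype=float)
    if np.min(np.diff(np.sort(shifts))) < 1e-9:
        raise CalibrationError("duplicate known shifts: calibration system is degenerate")

    seps, mids, names = [], [], []
    for spec, _shift in calib_spectra:
        peaks = fit_spectral_peaks(spec, 4, **peak_kwargs)
        s, _v, m = _pair_separations(peaks)
        seps.append(float(s.mean()))
        mids.append(float(m.mean()))
        names.append(spec.label or f"material@{_shift:.3f}GHz")
    seps = np.array(seps)

    slope, intercept = np.polyfit(shifts, seps, 1)
    if slope >= 0:
        raise CalibrationError("separation does not decrease with shift: check spectra/pairing")
    dispersion = -2.0 / slope
    fsr = float(intercept * dispersion)

    residuals = {
        name: float(omega - (fsr - dispersion * sep) / 2.0)
        for name, omega, sep in zip(names, shifts, seps)
    }
    rms = float(np.sqrt(np.mean(np.array(list(residuals.values())) ** 2)))
    high = rms > residual_tolerance_ghz
    if high:
        warnings.warn(
            f"calibration residual RMS {rms:.3g} GHz exceeds {residual_tolerance_ghz} GHz",
            stacklevel=2,
        )
    return SpectralCalibration(
        dispersion_ghz_per_px=float(dispersion),
        free_spectral_range_ghz=fsr,
        order_anchor_px=float(np.mean(mids)),
        residuals_ghz=residuals,
        materials_used=names,
        residual_rms_ghz=rms,
        high_residual_warning=high,
    )


def shift_from_spectrum(
    spectrum: BrillouinSpectrum, cal: SpectralCalibration, **peak_kwargs
) -> ShiftMeasurement:
    """Decode the Brillouin shift: Omega = (FSR - dispersion * d_px) / 2.

    The two intra-order separations (one per simulated/observed order) are
    averaged; the stderr propagates the fitted center covariances through
    dOmega/d(d_px) = -dispersion/2.
    """
    peaks = fit_spectral_peaks(spectrum, 4, **peak_kwargs)
    seps, sep_vars, _mids = _pair_separations(peaks)
    d_px = float(seps.mean())
    var_mean_sep = float(sep_vars.sum()) / 4.0
    fsr, disp = cal.free_spectral_range_ghz, cal.dispersion_ghz_per_px
    omega = (fsr - disp * d_px) / 2.0
    if not (0.0 < omega < fsr / 2.0):
        raise OrderAmbiguityError(
            f"decoded shift {omega:.3f} GHz outside (0, FSR/2) = (0, {fsr / 2:.3f}): order ambiguity"
        )
    return ShiftMeasurement(
        shift_ghz=float(omega),
        shift_stderr_ghz=float(disp / 2.0 * np.sqrt(var_mean_sep)),
        linewidth_ghz=float(np.mean([p.fwhm_px for p in peaks]) * disp),
        fit_rmse=float(np.mean([p.rmse for p in peaks])),
        peaks_used=4,
    )


def map_shifts(
    spectra_grid,
    cal: SpectralCalibration,
    roi: np.ndarray | None = None,
    pixel_size_um: float = 1.0,
    **peak_kwargs,
) -> tuple[BrillouinMap, ROISummary]:
    """Decode a rectangular grid of spectra into a shift map plus ROI summary.

    ``spectra_grid`` is a nested sequence (rows of :class:`BrillouinSpectrum`).
    Points where peak fitting or decoding fails are flagged invalid (NaN) and
    counted; the ROI mean ± SD is taken over valid points only.
    """
    rows = list(spectra_grid)
    if not rows or not rows[0]:
        raise MapError("empty spectra grid")
    ny, nx = len(rows), len(rows[0])
    if any(len(r) != nx for r in rows):
        raise MapError("ragged spectra grid: all rows must have equal length")

    shift = np.full((ny, nx), np.nan)
    stderr = np.full((ny, nx), np.nan)
    valid = np.zeros((ny, nx), dtype=bool)
    for j, row in enumerate(rows):
        for i, spec in enumerate(row):
            try:
                meas = shift_from_spectrum(spec, cal, **peak_kwargs)
            except (PeakDetectionError, FitConvergenceError, OrderAmbiguityError):
                continue
            shift[j, i] = meas.shift_ghz
            stderr[j, i] = meas.shift_stderr_ghz
            valid[j, i] = True

    if roi is None:
        roi_mask = np.ones((ny, nx), dtype=bool)
    else:
        roi_mask = np.asarray(roi, dtype=bool)
        if roi_mask.shape != (ny, nx):
            raise MapError("ROI mask shape must match the grid")
    use = roi_mask & valid
    n_roi = int(roi_mask.sum())
    if n_roi == 0 or use.sum() == 0:
        raise MapError("ROI contains no valid shift measurements")
    vals = shift[use]
    summary = ROISummary(
        mean_ghz=float(vals.mean()),
        sd_ghz=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        n_valid=int(use.sum()),
        invalid_fraction=float(1.0 - use.sum() / n_roi),
    )
    return BrillouinMap(shift, stderr, valid, pixel_size_um, roi_mask), summary
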