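"""Wave-based optical coherence elastography (OCE) inversion.

A nanosecond laser pulse vaporizes perfluorocarbon nanodroplets ("nanobombs")
deposited around a spheroid; the transient vaporization launches a mechanical
wave whose longitudinal component is tracked with phase-sensitive OCT as a
depth x time ("spatiotemporal") map.  The wave speed ``c`` is the inverse
slope of the per-depth arrival delay versus axial distance, and Young's
modulus follows from the bulk shear-wave relation

    c = sqrt(G / rho),   G = E / (2 (1 + nu))   =>   E = 2 rho (1 + nu) c^2

with density ``rho`` (default 1000 kg/m^3) and Poisson's ratio ``nu``
(default 0.49, nearly incompressible soft tissue).

Processing chain
----------------
1. :func:`phase_to_displacement` — optical phase to axial displacement,
   ``u = lambda0 * dphi / (4 pi n)``, with per-depth temporal unwrapping.
2. :func:`estimate_delays` — per-depth arrival delay relative to a reference
   depth via normalized cross-correlation with parabolic sub-frame
   interpolation of the correlation peak.
3. :func:`fit_wave_speed` — delay-vs-depth line fit (OLS or Theil–Sen);
   speed is the inverse slope.
4. :func:`young_modulus` — shear-wave equation.
5. :func:`analyze_oce_measurement` — runs the chain over a triplicate of
   maps and aggregates replicate speeds as mean ± SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import signal, stats

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    MeasurementFailureError,
    NoPropagatingWaveError,
    SpheromechError,
)

__all__ = [
    "SpatioTemporalMap",
    "DelayProfile",
    "WaveSpeedFit",
    "ElasticityParams",
    "ElasticityResult",
    "phase_to_displacement",
    "estimate_delays",
    "fit_wave_speed",
    "young_modulus",
    "analyze_oce_measurement",
]

MIN_DEPTH_SAMPLES = 8
MIN_TIME_SAMPLES = 8


@dataclass
class SpatioTemporalMap:
    """Depth x time record of the propagating wave.

    ``values`` holds optical phase in rad (``kind="phase"``) or axial
    displacement in nm (``kind="displacement"``).  ``axial_pitch_um`` is the
    optical-path-corrected physical depth increment per axial sample; the
    synthetic generator uses the same convention, so forward/inverse round
    trips are exact.
    """

    values: np.ndarray
    kind: Literal["phase", "displacement"]
    axial_pitch_um: float
    frame_interval_s: float
    center_wavelength_nm: float | None = None
    refractive_index: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigurationError("values must be a 2-D depth x time array")
        nz, nt = self.values.shape
        if nz < MIN_DEPTH_SAMPLES or nt < MIN_TIME_SAMPLES:
            raise ConfigurationError(
                f"map must be at least {MIN_DEPTH_SAMPLES} x {MIN_TIME_SAMPLES}, got {nz} x {nt}"
            )
        if self.axial_pitch_um <= 0 or self.frame_interval_s <= 0:
            raise ConfigurationError("axial_pitch_um and frame_interval_s must be positive")
        if self.kind not in ("phase", "displacement"):
            raise ConfigurationError(f"unknown kind {self.kind!r}")
        if self.kind == "phase":
            v = self.values
            if np.nanmax(v) > np.pi + 1e-9 or np.nanmin(v) <= -np.pi - 1e-9:
                raise ConfigurationError("phase values must lie in (-pi, pi]")

    @property
    def n_depths(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def depths_um(self) -> np.ndarray:
        return np.arange(self.n_depths) * self.axial_pitch_um

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_times) * self.frame_interval_s


@dataclass
class DelayProfile:
    """Arrival delay tau(z) relative to a reference depth, with per-depth quality."""

    depths_um: np.ndarray
    delays_s: np.ndarray
    quality: np.ndarray  # peak normalized correlation per depth, 0 for invalid
    reference_depth_um: float

    def __post_init__(self):
        self.depths_um = np.asarray(self.depths_um, dtype=float)
        self.delays_s = np.asarray(self.delays_s, dtype=float)
        self.quality = np.asarray(self.quality, dtype=float)
        if not (len(self.depths_um) == len(self.delays_s) == len(self.quality)):
            raise ConfigurationError("profile arrays must have equal length")

    def subset(self, mask: np.ndarray) -> "DelayProfile":
        mask = np.asarray(mask, dtype=bool)
        return DelayProfile(
            self.depths_um[mask], self.delays_s[mask], self.quality[mask], self.reference_depth_um
        )


@dataclass
class WaveSpeedFit:
    speed_mps: float
    stderr_mps: float
    r_squared: float
    n_depths: int
    slope_s_per_m: float
    intercept_s: float
    method: str


@dataclass
class ElasticityParams:
    """Material constants for the shear-wave equation."""

    density_kg_m3: float = 1000.0
    poisson_ratio: float = 0.49

    def __post_init__(self):
        if self.density_kg_m3 <= 0:
            raise ConfigurationError("density must be positive")
        if not (0 <= self.poisson_ratio < 0.5):
            raise ConfigurationError("Poisson's ratio must lie in [0, 0.5)")


@dataclass
class ElasticityResult:
    """Triplicate-aggregated elasticity for one spheroid measurement."""

    wave_speed_mps: float
    speed_stderr_mps: float
    young_modulus_pa: float
    r_squared: float
    n_depths_used: int
    replicate_speeds_mps: list
    method_notes: str = ""


def phase_to_displacement(m: SpatioTemporalMap, unwrap: bool = True) -> SpatioTemporalMap:
    """Convert optical phase to axial displacement, u = lambda0 * dphi / (4 pi n).

    Temporal 1-D unwrapping is applied per depth first (default), so
    physically smooth displacements that wrapped during acquisition are
    recovered as long as frame-to-frame phase steps stay below pi.
    """
    if m.kind != "phase":
        raise ConfigurationError("phase_to_displacement requires kind='phase'")
    if m.center_wavelength_nm is None or m.refractive_index is None:
        raise ConfigurationError("center_wavelength_nm and refractive_index must be set")
    phi = np.unwrap(m.values, axis=1) if unwrap else m.values
    u_nm = m.center_wavelength_nm * phi / (4.0 * np.pi * m.refractive_index)
    return SpatioTemporalMap(
        values=u_nm,
        kind="displacement",
        axial_pitch_um=m.axial_pitch_um,
        frame_interval_s=m.frame_interval_s,
        center_wavelength_nm=m.center_wavelength_nm,
        refractive_index=m.refractive_index,
        metadata=dict(m.metadata),
    )


def _parabolic_refine(c: np.ndarray, k: int) -> tuple[float, float]:
    """Sub-sample peak location by parabola through (k-1, k, k+1); returns (offset, value)."""
    if k <= 0 or k >= len(c) - 1:
        return 0.0, c[k]
    y0, y1, y2 = c[k - 1], c[k], c[k + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not a strict local max; keep integer peak
        return 0.0, y1
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    peak = y1 - 0.25 * (y0 - y2) * delta
    return delta, float(peak)


def estimate_delays(
    m: SpatioTemporalMap,
    reference_depth_um: float | None = None,
    window: tuple[float, float] | None = None,
) -> DelayProfile:
    """Per-depth arrival delay relative to the reference depth's waveform.

    Uses normalized cross-correlation over the (optionally windowed) time
    axis; the correlation peak is refined with parabolic interpolation to
    sub-frame precision.  Quality is the peak normalized correlation; depths
    with a flat (zero-variance) waveform are flagged invalid (quality 0,
    delay NaN) rather than raising.
    """
    if m.kind != "displacement":
        raise ConfigurationError("estimate_delays requires kind='displacement'; convert phase first")
    values = m.values
    if window is not None:
        t = m.times_s
        sel = (t >= window[0]) & (t <= window[1])
        if sel.sum() < MIN_TIME_SAMPLES:
            raise ConfigurationError("time window retains too few frames")
        values = values[:, sel]
    depths = m.depths_um
    if reference_depth_um is None:
        reference_depth_um = float(depths[0])
    if not (depths[0] - m.axial_pitch_um / 2 <= reference_depth_um <= depths[-1] + m.axial_pitch_um / 2):
        raise ConfigurationError("reference depth lies outside the map")
    ref_idx = int(np.argmin(np.abs(depths - reference_depth_um)))

    nt = values.shape[1]
    ref = values[ref_idx] - values[ref_idx].mean()
    ref_std = ref.std()
    delays = np.full(m.n_depths, np.nan)
    quality = np.zeros(m.n_depths)
    if ref_std == 0:
        return DelayProfile(depths, delays, quality, float(depths[ref_idx]))

    for i in range(m.n_depths):
        w = values[i] - values[i].mean()
        w_std = w.std()
        if w_std == 0:
            continue
        c = signal.correlate(w, ref, mode="full") / (nt * w_std * ref_std)
        k = int(np.argmax(c))
        delta, peak = _parabolic_refine(c, k)
        lag = (k - (nt - 1)) + delta
        delays[i] = lag * m.frame_interval_s
        quality[i] = min(peak, 1.0)
    return DelayProfile(depths, delays, quality, float(depths[ref_idx]))


def fit_wave_speed(
    profile: DelayProfile,
    min_quality: float = 0.5,
    fit: Literal["ols", "theil_sen"] = "ols",
) -> WaveSpeedFit:
    """Fit delay = a + b * depth over depths above the quality threshold.

    Speed is 1/b; its standard error follows from the slope stderr by the
    delta method (se_c = se_b / b^2).  A non-positive slope means delays do
    not increase with depth, i.e. no wave propagating into the sample.
    """
    keep = (profile.quality >= min_quality) & np.isfinite(profile.delays_s)
    n = int(keep.sum())
    if n < 3:
        raise InsufficientDataError(f"only {n} usable depths (need >= 3)")
    z_m = profile.depths_um[keep] * 1e-6
    tau = profile.delays_s[keep]

    if fit == "ols":
        res = stats.linregress(z_m, tau)
        slope, intercept, stderr_b = res.slope, res.intercept, res.stderr
        r2 = float(res.rvalue**2)
    elif fit == "theil_sen":
        ts = stats.theilslopes(tau, z_m)
        slope, intercept = ts.slope, ts.intercept
        # approximate slope stderr from the 95% CI half-width
        stderr_b = (ts.high_slope - ts.low_slope) / (2 * 1.96)
        resid = tau - (intercept + slope * z_m)
        sst = np.sum((tau - tau.mean()) ** 2)
        r2 = float(1.0 - np.sum(resid**2) / sst) if sst > 0 else 0.0
    else:
        raise ConfigurationError(f"unknown fit method {fit!r}")

    if not np.isfinite(slope) or slope <= 0:
        raise NoPropagatingWaveError(
            f"delay-vs-depth slope {slope:.3g} s/m is not positive: no propagating wave detected"
        )
    speed = 1.0 / slope
    stderr_c = float(stderr_b) / slope**2 if np.isfinite(stderr_b) else np.nan
    return WaveSpeedFit(
        speed_mps=float(speed),
        stderr_mps=float(stderr_c),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        n_depths=n,
        slope_s_per_m=float(slope),
        intercept_s=float(intercept),
        method=fit,
    )


def young_modulus(speed_mps: float, params: ElasticityParams | None = None) -> float:
    """Shear-wave equation: E = 2 rho (1 + nu) c^2 (Pa for c in m/s).

    With the default rho = 1000 kg/m^3 and nu = 0.49 this is E = 2980 c^2.
    """
    if params is None:
        params = ElasticityParams()
    if speed_mps < 0:
        raise ConfigurationError("wave speed must be non-negative")
    return 2.0 * params.density_kg_m3 * (1.0 + params.poisson_ratio) * speed_mps**2


def _single_map_speed(
    m: SpatioTemporalMap,
    min_quality: float,
    fit: str,
    surface_trim_fraction: float,
    reference_depth_um: float | None,
    window: tuple[float, float] | None,
) -> WaveSpeedFit:
    disp = phase_to_displacement(m) if m.kind == "phase" else m
    depths = disp.depths_um
    z_min = surface_trim_fraction * depths[-1]
    keep_depths = depths >= z_min
    ref = reference_depth_um
    if ref is None:
        ref = float(depths[keep_depths][0])
    profile = estimate_delays(disp, reference_depth_um=ref, window=window)
    return fit_wave_speed(profile.subset(keep_depths), min_quality=min_quality, fit=fit)


def analyze_oce_measurement(
    maps: Sequence[SpatioTemporalMap],
    params: ElasticityParams | None = None,
    *,
    min_quality: float = 0.5,
    fit: Literal["ols", "theil_sen"] = "ols",
    surface_trim_fraction: float = 0.1,
    reference_depth_um: float | None = None,
    window: tuple[float, float] | None = None,
) -> ElasticityResult:
    """Run the full inversion on a (typically triplicate) set of maps.

    The shallowest ``surface_trim_fraction`` of depths is excluded from the
    slope fit (surface artifacts).  Replicate speeds are aggregated as
    mean ± SD; the modulus is computed from the mean speed.  Failed
    replicates are logged as warnings; if every replicate fails a
    :class:`MeasurementFailureError` carries the per-replicate reasons.
    """
    if len(maps) == 0:
        raise ConfigurationError("need at least one map")
    if params is None:
        params = ElasticityParams()

    fits: list[WaveSpeedFit] = []
    reasons: list[str] = []
    for i, m in enumerate(maps):
        try:
            fits.append(
                _single_map_speed(m, min_quality, fit, surface_trim_fraction, reference_depth_um, window)
            )
        except SpheromechError as exc:
            reasons.append(f"replicate {i}: {exc}")
    if not fits:
        raise MeasurementFailureError(reasons)
    for r in reasons:
        warnings.warn(f"OCE replicate failed ({r})", stacklevel=2)

    speeds = np.array([f.speed_mps for f in fits])
    mean_speed = float(speeds.mean())
    if len(speeds) >= 2:
        sd = float(speeds.std(ddof=1))
        notes = f"{len(speeds)} replicates; stderr is SD across replicates"
    else:
        sd = fits[0].stderr_mps
        notes = "single replicate; stderr is the slope-fit delta-method stderr"
    if reasons:
        notes += f"; {len(reasons)} replicate(s) failed"
    return ElasticityResult(
        wave_speed_mps=mean_speed,
        speed_stderr_mps=sd,
        young_modulus_pa=young_modulus(mean_speed, params),
        r_squared=float(np.mean([f.r_squared for f in fits])),
        n_depths_used=int(round(np.mean([f.n_depths for f in fits]))),
        replicate_speeds_mps=[float(s) for s in speeds],
        method_notes=notes,
    )
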