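"""Synthetic instrument stand-ins with known ground truth.

Every input the pipeline consumes can be generated here with its ground
truth recorded in metadata, so each downstream stage is verifiable by
parameter recovery:

* OCE phase movies — a Gaussian displacement pulse sweeping through depth at
  a known speed, converted to wrapped optical phase with additive phase
  noise calibrated to the instrument's displacement stability (2.6 nm).
* Two-order VIPA spectra — Stokes/anti-Stokes Lorentzian pairs placed with
  the intra-order separation convention ``d_px = (FSR - 2*Omega)/dispersion``
  shared with :mod:`spheromech.brillouin`.
* Disk-like spheroid images of known diameter.
* Longitudinal study tables with configurable multiplicative day effects and
  lognormal replicate noise.

The default study effect factors are synthetic choices that mimic the
qualitative treated-vs-control ordering of the biological system (treated
LN229 declines most, HA stays nearly flat, co-culture is intermediate);
they are not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .brillouin import BrillouinSpectrum, theoretical_shift
from .errors import ConfigurationError, SimulationError, WrapError
from .imaging import SpheroidImage
from .oce import SpatioTemporalMap
from .study import CONDITIONS, DAYS, GROUPS, validate_study_table

__all__ = [
    "OCESimConfig",
    "BrillouinSimConfig",
    "StudyEffectSpec",
    "CALIBRATION_MATERIALS",
    "displacement_to_phase_std",
    "make_oce_phase_map",
    "make_brillouin_spectrum",
    "make_calibration_set",
    "default_calibration_shifts",
    "make_spheroid_image",
    "make_study_dataset",
    "default_study_spec",
]

# Tabulated (refractive index, acoustic velocity m/s) for the reference
# liquids used to calibrate the spectrometer; shifts follow from 2nv/lambda.
CALIBRATION_MATERIALS: dict[str, tuple[float, float]] = {
    "water": (1.330, 1482.0),
    "acetone": (1.359, 1174.0),
    "methanol": (1.328, 1103.0),
}


def displacement_to_phase_std(displacement_nm: float, refractive_index: float, wavelength_nm: float) -> float:
    """Phase std equivalent to a displacement noise floor: 4 pi n u / lambda."""
    return 4.0 * np.pi * refractive_index * displacement_nm / wavelength_nm


def _wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    w = np.mod(phi + np.pi, 2.0 * np.pi) - np.pi
    w[w == -np.pi] = np.pi
    return w


@dataclass
class OCESimConfig:
    """Forward model for one nanobomb-activation depth-time phase map.

    The displacement pulse at depth z is a Gaussian in time centered at
    ``pulse_center_time_s + z / true_speed_mps``; amplitude is constant with
    depth unless ``attenuation_length_um`` is set (exponential decay).
    Phase noise defaults to the equivalent of 2.6 nm displacement noise, the
    swept-source system's stated displacement stability at 1310 nm.
    """

    true_speed_mps: float = 2.0
    depth_extent_um: float = 400.0
    n_depth: int = 64
    frame_interval_s: float = 1e-5
    n_frames: int = 256
    pulse_center_time_s: float = 5e-4
    pulse_width_s: float = 5e-5
    displacement_amplitude_nm: float = 50.0
    refractive_index: float = 1.38  # soft-tissue convention; free parameter
    center_wavelength_nm: float = 1310.0
    phase_noise_std_rad: float | None = None  # default: 2.6 nm equivalent
    displacement_noise_floor_nm: float = 2.6
    attenuation_length_um: float | None = None
    allow_wrapping: bool = False
    wrap_safety_rad: float = np.pi
    seed: int = 0

    def __post_init__(self):
        if self.true_speed_mps <= 0:
            raise ConfigurationError("true_speed_mps must be positive")
        if self.n_depth < 8 or self.n_frames < 8:
            raise ConfigurationError("need at least 8 depth and 8 time samples")
        if self.depth_extent_um <= 0 or self.frame_interval_s <= 0 or self.pulse_width_s <= 0:
            raise ConfigurationError("extents and intervals must be positive")
        if self.displacement_amplitude_nm < 0:
            raise ConfigurationError("displacement amplitude must be >= 0")
        if self.phase_noise_std_rad is None:
            self.phase_noise_std_rad = displacement_to_phase_std(
                self.displacement_noise_floor_nm, self.refractive_index, self.center_wavelength_nm
            )
        if self.phase_noise_std_rad < 0:
            raise ConfigurationError("phase_noise_std_rad must be >= 0")
        t_total = self.n_frames * self.frame_interval_s
        t_last = self.pulse_center_time_s + self.depth_extent_um * 1e-6 / self.true_speed_mps
        if self.pulse_center_time_s - 3 * self.pulse_width_s < 0 or t_last + 3 * self.pulse_width_s > t_total:
            raise ConfigurationError(
                "pulse does not fit in the time window: arrival at the deepest sample "
                f"(+3 sigma) is {t_last + 3 * self.pulse_width_s:.2e} s vs window {t_total:.2e} s"
            )

    @property
    def axial_pitch_um(self) -> float:
        return self.depth_extent_um / self.n_depth


def make_oce_phase_map(config: OCESimConfig) -> SpatioTemporalMap:
    """Simulate a wrapped, noisy phase depth-time map with known wave speed."""
    z_um = np.arange(config.n_depth) * config.axial_pitch_um
    t = np.arange(config.n_frames) * config.frame_interval_s
    arrival = config.pulse_center_time_s + z_um[:, None] * 1e-6 / config.true_speed_mps
    amp = np.full_like(z_um, config.displacement_amplitude_nm)
    if config.attenuation_length_um is not None:
        amp = amp * np.exp(-z_um / config.attenuation_length_um)
    u_nm = amp[:, None] * np.exp(-((t[None, :] - arrival) ** 2) / (2.0 * config.pulse_width_s**2))
    phi_clean = 4.0 * np.pi * config.refractive_index * u_nm / config.center_wavelength_nm

    peak = float(np.abs(phi_clean).max())
    if not config.allow_wrapping and peak > config.wrap_safety_rad:
        raise WrapError(
            f"peak phase {peak:.3f} rad exceeds the wrap-safety bound "
            f"{config.wrap_safety_rad:.3f} rad; lower the displacement amplitude or allow wrapping"
        )
    rng = np.random.default_rng(config.seed)
    phi = phi_clean + rng.normal(0.0, config.phase_noise_std_rad, size=phi_clean.shape)
    phi = _wrap_phase(phi)
    return SpatioTemporalMap(
        values=phi,
        kind="phase",
        axial_pitch_um=config.axial_pitch_um,
        frame_interval_s=config.frame_interval_s,
        center_wavelength_nm=config.center_wavelength_nm,
        refractive_index=config.refractive_index,
        metadata={"ground_truth": {"true_speed_mps": config.true_speed_mps}, "config": asdict(config)},
    )


@dataclass
class BrillouinSimConfig:
    """Forward model for one two-order VIPA spectrum.

    Each order contributes an anti-Stokes and a Stokes Lorentzian separated
    by ``(FSR - 2*Omega)/dispersion`` pixels, symmetric about the order
    center; the two order centers are one FSR apart and centered on the
    pixel axis unless ``order_anchor_px`` is given.
    """

    true_shift_ghz: float = 5.0
    linewidth_ghz: float = 0.8
    free_spectral_range_ghz: float = 30.0
    dispersion_ghz_per_px: float = 0.1
    n_pixels: int = 700
    amplitude: float = 500.0
    baseline: float = 50.0
    noise_model: str = "none"  # none | gaussian | poisson
    gaussian_noise_std: float = 5.0
    order_anchor_px: float | None = None
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.true_shift_ghz < self.free_spectral_range_ghz / 2.0):
            raise ConfigurationError("true_shift_ghz must lie in (0, FSR/2)")
        if self.linewidth_ghz <= 0 or self.dispersion_ghz_per_px <= 0:
            raise ConfigurationError("linewidth and dispersion must be positive")
        if self.n_pixels < 64:
            raise ConfigurationError("need at least 64 pixels")
        if self.amplitude < 0 or self.baseline < 0:
            raise ConfigurationError("amplitude and baseline must be >= 0")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ConfigurationError(f"unknown noise model {self.noise_model!r}")

    def peak_positions_px(self) -> np.ndarray:
        """The four peak centers (two per order), sorted ascending."""
        fsr_px = self.free_spectral_range_ghz / self.dispersion_ghz_per_px
        anchor = (
            self.order_anchor_px
            if self.order_anchor_px is not None
            else (self.n_pixels - fsr_px) / 2.0
        )
        half_sep = (self.free_spectral_range_ghz - 2.0 * self.true_shift_ghz) / (
            2.0 * self.dispersion_ghz_per_px
        )
        centers = np.array([anchor, anchor + fsr_px])
        return np.sort(np.concatenate([centers - half_sep, centers + half_sep]))


def make_brillouin_spectrum(config: BrillouinSimConfig) -> BrillouinSpectrum:
    """Simulate one spectrum; ground-truth shift recorded in metadata."""
    positions = config.peak_positions_px()
    for order, (lo, hi) in enumerate([positions[:2], positions[2:]], start=1):
        if lo < 0 or hi > config.n_pixels - 1:
            raise SimulationError(
                f"order {order} peaks at px ({lo:.1f}, {hi:.1f}) fall outside [0, {config.n_pixels - 1}]"
            )
    x = np.arange(config.n_pixels, dtype=float)
    hwhm = config.linewidth_ghz / config.dispersion_ghz_per_px / 2.0
    y = np.full(config.n_pixels, config.baseline, dtype=float)
    for c in positions:
        y += config.amplitude * hwhm**2 / ((x - c) ** 2 + hwhm**2)

    rng = np.random.default_rng(config.seed)
    if config.noise_model == "gaussian":
        y = y + rng.normal(0.0, config.gaussian_noise_std, size=y.shape)
    elif config.noise_model == "poisson":
        y = rng.poisson(np.clip(y, 0, None)).astype(float)
    y = np.clip(y, 0.0, None)
    return BrillouinSpectrum(
        intensity=y,
        label="synthetic",
        metadata={
            "ground_truth": {
                "true_shift_ghz": config.true_shift_ghz,
                "dispersion_ghz_per_px": config.dispersion_ghz_per_px,
                "free_spectral_range_ghz": config.free_spectral_range_ghz,
                "peak_positions_px": positions.tolist(),
            },
            "config": asdict(config),
        },
    )


def default_calibration_shifts(wavelength_nm: float = 660.0) -> list[tuple[str, float]]:
    """Known shifts of the standard reference liquids at the given wavelength."""
    return [
        (name, theoretical_shift(n, v, wavelength_nm))
        for name, (n, v) in CALIBRATION_MATERIALS.items()
    ]


def make_calibration_set(
    materials: list[tuple[str, float]], config: BrillouinSimConfig
) -> list[BrillouinSpectrum]:
    """One spectrum per reference material, sharing dispersion/FSR with ``config``.

    Each spectrum is tagged with its material name and known shift.  Seeds
    are derived from ``config.seed`` so the set is reproducible as a whole.
    """
    if len(materials) < 2:
        raise ConfigurationError("need at least 2 calibration materials")
    shifts = np.array([s for _, s in materials], dtype=float)
    if np.min(np.diff(np.sort(shifts))) < 1e-9:
        raise ConfigurationError("duplicate calibration shifts: calibration would be degenerate")
    out = []
    for i, (name, shift) in enumerate(materials):
        cfg = BrillouinSimConfig(
            **{
                **asdict(config),
                "true_shift_ghz": float(shift),
                "seed": int(config.seed) + i,
            }
        )
        spec = make_brillouin_spectrum(cfg)
        spec.label = name
        spec.metadata["material"] = name
        spec.metadata["known_shift_ghz"] = float(shift)
        out.append(spec)
    return out


def make_spheroid_image(
    diameter_px: float,
    image_size: int = 256,
    foreground: float = 200.0,
    background: float = 50.0,
    noise_std: float = 5.0,
    seed: int = 0,
    pixel_size_um: float = 2.0,
    acquisition_day: int = 0,
    sample_id: str = "synthetic",
) -> SpheroidImage:
    """Centered rasterized disk of the stated diameter plus additive noise."""
    if diameter_px >= image_size:
        raise ConfigurationError("diameter_px must be smaller than image_size")
    if diameter_px <= 0:
        raise ConfigurationError("diameter_px must be positive")
    c = (image_size - 1) / 2.0
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    disk = (yy - c) ** 2 + (xx - c) ** 2 <= (diameter_px / 2.0) ** 2
    img = np.where(disk, foreground, background).astype(float)
    rng = np.random.default_rng(seed)
    if noise_std > 0:
        img = img + rng.normal(0.0, noise_std, size=img.shape)
    return SpheroidImage(
        pixels=img,
        pixel_size_um=pixel_size_um,
        acquisition_day=acquisition_day,
        sample_id=sample_id,
        metadata={
            "ground_truth": {
                "diameter_px": float(diameter_px),
                "area_px": int(disk.sum()),
                "foreground": foreground,
                "background": background,
            }
        },
    )


@dataclass
class StudyEffectSpec:
    """Multiplicative effect structure for the longitudinal study table.

    ``baselines[(group, condition)]`` is the day-0 cell mean;
    ``day_factors[(group, condition)][day]`` multiplies it (day 0 factor must
    be 1, factors in (0, 1]).  Replicate values add lognormal noise with the
    stated coefficient of variation, parameterized so the cell mean is
    exactly baseline x factor.
    """

    baselines: dict = field(default_factory=dict)
    day_factors: dict = field(default_factory=dict)
    cv: float = 0.10
    n_replicates: int = 9  # three independent experiments in triplicate
    seed: int = 0

    def __post_init__(self):
        if self.cv < 0:
            raise ConfigurationError("cv must be >= 0")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        for key in [(g, c) for g in GROUPS for c in CONDITIONS]:
            if key not in self.baselines or key not in self.day_factors:
                raise ConfigurationError(f"missing baseline or day factors for cell {key}")
            if self.baselines[key] <= 0:
                raise ConfigurationError(f"baseline for {key} must be positive")
            factors = self.day_factors[key]
            for day in DAYS:
                f = factors.get(day)
                if f is None or not (0.0 < f <= 1.0):
                    raise ConfigurationError(f"day factor for {key} day {day} must be in (0, 1]")
            if abs(factors[0] - 1.0) > 1e-12:
                raise ConfigurationError(f"day-0 factor for {key} must be 1")


_WAVE_SPEED_DEFAULTS = dict(
    baselines={
        ("LN229", "control"): 2.0, ("LN229", "treated"): 2.0,
        ("HA", "control"): 1.5, ("HA", "treated"): 1.5,
        ("CO", "control"): 1.8, ("CO", "treated"): 1.8,
    },
    day_factors={
        ("LN229", "control"): {0: 1.0, 4: 0.95, 7: 0.90},
        ("LN229", "treated"): {0: 1.0, 4: 0.70, 7: 0.50},
        ("HA", "control"): {0: 1.0, 4: 0.97, 7: 0.95},
        ("HA", "treated"): {0: 1.0, 4: 0.95, 7: 0.93},
        ("CO", "control"): {0: 1.0, 4: 0.95, 7: 0.90},
        ("CO", "treated"): {0: 1.0, 4: 0.85, 7: 0.75},
    },
)

_BRILLOUIN_DEFAULTS = dict(
    baselines={
        ("LN229", "control"): 5.20, ("LN229", "treated"): 5.20,
        ("HA", "control"): 5.05, ("HA", "treated"): 5.05,
        ("CO", "control"): 5.12, ("CO", "treated"): 5.12,
    },
    day_factors={
        ("LN229", "control"): {0: 1.0, 4: 0.995, 7: 0.990},
        ("LN229", "treated"): {0: 1.0, 4: 0.970, 7: 0.940},
        ("HA", "control"): {0: 1.0, 4: 0.995, 7: 0.990},
        ("HA", "treated"): {0: 1.0, 4: 0.990, 7: 0.985},
        ("CO", "control"): {0: 1.0, 4: 0.995, 7: 0.990},
        ("CO", "treated"): {0: 1.0, 4: 0.980, 7: 0.965},
    },
)


def default_study_spec(
    metric: str = "wave_speed_mps", cv: float | None = None, n_replicates: int = 9, seed: int = 0
) -> StudyEffectSpec:
    """Default effect structure mimicking the qualitative treated-vs-control
    ordering (treated LN229 declines most, HA nearly flat, co-culture
    intermediate).  Synthetic choices, not measured values.

    The default replicate CV is metric-specific: 10% for wave speed, 1% for
    Brillouin shift (shift changes in soft samples are a few percent, so
    replicate scatter at the 0.05 GHz level is the realistic regime).
    """
    if metric == "wave_speed_mps":
        base = _WAVE_SPEED_DEFAULTS
        if cv is None:
            cv = 0.10
    elif metric == "brillouin_shift_ghz":
        base = _BRILLOUIN_DEFAULTS
        if cv is None:
            cv = 0.01
    else:
        raise ConfigurationError(f"no default effect structure for metric {metric!r}")
    return StudyEffectSpec(
        baselines=dict(base["baselines"]),
        day_factors={k: dict(v) for k, v in base["day_factors"].items()},
        cv=cv,
        n_replicates=n_replicates,
        seed=seed,
    )


def make_study_dataset(spec: StudyEffectSpec, metric: str = "wave_speed_mps") -> pd.DataFrame:
    """Long-format study table: one row per (group, condition, day, replicate).

    Values are ``baseline * day_factor * lognormal(cv)`` with the lognormal
    parameterized to unit mean, so cell means equal baseline x factor
    exactly in expectation (and exactly when cv = 0).
    """
    rng = np.random.default_rng(spec.seed)
    sigma = np.sqrt(np.log(1.0 + spec.cv**2))
    rows = []
    for group in GROUPS:
        for condition in CONDITIONS:
            for day in DAYS:
                mean = spec.baselines[(group, condition)] * spec.day_factors[(group, condition)][day]
                if sigma > 0:
                    noise = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=spec.n_replicates)
                else:
                    noise = np.ones(spec.n_replicates)
                for rep in range(1, spec.n_replicates + 1):
                    rows.append(
                        {
                            "group": group,
                            "condition": condition,
                            "day": day,
                            "replicate": rep,
                            "metric": metric,
                            "value": float(mean * noise[rep - 1]),
                        }
                    )
    return validate_study_table(pd.DataFrame(rows))
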