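"""B-scan repeat averaging and spheroid morphometry.

Repeated B-scans are averaged pixelwise to raise SNR (the residual noise of
an N-frame average drops by sqrt(N) for independent noise).  Spheroid size
is tracked from 2-D brightfield-style images by global Otsu thresholding,
hole filling and largest-component selection; sizes are reported in physical
units via the pixel size, and longitudinal change is expressed relative to
day 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure

from .errors import ConfigurationError, MissingBaselineError, SegmentationError

__all__ = [
    "SpheroidImage",
    "SpheroidMorphology",
    "AveragingReport",
    "average_repeats",
    "segment_spheroid",
    "track_size",
]


@dataclass
class SpheroidImage:
    """2-D grayscale image of one spheroid with physical pixel size."""

    pixels: np.ndarray
    pixel_size_um: float
    acquisition_day: int = 0
    sample_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ConfigurationError("pixels must be 2-D")
        if not np.all(np.isfinite(self.pixels)):
            raise ConfigurationError("pixel intensities must be finite")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be positive")


@dataclass
class SpheroidMorphology:
    area_um2: float
    equivalent_diameter_um: float
    centroid_px: tuple
    circularity: float
    mask: np.ndarray
    pixel_size_um: float
    sample_id: str = ""
    acquisition_day: int = 0


@dataclass
class AveragingReport:
    n_frames: int
    noise_std_frame: float
    noise_std_mean_est: float
    snr_gain: float
    degenerate: bool  # identical frames: gain undefined


def average_repeats(frames: Sequence[np.ndarray]) -> tuple[np.ndarray, AveragingReport]:
    """Pixelwise mean of repeated frames with an SNR-gain estimate.

    The per-frame noise std is estimated from the residuals about the mean
    (pooled over pixels, unbiased in the frame count); under independent
    noise the average's noise std is sigma/sqrt(N), an SNR gain of sqrt(N).
    Identical frames leave the noise estimate at zero and the gain undefined
    (flagged ``degenerate``).
    """
    if len(frames) < 2:
        raise ConfigurationError("need at least 2 frames to average")
    stack = [np.asarray(f, dtype=float) for f in frames]
    shape = stack[0].shape
    if any(f.shape != shape for f in stack):
        raise ConfigurationError("all frames must share the same shape")
    arr = np.stack(stack)
    n = arr.shape[0]
    avg = arr.mean(axis=0)
    resid = arr - avg
    sigma2 = float((resid**2).sum() / ((n - 1) * avg.size))
    sigma = np.sqrt(sigma2)
    degenerate = sigma == 0.0
    gain = float("inf") if degenerate else float(np.sqrt(n))
    return avg, AveragingReport(
        n_frames=n,
        noise_std_frame=sigma,
        noise_std_mean_est=sigma / np.sqrt(n),
        snr_gain=gain,
        degenerate=degenerate,
    )


def segment_spheroid(
    image: SpheroidImage,
    *,
    min_separation_sigma: float = 4.0,
    min_area_px: int = 16,
) -> SpheroidMorphology:
    """Segment the spheroid and report its morphology in physical units.

    Global Otsu (between-class-variance) threshold; the *smaller* intensity
    class is taken as foreground (the spheroid occupies less than half the
    field), holes are filled and the largest 8-connected component kept.
    Contrast is judged by the inter-class mean separation in units of the
    pooled within-class std — an affine-invariant criterion, so segmentation
    is unchanged under a*I + b with a > 0.  Equivalent diameter is defined
    from the mask area, 2*sqrt(area/pi), so the diameter/area identity holds
    exactly for every output.
    """
    px = image.pixels
    if np.ptp(px) == 0:
        raise SegmentationError("segmentation failed: image has no intensity range")
    thr = filters.threshold_otsu(px)
    high = px > thr
    n_hi, n_lo = int(high.sum()), int((~high).sum())
    if n_hi == 0 or n_lo == 0:
        raise SegmentationError("segmentation failed: threshold produced a single class")
    mu_hi, mu_lo = px[high].mean(), px[~high].mean()
    var_within = (px[high].var() * n_hi + px[~high].var() * n_lo) / (n_hi + n_lo)
    sw = np.sqrt(var_within)
    # sw == 0 with two distinct classes means perfectly separated intensities
    if sw > 0 and (mu_hi - mu_lo) < min_separation_sigma * sw:
        raise SegmentationError(
            "segmentation failed: inter-class contrast below floor "
            f"({(mu_hi - mu_lo) / sw:.2f} sigma < {min_separation_sigma})"
        )

    fg = high if n_hi <= n_lo else ~high
    fg = ndimage.binary_fill_holes(fg)
    labels = measure.label(fg, connectivity=2)
    if labels.max() == 0:
        raise SegmentationError("segmentation failed: no foreground component")
    props = measure.regionprops(labels)
    largest = max(props, key=lambda r: r.area)
    if largest.area < min_area_px:
        raise SegmentationError(f"segmentation failed: largest component {largest.area} px too small")
    mask = labels == largest.label

    area_px = float(largest.area)
    eq_d_px = 2.0 * np.sqrt(area_px / np.pi)
    perim = float(largest.perimeter_crofton)
    circularity = 1.0 if perim == 0 else min(4.0 * np.pi * area_px / perim**2, 1.0)
    ps = image.pixel_size_um
    return SpheroidMorphology(
        area_um2=area_px * ps**2,
        equivalent_diameter_um=eq_d_px * ps,
        centroid_px=tuple(largest.centroid),
        circularity=float(circularity),
        mask=mask,
        pixel_size_um=ps,
        sample_id=image.sample_id,
        acquisition_day=image.acquisition_day,
    )


def track_size(morphologies_by_day: Mapping[int, "SpheroidMorphology | float"]) -> pd.DataFrame:
    """Per-sample size trajectory relative to day 0.

    Accepts a mapping day -> morphology (or bare equivalent diameter in um).
    Returns a table with columns day, eq_diameter_um, relative_size where
    relative_size = diameter(day) / diameter(day 0).
    """
    if 0 not in morphologies_by_day:
        raise MissingBaselineError("day-0 entry required for relative size tracking")

    def _diam(v):
        return float(getattr(v, "equivalent_diameter_um", v))

    days = sorted(morphologies_by_day)
    diam0 = _diam(morphologies_by_day[0])
    if diam0 <= 0:
        raise ConfigurationError("day-0 diameter must be positive")
    rows = [
        {"day": d, "eq_diameter_um": _diam(morphologies_by_day[d]),
         "relative_size": _diam(morphologies_by_day[d]) / diam0}
        for d in days
    ]
    return pd.DataFrame(rows)
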