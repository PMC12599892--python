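"""Exception hierarchy shared across the pipeline stages."""


class SpheromechError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SpheromechError, ValueError):
    """Invalid configuration or missing required metadata."""


class SimulationError(SpheromechError):
    """A forward model cannot produce a physically decodable output."""


class WrapError(SimulationError):
    """Simulated phase would wrap beyond the safety bound."""


class InsufficientDataError(SpheromechError):
    """Too few usable observations for the requested fit."""


class NoPropagatingWaveError(SpheromechError):
    """Delay-vs-depth slope is non-positive: no wave travels into the sample."""


class MeasurementFailureError(SpheromechError):
    """Every replicate of a measurement failed; carries per-replicate reasons."""

    def __init__(self, reasons):
        self.reasons = list(reasons)
        super().__init__("all replicates failed: " + "; ".join(map(str, self.reasons)))


class PeakDetectionError(SpheromechError):
    """Fewer detectable spectral peaks than requested."""

    def __init__(self, message, found=()):
        self.found = list(found)
        super().__init__(message)


class FitConvergenceError(SpheromechError):
    """Nonlinear least squares failed to converge."""


class CalibrationError(SpheromechError, ValueError):
    """Degenerate or insufficient calibration inputs."""


class OrderAmbiguityError(SpheromechError):
    """Decoded Brillouin shift falls outside (0, FSR/2)."""


class MapError(SpheromechError):
    """A shift map or ROI summary cannot be computed."""


class SegmentationError(SpheromechError):
    """Spheroid segmentation failed (no contrast or no foreground)."""


class MissingBaselineError(SpheromechError, KeyError):
    """Size tracking requires a day-0 entry."""
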