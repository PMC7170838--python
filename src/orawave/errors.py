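"""Exception hierarchy shared across the pipeline stages."""


class OrawaveError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(OrawaveError, ValueError):
    """Invalid simulation or run configuration."""


class ParseError(OrawaveError, ValueError):
    """Malformed waveform/covariate table; message names the offending row."""


class PeakDetectionError(OrawaveError, RuntimeError):
    """Fewer than two qualifying applanation peaks in a trace."""


class FeatureError(OrawaveError, RuntimeError):
    """Degenerate trace geometry; message names the feature field."""


class AssemblyError(OrawaveError, ValueError):
    """Design-matrix assembly failed (missing covariates/response)."""


class DegenerateFitError(OrawaveError, RuntimeError):
    """Zero-residual or rank-deficient least-squares problem."""


class SaturationError(OrawaveError, RuntimeError):
    """Too few observations for the requested number of parameters."""


class TrainingError(OrawaveError, RuntimeError):
    """Non-finite loss during VAE optimisation; message reports the epoch."""


class PipelineError(OrawaveError, RuntimeError):
    """A pipeline stage failed; message names the stage."""
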