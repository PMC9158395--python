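"""Exception hierarchy for the pipeline's failure classes."""


class HippoclustError(Exception):
    """Base class for all package errors."""


class ConfigError(HippoclustError):
    """Invalid configuration (e.g. non-PSD correlation matrix, bad sizes)."""


class ShapeError(HippoclustError):
    """Array/grid dimension mismatch (3D vs 4D, mask vs volume lattice)."""


class FormatError(HippoclustError):
    """File content not in the expected format (e.g. non-binary mask)."""


class DegenerateROIError(HippoclustError):
    """ROI empty or entirely zero-variance; named ROI where known."""


class SimulationError(HippoclustError):
    """Synthetic generation impossible (e.g. subject without latent cluster)."""


class SelectionError(HippoclustError):
    """Cluster-number selection impossible (all validity indices abstained)."""


class UndefinedTestError(HippoclustError):
    """Statistical test undefined on the data (e.g. all observations tied)."""


class JoinError(HippoclustError):
    """Subject tables/labels could not be aligned."""
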