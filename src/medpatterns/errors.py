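"""Exception hierarchy used across the package."""


class MedpatternsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MedpatternsError, ValueError):
    """Invalid input data or model parameters; the message names the offending field."""


class AlignmentError(MedpatternsError, ValueError):
    """Two-phase matrices whose subjects cannot be aligned."""


class DegenerateClassError(MedpatternsError, RuntimeError):
    """A latent class lost essentially all posterior mass during EM."""


class FitError(MedpatternsError, RuntimeError):
    """Model fitting failed (all starts degenerate, broken monotonicity, ...)."""


class ConfigurationError(MedpatternsError, ValueError):
    """Invalid run or labeling configuration."""
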