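"""Exception hierarchy shared across the pipeline.

The CLI maps these onto distinct exit codes (config = 2, I/O = 3,
convergence = 4), so stage failures are distinguishable in shell scripts.
"""


class ChromofoldError(Exception):
    """Base class for all package-specific errors."""


class PotentialDomainError(ChromofoldError, ValueError):
    """A pair separation fell outside the domain of a potential
    (e.g. a FENE bond at or beyond its maximum extension R0)."""


class ConfigError(ChromofoldError, ValueError):
    """Invalid parameter combination or malformed configuration."""


class InputFormatError(ChromofoldError, ValueError):
    """A contact-matrix, BED or image file failed validation; the message
    carries the offending line number where applicable."""


class ConvergenceError(ChromofoldError, RuntimeError):
    """An iterative stage (Monte Carlo restraint satisfaction, Langevin
    integration) failed to reach its contract."""
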