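"""Exception hierarchy.

``OptopaceError`` is the common base so callers (and the CLI) can catch
everything from this package in one clause.  ``ValidationError`` covers bad
parameters and bad inputs discovered before any computation; it maps to CLI
exit code 2.  Everything else maps to exit code 1.
"""


class OptopaceError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(OptopaceError, ValueError):
    """Invalid parameters, specs, or configuration."""


class FormatError(OptopaceError):
    """A file did not conform to the expected on-disk format."""


class DegenerateSignalError(OptopaceError):
    """A signal is flat or otherwise carries no usable structure."""


class TwoWallsNotFoundError(OptopaceError):
    """Fewer than two candidate sidewall peaks in an intensity profile."""


class PipelineError(OptopaceError):
    """A multi-stage computation failed; message names the stage."""
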