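"""Exception hierarchy and CLI exit codes.

Every error raised by the package derives from :class:`SiraError`, so callers
can catch one type. The CLI maps each leaf class to a distinct exit code.
"""

from __future__ import annotations


class SiraError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(SiraError):
    """Malformed input: bad DNA alphabet, bad site spec, bad file content."""

    exit_code = 2


class DesignError(SiraError):
    """A requested design is internally inconsistent (e.g. symmetric vector
    channels, payload shorter than the annealing length, target segment not
    junction-bounded)."""

    exit_code = 3


class CapacityError(DesignError):
    """More fragments requested than the six asymmetric overlap channels of a
    single integrase can address."""

    exit_code = 4


class IncompatibleSitesError(SiraError):
    """A crossover was requested between sites that cannot recombine under
    the given enzyme condition."""

    exit_code = 5


class ClosureLimitError(SiraError):
    """Reaction-network exploration hit a configured limit.

    Carries the partial result so callers can inspect how far the search got.
    """

    exit_code = 6

    def __init__(self, message: str, partial=None):
        super().__init__(message)
        self.partial = partial
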