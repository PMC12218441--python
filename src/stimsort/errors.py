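"""Exception hierarchy shared across stimsort modules."""


class StimsortError(Exception):
    """Base class for all stimsort errors."""


class SpectrumParseError(StimsortError):
    """Raised when a spectral text file cannot be parsed; names the line."""


class ValidationError(StimsortError, ValueError):
    """A domain object violates one of its invariants."""


class WindowRangeError(StimsortError, ValueError):
    """An integration window falls outside the spectrum's wavenumber span."""


class InsufficientDataError(StimsortError, ValueError):
    """Too few observations for the requested statistic."""


class InvalidReferenceError(StimsortError, ValueError):
    """The reference (fluid) spectrum has a non-positive integral."""


class InvalidSpectrumError(StimsortError, ValueError):
    """A spectrum is unusable for the requested index (e.g. zero denominator)."""


class DomainError(StimsortError, ValueError):
    """A scalar input lies outside the mathematical domain of an operation."""


class EmptySampleError(StimsortError, ValueError):
    """A sample column has zero total count; names the sample."""


class ContrastError(StimsortError, ValueError):
    """A contrast selector matched no samples."""


class DegenerateDesignError(StimsortError, ValueError):
    """The permutation design admits fewer than two distinct relabelings."""


class SpecError(StimsortError, ValueError):
    """A synthetic-data specification is infeasible."""
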