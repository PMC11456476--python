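"""Exception hierarchy for the MR screening pipeline."""


class MRScreenError(Exception):
    """Base class for all package errors."""


class ConfigError(MRScreenError, ValueError):
    """An invalid configuration field value; the message names the field."""


class FormatError(MRScreenError, ValueError):
    """Malformed input file (missing columns, bad coordinates, empty file)."""


class DataError(MRScreenError, ValueError):
    """Inconsistent data content, e.g. duplicate SNP identifiers."""


class DomainError(MRScreenError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class InsufficientInstrumentsError(MRScreenError, ValueError):
    """Too few instruments for the requested estimator or diagnostic."""


class EstimationError(MRScreenError, RuntimeError):
    """Numerical estimation failed; carries optimizer diagnostics."""
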