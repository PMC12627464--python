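"""Exception hierarchy for validation, coverage and numerical failures."""


class EaaFingerError(Exception):
    """Base class for all package errors."""


class SchemaError(EaaFingerError):
    """A required column or field is missing or unresolvable."""


class ParseError(EaaFingerError):
    """A value could not be parsed (carries row context where known)."""


class ValidationError(EaaFingerError):
    """A table or profile violates an invariant (duplicates, non-finite values)."""


class CoverageError(EaaFingerError):
    """An amino-acid panel, organ or group required downstream is incomplete."""


class ConfigurationError(EaaFingerError):
    """A simulation or run configuration is inconsistent."""


class SampleSizeError(EaaFingerError):
    """Too few observations for the requested statistic."""


class IdentifiabilityError(EaaFingerError):
    """The mixing endmembers are too close for the fraction to be estimable."""


class NumericalError(EaaFingerError):
    """A matrix was singular or a quantity non-finite after fallbacks."""
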