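"""Exception and warning types shared across the package."""


class FibromechError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(FibromechError):
    """A file or table does not conform to the declared schema."""


class DegenerateBaselineError(FibromechError):
    """Baseline denominator F0 - B0 is non-positive; dF/F0 is undefined."""


class UndefinedDecayError(FibromechError):
    """Decay time requested for a trace without a positive peak."""


class ContactPointError(FibromechError):
    """No contact point could be located on a force curve."""


class NonIdentifiableWarning(UserWarning):
    """Fit parameters are not identifiable from the supplied data."""
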