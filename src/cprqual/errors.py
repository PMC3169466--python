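"""Exception hierarchy shared across the package."""


class CprQualError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CprQualError):
    """An input file does not match the declared CSV layout."""


class ValidationError(CprQualError):
    """Data violate a domain invariant (ordering, sign, span)."""


class CohortError(CprQualError):
    """A cohort-level constraint failed (duplicate ids, empty manifest)."""


class ZeroVarianceError(CprQualError):
    """A statistic is undefined because the data carry no variance."""
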