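"""Exception hierarchy for actimr."""


class ActimrError(Exception):
    """Base class for all actimr errors."""


class ConfigurationError(ActimrError):
    """Invalid configuration: missing columns, unknown methods, bad options."""


class EmptyInputError(ActimrError):
    """An operation received no usable records."""


class HarmonisationError(ActimrError):
    """Allele pair at a shared rsid cannot be reconciled."""


class UnknownInstrumentError(ActimrError, KeyError):
    """Requested built-in instrument does not exist."""


class DomainError(ActimrError, ValueError):
    """Numeric argument outside its mathematical domain."""


class DegenerateParameterError(DomainError):
    """Parameter combination makes the requested quantity undefined."""


class InsufficientVariantsError(ActimrError):
    """Too few variants for the requested estimator."""


class NoSolutionError(ActimrError):
    """Root search failed to bracket a solution."""


class CollinearityError(ActimrError):
    """Exposure effect matrix is rank deficient."""
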