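"""Exception types shared across the package."""


class NcflowError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NcflowError, ValueError):
    """An input object violates a structural invariant."""


class RccFormatError(NcflowError, ValueError):
    """An RCC lane file does not follow the sectioned-CSV dialect."""


class CodesetMismatchError(NcflowError, ValueError):
    """Lanes being assembled do not share an identical probe set."""


class ConfigurationError(NcflowError, ValueError):
    """An operation was requested on data lacking a required probe class,
    or with an inconsistent configuration."""


class NormalizationError(NcflowError, RuntimeError):
    """A sample cannot be normalized (e.g. all control probes at the
    zero floor)."""
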