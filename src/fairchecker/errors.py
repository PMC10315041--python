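"""Package-wide exception types."""


class FairCheckerError(Exception):
    """Base class for all package errors."""


class RetrievalError(FairCheckerError):
    """A document could not be retrieved (unreachable host, timeout)."""


class UnsupportedFeatureError(FairCheckerError):
    """A requested capability is not available in this installation."""


class ContractError(FairCheckerError):
    """An operation was called with arguments violating its contract."""


class FormatError(FairCheckerError):
    """An input file does not parse in its declared serialization."""


class ProfileParseError(FairCheckerError):
    """A profile specification document is malformed."""
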