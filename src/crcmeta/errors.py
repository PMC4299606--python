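"""Exception hierarchy shared across the package."""


class CrcmetaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CrcmetaError):
    """Invalid configuration value; the message names the offending field."""


class DataError(CrcmetaError):
    """Malformed or inconsistent input data."""


class StageError(CrcmetaError):
    """Operation applied to a FeatureMatrix at the wrong processing stage."""


class ContractError(CrcmetaError):
    """A precondition of an operation was violated."""


class FeatureMismatchError(DataError):
    """A matrix is missing features required by a frozen normalization state."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(
            f"matrix is missing {len(self.missing)} retained feature(s): "
            + ", ".join(map(str, self.missing[:10]))
            + (" ..." if len(self.missing) > 10 else "")
        )


class ParseError(DataError):
    """File could not be parsed; carries a line number when available."""


class IntegrityError(CrcmetaError):
    """A serialized document is truncated, corrupt, or of the wrong version."""
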