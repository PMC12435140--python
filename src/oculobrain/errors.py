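"""Exception hierarchy shared across the pipeline."""


class OculobrainError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(OculobrainError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class InputError(OculobrainError, ValueError):
    """Invalid data handed to an operation (wrong shape, empty mask, bad band...)."""


class GenerationError(OculobrainError, RuntimeError):
    """The synthetic generator cannot honour the requested configuration."""


class CollinearityError(InputError):
    """A regression design matrix is rank deficient.

    ``columns`` lists the labels of the offending (linearly dependent) columns.
    """

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear columns: {self.columns}")


class FormatError(OculobrainError, ValueError):
    """A file on disk could not be parsed in the expected format."""
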