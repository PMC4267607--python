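"""Exception hierarchy shared across the package.

CLI exit codes map SchemaError -> 2 and ConfigurationError -> 3; everything
else is an ordinary Python error (argument misuse raises ValueError /
IndexError directly at the call site).
"""


class EthosegError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(EthosegError):
    """A configuration object is internally inconsistent or incomplete."""


class DataError(EthosegError):
    """Input data violate a contract (missing labels, empty tables, ...)."""


class SchemaError(DataError):
    """A file does not match its declared tabular schema."""
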