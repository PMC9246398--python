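"""Exception hierarchy for swsystolic."""


class SwsystolicError(Exception):
    """Base class for all package errors."""


class AlphabetError(SwsystolicError, ValueError):
    """A symbol is not a member of the declared alphabet."""


class InputError(SwsystolicError, ValueError):
    """Malformed or empty input (sequences, FASTA files)."""


class ConstraintError(SwsystolicError, ValueError):
    """A structural constraint is violated (e.g. database shorter than query)."""


class ConfigurationError(SwsystolicError, ValueError):
    """Inconsistent run configuration (PE count, output format, ...)."""


class ContractViolation(SwsystolicError, ValueError):
    """An internal pre/post-condition does not hold for the supplied values."""
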