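"""Exception hierarchy for agep."""


class AgepError(Exception):
    """Base class for all agep errors."""


class InputError(AgepError):
    """Malformed or inconsistent user input (files, matrices, ids)."""


class ConfigurationError(AgepError):
    """A configuration that leaves nothing to compute (e.g. no tissue survives)."""


class InsufficientDataError(AgepError):
    """Fewer observations than the operation requires."""


class DegenerateDistributionError(AgepError):
    """All observations identical: no bandwidth / density exists."""


class DomainError(AgepError):
    """Numeric argument outside its mathematical domain."""
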