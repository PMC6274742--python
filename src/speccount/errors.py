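"""Exception hierarchy for the spectral-counting pipeline.

Every stage raises one of these so the CLI can report which stage failed
and exit non-zero without a traceback.
"""


class SpeccountError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(SpeccountError):
    """Invalid configuration: missing column, unknown condition label, bad parameter."""


class DataError(SpeccountError):
    """Invalid data content: duplicate accession, missing length, universe mismatch."""


class EmptyInputError(SpeccountError):
    """An input yielded zero usable records."""


class DomainError(SpeccountError):
    """A numeric precondition was violated (e.g. count exceeding its total)."""
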