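"""Exception taxonomy shared across the package.

Three failure families are distinguished so callers can react sensibly:
configuration mistakes (wrong column name, unknown classifier kind),
malformed data (bad alphabet, ragged CSV), and lookups of entities that
are simply not in a registry.
"""


class MirdapError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MirdapError):
    """A caller-supplied option or column name is invalid."""


class DataError(MirdapError):
    """An input file or in-memory table violates its format contract."""


class UnknownEntityError(MirdapError, KeyError):
    """A disease or miRNA name is absent from the relevant registry."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return MirdapError.__str__(self)


class TrainingError(MirdapError):
    """A model fit cannot proceed (e.g. empty vocabulary, too few rows)."""


class StructuralError(MirdapError):
    """An internal graph invariant is violated (e.g. unreachable ancestor)."""
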