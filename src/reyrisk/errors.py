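"""Exception hierarchy shared across the package."""


class ReyRiskError(Exception):
    """Base class for all package errors."""


class ConfigError(ReyRiskError):
    """Invalid configuration (bad paths, missing seed, empty element group)."""


class DataError(ReyRiskError):
    """Invalid input data (nonpositive concentration, missing column)."""


class MissingElementError(DataError):
    """A required element is absent from a table; message names the element."""

    def __init__(self, element: str, table: str = "table"):
        self.element = element
        super().__init__(f"element {element!r} is missing from {table}")
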