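"""Exception types shared across the package."""


class ParetomutError(Exception):
    """Base class for all package-specific errors."""


class UnknownGeneError(ParetomutError, KeyError):
    """A gene was referenced that is not part of the bound alteration matrix."""

    def __init__(self, gene: str):
        self.gene = gene
        super().__init__(gene)

    def __str__(self) -> str:  # KeyError would repr() the message
        return f"unknown gene: {self.gene!r}"


class ConfigurationError(ParetomutError, ValueError):
    """Invalid parameter, mode or configuration value."""


class ParseError(ParetomutError, ValueError):
    """A delimited input file violates the expected format."""
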