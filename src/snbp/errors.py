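"""Typed exceptions shared across the toolkit."""


class SnbpError(Exception):
    """Base class for all toolkit errors."""


class ParseError(SnbpError):
    """A record in an input file could not be parsed.

    Carries the path and 1-based line number of the offending line so the
    message pinpoints the problem.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += f"{path}"
        if line is not None:
            prefix += f":{line}"
        if prefix:
            message = f"{prefix}: {message}"
        super().__init__(message)


class TreeParseError(ParseError):
    """Malformed newick; message names the offending token."""


class DuplicateIdError(ParseError):
    """Two records share an identifier that must be unique."""


class ConfigError(SnbpError):
    """Invalid simulation or pipeline configuration."""


class SimulationError(SnbpError):
    """A generator could not produce valid output (e.g. rejection failure)."""


class UnimodalCoverageError(SnbpError):
    """Coverage density has fewer than two local maxima.

    The two-peak threshold cannot be derived automatically; supply a manual
    threshold instead.
    """


class SaturationError(SnbpError):
    """Substitution proportion too high for the distance correction."""


class MissingDataError(SnbpError):
    """A required record (contig, species, node) is absent from its table."""
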