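"""Exception types shared across the package."""


class DomainError(ValueError):
    """An argument is outside the mathematical domain of an operation."""


class ParseError(ValueError):
    """A coordinate or table file could not be parsed.

    Carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class LabelingError(ValueError):
    """A coordinate file parses but lacks the lattice labels this package needs."""


class InsufficientDataError(ValueError):
    """Too few points to perform the requested geometric measurement."""


class DegenerateGeometryError(ValueError):
    """Input geometry collapses (coincident points, zero-length edges)."""


class FlatRibbonError(ValueError):
    """Twist below tolerance: no finite pitch exists."""


class NoPeriodicityError(ValueError):
    """A height profile carries no detectable periodic modulation."""


class InsufficientPeriodsError(ValueError):
    """Fewer than two profile periods are visible in the map."""


class DetectionError(ValueError):
    """No object footprint detectable above the image background."""


class ConfigError(ValueError):
    """Invalid pipeline configuration; lists the offending keys."""

    def __init__(self, problems: dict[str, str]):
        self.problems = dict(problems)
        detail = "; ".join(f"{k}: {v}" for k, v in self.problems.items())
        super().__init__(f"invalid configuration: {detail}")
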