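"""Exception hierarchy shared across the pipeline stages."""


class McidNormError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(McidNormError):
    """An input table is missing a required column or has an unparseable cell."""


class ValidationError(McidNormError):
    """A value violates a domain invariant (e.g. a non-positive MCID)."""


class UnknownPromError(McidNormError, KeyError):
    """A PROM name could not be resolved against the registry."""

    def __init__(self, name: str, known: tuple[str, ...] = ()):
        self.name = name
        self.known = known
        msg = f"unknown PROM {name!r}"
        if known:
            msg += f"; known instruments: {', '.join(known)}"
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError would repr() the message
        return self.args[0]


class NonNormalizableError(McidNormError):
    """The instrument has no published MCID, so MCID-unit conversion is undefined."""


class ImputationError(McidNormError):
    """No eligible donor SD exists for a record with neither SD nor range."""


class RankingError(McidNormError):
    """A frequency ranking cannot be built or does not cover a requested PROM."""


class PrioritizationError(McidNormError):
    """A study cannot be collapsed to a single instrument (e.g. disjoint arms)."""


class DegenerateEffectError(McidNormError):
    """An effect size has zero sampling variance and cannot be weighted."""


class ConvergenceError(McidNormError):
    """Iterative estimation failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_value: float):
        super().__init__(message)
        self.last_value = last_value


class ConfigurationError(McidNormError):
    """A run or simulation configuration is internally inconsistent."""
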