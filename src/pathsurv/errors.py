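"""Exception hierarchy shared across the package."""


class PathsurvError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PathsurvError):
    """A file or in-memory structure violates its documented contract."""


class FormatError(ValidationError):
    """A file could not be parsed in its declared dialect."""


class CycleError(ValidationError):
    """The pathway hierarchy contains a directed cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(f"hierarchy contains a cycle: {' -> '.join(map(str, self.cycle))}")


class PathwayExcludedError(PathsurvError):
    """A pathway cannot be scored (e.g. too few measured genes)."""

    def __init__(self, pathway_id, reason):
        self.pathway_id = pathway_id
        self.reason = reason
        super().__init__(f"pathway {pathway_id!r} excluded: {reason}")


class NonIdentifiableError(PathsurvError):
    """A regression design is degenerate (constant or collinear covariates)."""


class UndefinedSignalError(PathsurvError):
    """A statistic is undefined on the given data (e.g. no comparable pairs)."""


class ConfigError(PathsurvError):
    """A run configuration is invalid."""
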