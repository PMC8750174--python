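"""Exception hierarchy shared across the pipeline stages."""


class OxscreenError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(OxscreenError, ValueError):
    """A parameter is outside its legal range or vocabulary."""


class InsufficientDataError(OxscreenError, ValueError):
    """Fewer observations than the statistic requires (e.g. <2 replicates)."""


class InfiniteEffectError(OxscreenError, ArithmeticError):
    """Zero pooled spread with unequal means: the standardized difference diverges."""


class MissingReferenceError(OxscreenError, KeyError):
    """The reference/control condition is absent or degenerate where required."""


class ParseError(OxscreenError, ValueError):
    """A line or record of an input file could not be interpreted."""


class UndefinedKappaError(OxscreenError, ArithmeticError):
    """Chance agreement equals 1, so the kappa score is undefined."""


class ConfigError(OxscreenError, ValueError):
    """A pipeline configuration failed validation; carries all violations."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class PipelineError(OxscreenError, RuntimeError):
    """A pipeline stage failed; names the failing stage."""

    def __init__(self, stage, cause):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")
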