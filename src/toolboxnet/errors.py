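"""Exception hierarchy shared across the package."""


class ToolboxError(Exception):
    """Base class for all toolboxnet errors."""


class BudgetExceededError(ToolboxError):
    """Tree generation exceeded the configured node budget."""


class SamplingFailureError(ToolboxError):
    """Rejection sampling failed to hit the size window within max attempts."""


class MapFormulaParseError(ToolboxError):
    """A malformed line in a KEGG map-formula stream."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class UnreachableTargetError(ToolboxError):
    """Requested target metabolite lies outside the reachable scope."""


class LeavesExhaustedError(ToolboxError):
    """No unacquired leaves remain in the tree toolbox simulation."""


class ScopeExhaustedError(ToolboxError):
    """No unsynthesizable scope metabolites remain (simulation complete)."""


class GenerationError(ToolboxError):
    """Synthetic universe parameters are infeasible."""


class InsufficientDataError(ToolboxError):
    """Not enough non-empty bins for a power-law fit."""


class ConfigError(ToolboxError):
    """Invalid experiment configuration."""

    def __init__(self, message: str, field: str | None = None):
        self.field = field
        if field is not None:
            message = f"{field}: {message}"
        super().__init__(message)
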