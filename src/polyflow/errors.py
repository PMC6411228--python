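"""Exception hierarchy for the workflow engine."""


class PolyflowError(Exception):
    """Base class for all engine errors."""


class ParseError(PolyflowError):
    """A workflow file could not be parsed.  Carries a 1-based line number."""

    def __init__(self, message: str, lineno: int | None = None):
        self.lineno = lineno
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)


class EvaluationError(PolyflowError):
    """An expression or statement inside a workflow failed to evaluate."""


class InterpolationError(EvaluationError):
    """A template could not be expanded (undefined name, unbalanced delimiters)."""


class TargetError(PolyflowError):
    """A dependency target is missing, untracked, or otherwise unusable."""


class DAGError(PolyflowError):
    """The execution graph could not be built or is inconsistent."""


class CycleError(DAGError):
    """A dependency cycle was detected.  ``path`` lists the offending nodes."""

    def __init__(self, message: str, path=None):
        super().__init__(message)
        self.path = list(path or [])


class ExecutionError(PolyflowError):
    """A step or substep failed during execution."""


class TaskError(PolyflowError):
    """A task could not be submitted, executed, or managed."""


class ConfigError(PolyflowError):
    """A host or engine configuration file is invalid."""
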