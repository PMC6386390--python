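"""Exception types shared across the package."""


class NetsmoothError(Exception):
    """Base class for all package-specific errors."""


class ParseError(NetsmoothError):
    """An input file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f" [{path}"
            loc += f", line {line}]" if line is not None else "]"
        super().__init__(message + loc)


class ValidationError(NetsmoothError, ValueError):
    """An in-memory object violates one of its invariants."""


class ConvergenceError(NetsmoothError):
    """Iterative propagation hit max_iter before the residual fell below tolerance."""

    def __init__(self, message: str, residual: float, n_iter: int):
        self.residual = residual
        self.n_iter = n_iter
        super().__init__(f"{message} (residual={residual:.3e} after {n_iter} iterations)")
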