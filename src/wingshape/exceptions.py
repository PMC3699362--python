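"""Exception hierarchy shared across the package."""


class WingshapeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(WingshapeError, ValueError):
    """A file does not conform to its declared format (TPS, Newick, CSV)."""


class ValidationError(WingshapeError, ValueError):
    """Input data violate a documented invariant (labels, ranges, shapes)."""


class GeometryError(WingshapeError, ValueError):
    """A wing outline or mask is degenerate or self-intersecting."""


class ConvergenceError(WingshapeError, RuntimeError):
    """An iterative procedure failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
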