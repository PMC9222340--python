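"""Exception hierarchy.

All simulator errors derive from :class:`ExtrusimError` so callers can catch
the package's failures with one handler while input-validation errors remain
ordinary ``ValueError`` subclasses.
"""

from __future__ import annotations


class ExtrusimError(Exception):
    """Base class for all package errors."""


class DomainError(ExtrusimError, ValueError):
    """A physical quantity is outside its admissible domain (T <= 0 K, ...)."""


class RangeError(ExtrusimError, ValueError):
    """A lookup outside a tabulated range (extrapolation refused)."""


class GeometryError(ExtrusimError, ValueError):
    """Degenerate or inconsistent machine geometry."""


class ConfigError(ExtrusimError, ValueError):
    """Invalid configuration file or object graph.

    ``problems`` collects every individual failure so users can fix a file in
    one pass.
    """

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class SingularFitError(ExtrusimError, ValueError):
    """Rank-deficient regression design; names the unidentifiable terms."""

    def __init__(self, terms):
        self.terms = list(terms)
        super().__init__(
            "singular fit: unidentifiable coefficient(s): " + ", ".join(self.terms)
        )


class ConvergenceError(ExtrusimError, RuntimeError):
    """Iterative solver failed to converge; carries the last bracket/state."""

    def __init__(self, message, detail=None):
        self.detail = detail or {}
        super().__init__(message)
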