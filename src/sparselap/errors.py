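"""Exception hierarchy.

``InputError`` covers malformed or empty inputs (CLI exit code 2);
``NumericalError`` covers solver failures (CLI exit code 3).
"""


class SparselapError(Exception):
    """Base class for all package errors."""


class InputError(SparselapError, ValueError):
    """Invalid, empty, or inconsistent input."""


class EmptyResultError(InputError):
    """An operation removed every marker or sample."""


class DisconnectedGraphError(SparselapError):
    """The weight graph has more than one connected component."""

    def __init__(self, n_components: int, message: str | None = None):
        self.n_components = n_components
        super().__init__(
            message
            or f"weight graph has {n_components} connected components; "
            "increase epsilon so every individual keeps at least one neighbor"
        )


class NumericalError(SparselapError):
    """A numerical routine failed to converge or produced invalid output."""
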