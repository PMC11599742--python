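"""Exception hierarchy for lipshell.

Every operational failure mode raises a named subclass of
:class:`LipshellError` so callers (and the CLI) can map errors to exit
codes without string matching.
"""


class LipshellError(Exception):
    """Base class for all lipshell errors."""


class InvalidComponentCode(LipshellError):
    """Chemical-component identifier is not a 3-character uppercase alphanumeric code."""


class ElementInferenceRequired(LipshellError):
    """Atom records lack element assignments and no atom name is available to infer from."""


class FormatError(LipshellError):
    """Structure file could not be parsed under the requested format."""


class SelectionError(LipshellError):
    """Atom-selection expression violates the grammar."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


class AssemblyUnavailable(LipshellError):
    """No transforms supplied and none derivable from the deposited assembly instructions."""


class UnderdeterminedSuperposition(LipshellError):
    """Fewer than 3 correspondence points, or degenerate (collinear) geometry."""


class EmptyCorrespondence(LipshellError):
    """Two structures share no residues/atoms eligible for pairing."""


class InsufficientData(LipshellError):
    """Not enough protein residues to estimate membrane boundaries."""


class UnknownChain(LipshellError):
    """A requested protomer chain is absent from the structure."""


class EmptyInput(LipshellError):
    """An operation requiring non-empty atom sets received an empty one."""


class InvalidProtomerCount(LipshellError):
    """Protomer count must be a positive integer."""


class PlacementFailure(LipshellError):
    """Synthetic lipid placement could not satisfy the requested geometry after bounded retries."""
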