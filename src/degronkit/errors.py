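"""Exception hierarchy shared across the toolkit.

``DegronkitError`` is the base for every error the library raises on bad
data or bad requests, so callers (and the CLI) can distinguish data problems
from programming errors.
"""


class DegronkitError(Exception):
    """Base class for all toolkit errors."""


class StructureParseError(DegronkitError):
    """A coordinate file could not be parsed, or parsed to an empty polymer."""


class SelectionError(DegronkitError):
    """A residue/chain selection referenced something that does not exist."""


class ContactError(DegronkitError):
    """Invalid input to contact-map computation or comparison."""


class SuperpositionError(DegronkitError):
    """Too few / mismatched atom pairs for a rigid-body fit."""


class SequenceError(DegronkitError):
    """Invalid sequence, mutation spec, or FASTA content."""


class AlignmentError(DegronkitError):
    """Invalid alignment request (unknown matrix, position out of range...)."""


class ModelLayoutError(DegronkitError):
    """A predicted model does not match the expected segment layout."""


class FixtureError(DegronkitError):
    """A synthetic-fixture specification is invalid or geometrically infeasible."""
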