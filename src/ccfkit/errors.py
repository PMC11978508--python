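"""Exception hierarchy.

Every error raised by ccfkit derives from :class:`CcfkitError` so callers
(and the CLI) can distinguish validation problems (exit code 2) from bugs.
"""


class CcfkitError(Exception):
    """Base class for all ccfkit errors."""


class InvalidPlacementError(CcfkitError, ValueError):
    """A cuboid placement has non-positive dimensions or non-finite angles."""


class OpenMeshError(CcfkitError, ValueError):
    """An operation requiring a watertight mesh received an open one."""


class MethodMismatchError(CcfkitError, ValueError):
    """The exact box-overlap method was requested for non-box meshes."""


class SchemaError(CcfkitError, KeyError):
    """A JSON document is missing a required key."""

    def __init__(self, key: str, context: str = ""):
        self.key = key
        msg = f"missing required key {key!r}"
        if context:
            msg += f" in {context}"
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


class RecordValidationError(CcfkitError, ValueError):
    """A field value fails validation (malformed UUID, bad enum, ...)."""


class ReferenceMismatchError(CcfkitError, ValueError):
    """An extraction site refers to a different reference organ than the scene."""


class DuplicateIdError(CcfkitError, ValueError):
    """Identifiers that must be unique are duplicated."""


class TableFormatError(CcfkitError, ValueError):
    """An ASCT+B-style CSV is missing a required header column family."""


class PartonomyCycleError(CcfkitError, ValueError):
    """The part_of hierarchy contains a cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(f"partonomy contains a cycle: {' > '.join(self.cycle)}")


class UnknownStructureError(CcfkitError, LookupError):
    """An anatomical-structure id is absent from the table or scene."""


class UndefinedSimilarityError(CcfkitError, ValueError):
    """Cosine similarity is undefined for an all-zero vector."""


class NoReferenceError(CcfkitError, ValueError):
    """Spatial-origin prediction was asked against an empty reference atlas."""


class NoDataError(CcfkitError, ValueError):
    """No colliding anatomical structure has population data."""


class EmptyTargetError(CcfkitError, ValueError):
    """A distance query names target cell types with no cells."""


class DimensionalityError(CcfkitError, ValueError):
    """Cell positions mix 2D and 3D coordinates."""


class WindowError(CcfkitError, ValueError):
    """A k-NN window exceeds the number of cells."""


class CardinalityError(CcfkitError, ValueError):
    """More clusters requested than observations."""


class ContainmentError(CcfkitError, ValueError):
    """A synthetic child structure escapes its parent's extent."""


class SizingError(CcfkitError, ValueError):
    """A sampled tissue block is too large for its target structure."""


class UnsupportedFormatError(CcfkitError, ValueError):
    """A mesh file extension is recognized but not parsed (e.g. GLB)."""
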