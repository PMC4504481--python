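"""Typed errors raised across the package.

Every reader/operation failure is one of these; callers never see a
partially constructed object.
"""


class DarcError(Exception):
    """Base class for all package errors (maps to CLI exit code 1)."""


class EmptyStructureError(DarcError):
    """A structure file parsed but contained no atoms."""


class ConformerMismatchError(DarcError):
    """Conformer records in one ensemble disagree on atom count/ordering."""


class RayFileError(DarcError):
    """Malformed or unsupported ray-file."""


class UnsupportedGridError(DarcError):
    """A scalar grid that is not orthogonal/regular, or two grids that do not overlap."""


class EmptyPocketError(DarcError):
    """Pocket detection found no pocket cells for the given target selection."""


class SelectionError(DarcError):
    """A residue selection that does not exist in the receptor."""
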