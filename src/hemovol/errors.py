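"""Exception hierarchy for hemovol.

All package-specific failures derive from :class:`HemovolError` so callers
(and the CLI) can distinguish processing errors from programming errors.
"""


class HemovolError(Exception):
    """Base class for all hemovol processing errors."""


class CTReadError(HemovolError):
    """A CT series or volume could not be read into a valid HU grid."""


class NotHeadCTError(HemovolError):
    """The volume does not look like a head NCCT (e.g. no skull found)."""


class GridMismatchError(HemovolError):
    """A mask and its companion volume do not share the same voxel grid."""


class EmptyMaskError(HemovolError):
    """An operation that requires a non-empty mask received an empty one."""


class CohortError(HemovolError):
    """A serial-comparison cohort table is malformed (duplicate ids, bad rows)."""


class UndefinedStatisticError(HemovolError):
    """A diagnostic statistic is undefined for the given 2x2 cell pattern."""


class PhantomSpecError(HemovolError):
    """A phantom specification violates its geometric constraints."""
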