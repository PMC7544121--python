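"""Exception hierarchy.

``FormatError`` covers malformed or inconsistent input files (CLI exit code 2);
``StageError`` covers failures inside an analysis stage (CLI exit code 3).
"""


class MendelmapError(Exception):
    """Base class for all package errors."""


class FormatError(MendelmapError):
    """An input file is malformed or violates a documented precondition."""


class StageError(MendelmapError):
    """An analysis stage received arguments it cannot operate on."""


class UndefinedLDError(StageError):
    """Genotype r^2 requested for a pair that is monomorphic after
    pairwise exclusion of missing calls."""
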