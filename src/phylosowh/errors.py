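"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes (usage -> 2, data -> 3, numerical -> 4).
"""


class PhyloError(Exception):
    """Base class for all package errors."""


class UsageError(PhyloError):
    """Caller violated an operation contract (bad arguments, empty input)."""


class DataError(PhyloError):
    """Input data are malformed or internally inconsistent."""


class AlignmentError(DataError):
    """Alignment-specific data problem (ragged rows, unknown characters)."""


class NumericalError(PhyloError):
    """Likelihood or optimisation produced non-finite values."""
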