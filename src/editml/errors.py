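"""Exception hierarchy shared by all pipeline stages.

CLI exit-code mapping: :class:`InputFormatError` / :class:`ConsistencyError`
map to exit code 2 (bad input), :class:`CapacityError` /
:class:`DegenerateDataError` to exit code 3 (degenerate data).
"""


class EditmlError(Exception):
    """Base class for all editml errors."""


class InputFormatError(EditmlError):
    """A file is malformed or not in the required state (e.g. unsorted BAM)."""


class ConsistencyError(EditmlError):
    """Two inputs disagree (e.g. alignment contig absent from the reference)."""


class CapacityError(EditmlError):
    """A request exceeds what the data can supply (e.g. sampling pool too small)."""


class DegenerateDataError(EditmlError):
    """Data cannot support the operation (e.g. single-class training input)."""


class FeatureOrderError(EditmlError):
    """Feature names/order of a vector batch do not match the model."""
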