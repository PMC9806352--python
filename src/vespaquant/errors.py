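"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: format/validation problems exit with 2,
data-policy and degenerate-data problems with 3.
"""


class VespaQuantError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(VespaQuantError):
    """An input table is malformed (missing column, unparseable field)."""


class ValidationError(VespaQuantError):
    """A parsed value violates a domain invariant (negative AUC, conflicting
    annotation, effective length exceeding length, ...)."""


class BoundsError(VespaQuantError):
    """A band definition falls outside the lane profile it is applied to."""


class DegenerateDataError(VespaQuantError):
    """The input is structurally valid but carries no usable signal
    (all-zero lane, zero total AUC, no toxin-annotated transcripts)."""


class DataPolicyError(VespaQuantError):
    """A configurable strictness policy rejected the data, e.g. a band with
    positive densitometric proportion but no toxin identification under the
    ``error`` zero-band policy."""
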