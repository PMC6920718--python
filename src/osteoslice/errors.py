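"""Exception hierarchy shared by all pipeline stages.

``ValidationError`` covers anything a user can fix by correcting inputs
(bad manifests, out-of-range requests, malformed stacks); the CLI maps it
to exit code 1, and unexpected runtime failures to 2.
"""


class OsteosliceError(Exception):
    """Base class for all package errors."""


class ValidationError(OsteosliceError):
    """Invalid user input (data model violation, out-of-range request)."""


class ConfigurationError(ValidationError):
    """Missing or inconsistent manifest / config keys."""


class FormatError(ValidationError):
    """Unreadable or structurally inconsistent image data."""


class AlignmentError(OsteosliceError):
    """Principal-axis alignment cannot be performed (degenerate geometry)."""


class SegmentationError(OsteosliceError):
    """Compartment segmentation failed on too many slices."""
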