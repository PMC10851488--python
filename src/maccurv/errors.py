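"""Exception hierarchy.

All package errors derive from :class:`MacCurvError` so batch drivers can
isolate per-eye failures without swallowing programming errors.
"""


class MacCurvError(Exception):
    """Base class for all maccurv errors."""


class ConfigurationError(MacCurvError):
    """Required metadata or configuration is missing or inconsistent."""


class FormatError(MacCurvError):
    """An input file is not in the expected format."""


class ValidationError(MacCurvError):
    """A domain object violates one of its invariants."""


class RejectionError(ValidationError):
    """A segmentation line has too many missing columns to be usable."""


class DetectionError(MacCurvError):
    """RPE line detection failed on a B-scan."""


class AggregationError(MacCurvError):
    """No usable scans were available to aggregate for an eye."""
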