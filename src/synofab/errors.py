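"""Exception hierarchy shared across the pipeline stages."""


class SynofabError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SynofabError):
    """An invalid or inconsistent configuration value; the message names the field."""


class CalibrationError(SynofabError):
    """Tolerance calibration cannot proceed (e.g. too few standard observations)."""


class QuantificationError(SynofabError):
    """Concentration cannot be computed (non-positive volume or standard intensity)."""


class FormatError(SynofabError):
    """A file does not follow the expected table contract."""
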