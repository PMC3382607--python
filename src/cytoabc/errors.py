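"""Exception hierarchy for the cytoabc pipeline."""


class CytoabcError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CytoabcError):
    """Invalid simulation, panel or run configuration."""


class ContractError(CytoabcError):
    """A precondition of an operation was violated by its inputs."""


class CalibrationError(CytoabcError):
    """Bead calibration is impossible or inconsistent (e.g. non-monotone medians)."""


class ParseError(CytoabcError):
    """A cytometry file could not be parsed; the message names the offending segment."""
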