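"""Exception hierarchy shared across the package."""


class ChemogradError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ChemogradError, ValueError):
    """A parameter value violates an operation's contract."""


class ConfigurationError(ChemogradError):
    """A run configuration is incomplete or internally inconsistent."""


class SolverError(ChemogradError):
    """A numerical solver left its validity envelope (e.g. negative densities)."""


class UnsupportedFormatError(ChemogradError):
    """An input file is not in a format the package reads."""


class CalibrationError(ChemogradError):
    """Intensity-to-concentration calibration could not be established."""
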