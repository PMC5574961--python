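"""Exception hierarchy used across the package."""


class SonokineticsError(Exception):
    """Base class for package errors."""


class ArgumentError(SonokineticsError, ValueError):
    """Invalid argument value (wrong sign, unknown name, incompatible shapes)."""


class DegenerateDataError(SonokineticsError, ValueError):
    """Input data too small or too uninformative for the requested operation."""


class NumericalError(SonokineticsError, RuntimeError):
    """An integrator or optimizer failed; the message carries diagnostics."""


class SceneError(SonokineticsError, RuntimeError):
    """Synthetic scene construction failed (e.g. infeasible cell packing)."""


class FormatError(SonokineticsError, ValueError):
    """Malformed input file; the message names the offending field."""


class ConfigError(FormatError):
    """Invalid configuration value; the message names the offending field."""
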