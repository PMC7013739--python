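"""Exception hierarchy for pulseaf."""


class PulseAFError(Exception):
    """Base class for all pulseaf errors."""


class ConfigurationError(PulseAFError, ValueError):
    """Invalid parameter or configuration value."""


class InsufficientBeatsError(PulseAFError, ValueError):
    """Too few detected beats to proceed with the requested analysis."""


class SignalError(PulseAFError, ValueError):
    """Degenerate or malformed signal content."""


class ParseError(PulseAFError, ValueError):
    """Malformed on-disk record (CSV signal, config file, ...)."""
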