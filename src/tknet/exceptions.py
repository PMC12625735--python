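"""Exception hierarchy for tknet."""


class TknetError(Exception):
    """Base class for all tknet errors."""


class ConfigurationError(TknetError, ValueError):
    """Invalid simulation or pipeline configuration."""


class ValidationError(TknetError, ValueError):
    """Invalid input data (shapes, namespaces, value ranges)."""


class DesignError(TknetError, ValueError):
    """Experimental design unusable for the requested test."""
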