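"""Exception hierarchy.

``ValidationError`` covers bad user input (configs, masks, malformed frames);
``SchemaError`` covers malformed files; ``UnstableIntegrationError`` signals
that the simulator's fixed time step cannot resolve the requested dynamics.
"""


class WormwaveError(Exception):
    """Base class for all package errors."""


class ValidationError(WormwaveError, ValueError):
    """Invalid configuration, parameter, or data values."""


class SchemaError(ValidationError):
    """A file does not conform to the expected schema."""


class UnstableIntegrationError(WormwaveError, RuntimeError):
    """The integration step is too large for the configured dynamics."""
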