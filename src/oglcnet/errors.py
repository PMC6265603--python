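"""Structured exceptions shared across the package."""


class OglcnetError(Exception):
    """Base class for all package errors."""


class InvalidNetError(OglcnetError):
    """A Petri net violates a structural invariant.

    Carries the list of violation records produced by
    :func:`oglcnet.core.validate_net` so callers can inspect the first
    offending element programmatically.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        first = self.violations[0] if self.violations else None
        super().__init__(
            f"invalid net: {first}" if first else "invalid net"
        )


class UnknownElementError(OglcnetError, KeyError):
    """A place/transition id does not exist in the net."""


class SimulationError(OglcnetError):
    """Numerical integration failed or produced an inadmissible marking."""

    def __init__(self, message, time=None):
        self.time = time
        super().__init__(message if time is None else f"{message} (t={time:g})")


class ConfigError(OglcnetError):
    """A configuration file or override map is malformed."""


class InterventionError(OglcnetError):
    """An intervention cannot be applied to the given net."""


class PnmlError(OglcnetError):
    """A PNML document is malformed or structurally inconsistent."""
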