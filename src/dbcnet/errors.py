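"""Exception types shared across the package."""


class DbcnetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DbcnetError):
    """A network spec or run configuration violates an invariant.

    The message names the offending field path (e.g. ``network.p_plastic``).
    """


class MeasurementError(DbcnetError):
    """An electrophysiological measurement left its validity regime."""


class SimulationError(DbcnetError):
    """The integration produced a non-finite state; names neuron and time."""
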