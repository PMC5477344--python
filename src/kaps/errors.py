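"""Exception hierarchy for the KAPS toolkit."""


class KapsError(Exception):
    """Base class for all package-specific errors."""


class ProtocolError(KapsError):
    """Invalid protocol or command-profile configuration."""


class SchemaError(KapsError):
    """A trial file or record violates the on-disk schema."""


class SimulationInstabilityError(KapsError):
    """The limb simulation diverged numerically."""


class FilterError(KapsError):
    """The signal is unsuitable for the requested filter."""


class ParameterError(KapsError):
    """Invalid input to a kinematic-parameter computation."""


class DegenerateDataError(KapsError):
    """Statistical input is degenerate (e.g. constant sample)."""


class ModelError(KapsError):
    """Normative-model fitting or application failed."""
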