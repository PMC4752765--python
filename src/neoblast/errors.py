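"""Exception types raised by the simulator."""


class NeoblastError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(NeoblastError, ValueError):
    """A parameter set violates a model invariant (e.g. p1 >= p3)."""


class InfeasibleParametersError(NeoblastError, ValueError):
    """No steady state exists for this parameter/food combination."""


class DegenerateStateError(NeoblastError, ValueError):
    """A state the model equations cannot evaluate (e.g. all D_i = 0)."""


class ConfigError(NeoblastError, ValueError):
    """A run configuration file is malformed or inconsistent."""
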