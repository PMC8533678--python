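"""Exception hierarchy shared across the pipeline stages."""


class StressFluxError(Exception):
    """Base class for all package errors."""


class ConfigurationError(StressFluxError):
    """Invalid parameter, specification or run-configuration value."""


class FormatError(StressFluxError):
    """Malformed input file (count matrix, annotation, metabolic model...)."""


class InfeasibleError(StressFluxError):
    """The linear program has no feasible solution under the given constraints."""


class UnboundedError(StressFluxError):
    """The linear program objective is unbounded."""
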