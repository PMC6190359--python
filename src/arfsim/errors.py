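"""Exception hierarchy for arfsim."""


class ArfsimError(Exception):
    """Base class for all arfsim errors."""


class DomainError(ArfsimError, ValueError):
    """A physical quantity is outside its admissible domain (e.g. negative density)."""


class ConfigError(ArfsimError, ValueError):
    """A scenario configuration failed schema validation.

    The message carries the dotted path of the offending field, e.g.
    ``field.components[0].axis``.
    """


class QuadratureError(ArfsimError, RuntimeError):
    """Volume-average quadrature failed to converge within its refinement budget."""


class UndefinedMetricError(ArfsimError, ZeroDivisionError):
    """The force-difference metric is undefined (all-zero reference curve)."""
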