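"""Exception hierarchy for emborder."""


class EmborderError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(EmborderError, ValueError):
    """An invalid parameter value (non-positive sigma, zero iterations, ...)."""


class ConfigError(EmborderError, ValueError):
    """Aggregated configuration problems.

    ``errors`` holds one human-readable message per offending field.
    """

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class InfeasibleDensityError(ParameterError):
    """Requested protrusion bases cannot fit without overlap."""


class DegeneratePhaseError(EmborderError):
    """One phase of the level set carries (near-)zero Heaviside mass."""


class DivergenceError(EmborderError):
    """The level-set evolution produced a non-finite energy."""


class NoBorderError(EmborderError):
    """No zero-level contour crosses the region of interest."""


class TopologyError(EmborderError):
    """A contour exists but does not connect the designated ROI sides."""
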