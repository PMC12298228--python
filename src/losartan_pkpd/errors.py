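"""Exception hierarchy for losartan_pkpd."""


class LosartanPKPDError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(LosartanPKPDError, ValueError):
    """A model parameter, dose, or configuration value violates its constraints."""


class IntegrationError(LosartanPKPDError, RuntimeError):
    """The ODE/DDE solver failed to produce an acceptable solution."""


class GenotypeParseError(LosartanPKPDError, ValueError):
    """A genotype label could not be parsed; the message names the offending token."""


class UnsupportedGenotypeError(LosartanPKPDError, KeyError):
    """A syntactically valid genotype has no fitted rate constant (no interpolation)."""


class AnalysisError(LosartanPKPDError, ValueError):
    """A post-processing step (PK metric, fit, profile) received unusable input."""
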