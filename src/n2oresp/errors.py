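"""Exception hierarchy for the incubation-analysis pipeline."""


class N2ORespError(Exception):
    """Base class for all package errors."""


class ArgumentError(N2ORespError, ValueError):
    """An argument violates a documented precondition."""


class SchemaError(N2ORespError, ValueError):
    """An input table is missing required columns or is empty."""


class ValidationError(N2ORespError, ValueError):
    """Input data violate a structural invariant (e.g. non-monotone time)."""


class UnknownDonorError(N2ORespError, KeyError):
    """Requested electron donor is not in the registry."""


class UnsupportedSpeciesError(N2ORespError, ValueError):
    """Composition is more oxidized than CO2 (no electrons to donate)."""


class StoichiometryError(N2ORespError, ValueError):
    """A balanced reaction could not be constructed or failed verification."""


class ConfigurationError(N2ORespError, ValueError):
    """A required configuration value (e.g. OD to cell conversion) is absent."""


class DegenerateFitError(N2ORespError, ValueError):
    """Regression input has no variance or too few points."""


class CalibrationRangeWarning(UserWarning):
    """Temperature outside the solubility function's calibration range."""
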