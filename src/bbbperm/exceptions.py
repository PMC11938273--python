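"""Exception hierarchy shared across the package."""


class BBBPermError(Exception):
    """Base class for all package-specific errors."""


class ParseError(BBBPermError):
    """A structure file or string could not be parsed."""


class ElementError(ParseError):
    """An unknown chemical element symbol was encountered."""


class EmbeddingError(BBBPermError):
    """3D coordinate embedding failed after bounded retries."""


class ParameterizationError(BBBPermError):
    """The force field cannot parameterize one or more atoms."""


class NumericalError(BBBPermError):
    """A numerical computation produced a non-finite result."""


class ConfigurationError(BBBPermError):
    """An option, identifier, or setting is invalid or unsupported."""


class RadiusTableError(BBBPermError):
    """The van der Waals radius table lacks an element present in the molecule."""


class StateError(BBBPermError):
    """A required per-atom annotation (coordinates, radius, charge) is missing."""


class SchemaError(BBBPermError):
    """A feature-table file violates the expected schema."""


class MissingFeatureError(BBBPermError):
    """A score component references a descriptor absent from the input."""


class SampleSizeError(BBBPermError):
    """Too few observations for the requested statistical test."""


class ImputationError(BBBPermError):
    """A row has no observed feature to impute from."""


class ResamplingError(BBBPermError):
    """A class is too small to synthesize new members from."""


class HPOError(BBBPermError):
    """Every hyperparameter candidate failed to train."""


class UndefinedMetricError(BBBPermError):
    """A metric (e.g. AUC with single-class truth) is undefined."""
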