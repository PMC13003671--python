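"""Exception types shared across the package."""


class GardensetError(Exception):
    """Base class for all package errors."""


class SchemaError(GardensetError):
    """A required column is missing or a file does not match its schema."""


class ValidationError(GardensetError):
    """Input data violates an invariant (duplicate visits, out-of-range values)."""


class ConfigurationError(GardensetError):
    """A configuration value is invalid; the message names the field."""


class MissingCountError(GardensetError):
    """A visit needed by the reconstruction has a blank count."""


class UndefinedFruitSetError(GardensetError):
    """Fruit set is undefined because no flower ever bloomed (zero denominator).

    Distinct from a fruit set of 0%, which is a valid observation.
    """
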