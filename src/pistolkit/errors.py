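"""Exception hierarchy shared across the toolkit."""


class PistolkitError(Exception):
    """Base class for all toolkit errors."""


class FormatError(PistolkitError):
    """A file could not be parsed in the expected format."""


class AlphabetError(PistolkitError):
    """A sequence contains characters outside the allowed alphabet."""


class MissingFeatureError(PistolkitError):
    """A required annotation (e.g. a CDS feature) is absent."""


class CoordinateError(PistolkitError):
    """A region or position falls outside its parent sequence."""


class ConfigError(PistolkitError):
    """A parameter combination is outside the configured bounds."""


class ScaffoldIntegrityError(PistolkitError):
    """A scaffold position does not carry the base it is declared to carry."""


class NoSiteError(PistolkitError):
    """A substrate does not contain the construct's binding footprint."""


class NonIdentifiableError(PistolkitError):
    """A fit cannot be performed because the data carry no signal."""


class GenerationError(PistolkitError):
    """A synthetic fixture could not be generated under the given constraints."""
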