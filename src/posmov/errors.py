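"""Exception hierarchy used across the package."""


class PosmovError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PosmovError):
    """A file does not conform to the expected on-disk schema."""


class IntegrityError(PosmovError):
    """Data violates a structural invariant (gaps, overlaps, duplicates)."""


class RangeError(PosmovError):
    """A value lies outside its physically admissible range."""


class VocabularyError(PosmovError):
    """A category label is not part of the closed track vocabulary."""


class ConfigurationError(PosmovError):
    """A recording configuration request cannot be satisfied."""


class ModelError(PosmovError):
    """A generative or statistical model is ill-posed."""
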