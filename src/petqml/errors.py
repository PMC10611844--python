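"""Exception types shared across the pipeline."""


class PetqmlError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PetqmlError):
    """A cohort spec, prep config, or run config violates an invariant."""


class SizingError(PetqmlError):
    """Dimension / cardinality mismatch (non-power-of-two length, too-small cohort, ...)."""


class EncodingError(PetqmlError):
    """A vector cannot be amplitude-encoded (norm, zero vector, ...)."""


class DegenerateDataError(PetqmlError):
    """Training data has a single class or is otherwise unusable for fitting."""
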