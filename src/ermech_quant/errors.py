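"""Exception hierarchy shared by all analysis stages."""


class ErMechError(Exception):
    """Base class for all package errors."""


class DomainError(ErMechError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class ConfigurationError(ErMechError, ValueError):
    """A named option, profile or parameter set is not recognised."""


class GenerationError(ErMechError, RuntimeError):
    """A synthetic fixture could not be realised under its constraints."""


class GatingError(ErMechError, ValueError):
    """Input was rejected by a quality gate (e.g. too few photons)."""


class FormatError(ErMechError, ValueError):
    """Structured input violates its declared format contract."""


class SegmentationError(ErMechError, RuntimeError):
    """A segmentation step produced an empty or unusable mask."""


class DegenerateInputError(ErMechError, ValueError):
    """Input is too symmetric/constant for the requested estimate."""


class PipelineIOError(ErMechError, IOError):
    """A file referenced by a run manifest is missing or malformed."""
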