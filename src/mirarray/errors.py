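"""Exception hierarchy shared across the pipeline."""


class MirArrayError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(MirArrayError):
    """A configuration value is out of its documented range."""


class FormatError(MirArrayError):
    """An input file does not conform to its declared tabular dialect."""


class InputError(MirArrayError):
    """Inputs are structurally valid but semantically unusable."""


class NormalizationError(MirArrayError):
    """Normalization cannot proceed (e.g. no reference probes)."""
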