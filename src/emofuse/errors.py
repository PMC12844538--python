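"""Structured exceptions shared across the pipeline."""


class EmofuseError(Exception):
    """Base class for all pipeline errors."""


class InvalidInputError(EmofuseError, ValueError):
    """An input object violates a documented precondition."""


class ShapeError(EmofuseError, ValueError):
    """Array dimensions do not match the documented contract."""


class FormatError(EmofuseError, ValueError):
    """A file on disk does not follow the expected layout."""


class TrainingError(EmofuseError, RuntimeError):
    """Training aborted (e.g. non-finite loss)."""
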