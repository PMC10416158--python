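"""Exception hierarchy.

Every failure a caller can act on gets its own class; all inherit from
:class:`GoniposeError` so scripts can catch the package's errors as one family.
"""


class GoniposeError(Exception):
    """Base class for all errors raised by gonipose."""


class MissingLandmarkError(GoniposeError, KeyError):
    """A required keypoint is absent from a frame."""

    def __init__(self, keypoint: str, context: str = ""):
        self.keypoint = keypoint
        msg = f"missing landmark {keypoint!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


class DegenerateGeometryError(GoniposeError, ValueError):
    """A geometric quantity is undefined (zero-length vector, coincident points)."""


class ValidationError(GoniposeError, ValueError):
    """An input value violates its documented range or type."""


class ProjectionError(GoniposeError, ValueError):
    """A 3D point cannot be projected (it lies at or behind the camera plane)."""


class ConfigError(GoniposeError, ValueError):
    """A configuration file or option set is invalid."""


class ParseError(GoniposeError, ValueError):
    """A CSV input does not follow the documented dialect."""

    def __init__(self, msg: str, line: int | None = None):
        self.line = line
        if line is not None:
            msg = f"line {line}: {msg}"
        super().__init__(msg)


class SchemaMismatchError(GoniposeError, ValueError):
    """Feature columns handed to a model differ from the schema it was trained on."""

    def __init__(self, expected, got):
        self.expected = list(expected)
        self.got = list(got)
        missing = sorted(set(self.expected) - set(self.got))
        extra = sorted(set(self.got) - set(self.expected))
        super().__init__(
            f"feature schema mismatch: missing={missing} unexpected={extra}"
        )


class InsufficientDataError(GoniposeError, ValueError):
    """Too few rows to train or evaluate the requested model."""


class MetricUndefinedError(GoniposeError, ValueError):
    """A metric is undefined for the given data (e.g. MAPE with zero truths)."""


class BundleError(GoniposeError, ValueError):
    """A persisted model bundle is missing, tampered, or version-incompatible."""
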