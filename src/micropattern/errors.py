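"""Exception hierarchy shared across the package.

``InputError`` covers malformed user input (bad paths, inconsistent
geometry, invalid parameters) and maps to CLI exit code 1; everything
else that goes wrong mid-pipeline maps to exit code 2 via ``StageError``.
"""


class MicropatternError(Exception):
    """Base class for all package errors."""


class InputError(MicropatternError, ValueError):
    """Invalid user-supplied input: paths, shapes, parameters, configs."""


class GeometryError(InputError):
    """Inconsistent image/mask geometry or out-of-bounds coordinates."""


class InfeasibleSpecError(InputError):
    """A synthetic colony spec that cannot be realized (e.g. density too
    high for the non-overlap placement constraint)."""


class DegenerateImageError(MicropatternError):
    """An image on which the requested operation is undefined, e.g. an
    all-zero or uniform nuclear channel that admits no threshold."""


class NoCrossingError(MicropatternError):
    """A radial profile with no half-maximum crossing for the channel."""


class StageError(MicropatternError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
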