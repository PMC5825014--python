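"""Exception hierarchy.

``ValidationError`` covers bad user input (seeds, configs, shapes) and maps
to exit code 2 in the CLI; ``PipelineError`` wraps stage failures (exit 1).
"""


class SpinemorphError(Exception):
    """Base class for all package errors."""


class ValidationError(SpinemorphError, ValueError):
    """Invalid parameters or input data."""


class EmptyForegroundError(SpinemorphError):
    """Thresholding produced no foreground voxels."""


class NoPathError(SpinemorphError):
    """Requested voxels are not connected inside the given region."""


class UndefinedLandmarkError(SpinemorphError):
    """A landmark (e.g. central base point of a detached spine) is undefined."""


class PipelineError(SpinemorphError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
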