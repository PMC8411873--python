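"""Exception hierarchy for the firehealth pipeline.

Every stage raises a subclass of :class:`FireHealthError` so the pipeline
driver can abort with a stage-named error and a partial-output manifest.
"""


class FireHealthError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(FireHealthError):
    """Invalid configuration value (bad bounds, negative amplitude, ...)."""


class GridAlignmentError(FireHealthError):
    """Two gridded products do not share the same lat/lon coordinates."""


class ExtrapolationError(FireHealthError):
    """A regridding target lies outside the source grid extent."""


class StationPlacementError(FireHealthError):
    """A monitoring station lies outside the analysis domain."""


class UndefinedValueError(FireHealthError):
    """A metric is undefined for the given inputs (e.g. zero population)."""


class MissingBaselineError(FireHealthError):
    """Baseline health data missing for one or more regions."""


class StageError(FireHealthError):
    """A pipeline stage failed; carries the stage name and partial outputs."""

    def __init__(self, stage: str, message: str, manifest: list[str] | None = None):
        self.stage = stage
        self.manifest = manifest or []
        super().__init__(f"stage '{stage}' failed: {message}")
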