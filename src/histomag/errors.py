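"""Package-wide exception types."""


class HistomagError(Exception):
    """Base class for all histomag errors."""


class BackgroundOnlyError(HistomagError):
    """No foreground pixels survive the optical-density threshold."""


class RankDeficientError(HistomagError):
    """Single-stain / rank-deficient image: second singular value negligible."""


class DegenerateImageError(HistomagError):
    """An image channel is empty/zero where the operation needs signal."""


class StageError(HistomagError):
    """A preprocessing stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


class ConfigError(HistomagError):
    """An invalid configuration value, named after the violated invariant."""
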