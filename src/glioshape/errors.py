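"""Package-wide exception types.

Every error carries a short machine-readable ``code`` (stable across
versions) alongside the human-readable message, so the CLI can map
failures onto exit codes and stage-tagged diagnostics.
"""

from __future__ import annotations


class GlioshapeError(Exception):
    """Base class; ``code`` is a short stable identifier like ``"empty-mask"``."""

    def __init__(self, code: str, message: str | None = None):
        self.code = code
        super().__init__(message or code)


class MaskError(GlioshapeError):
    """Problems with a segmentation mask (empty, no medial arc, ...)."""


class CurveError(GlioshapeError):
    """Problems with a boundary curve (degenerate, closed where open needed, ...)."""


class EstimatorError(GlioshapeError):
    """An estimator could not run (insufficient scales, too few points, ...)."""


class CohortError(GlioshapeError):
    """Problems with cohort data or association inputs."""


class SurvivalError(GlioshapeError):
    """Problems in survival estimation, model fitting or validation."""
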