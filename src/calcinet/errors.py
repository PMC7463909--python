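"""Exception hierarchy for calcinet.

All package-specific failures derive from :class:`CalcinetError` so callers
can catch one base class at pipeline level.
"""


class CalcinetError(Exception):
    """Base class for all calcinet errors."""


class PlacementInfeasibleError(CalcinetError):
    """Cell placement could not satisfy the minimum-separation constraint."""

    def __init__(self, n_placed: int, n_requested: int, attempts: int):
        self.n_placed = n_placed
        self.n_requested = n_requested
        self.attempts = attempts
        super().__init__(
            f"placed {n_placed}/{n_requested} cells after {attempts} "
            f"rejection attempts; field too crowded for the requested "
            f"minimum separation"
        )


class UnknownPresetError(CalcinetError):
    """Requested simulation regime preset does not exist."""


class MalformedRecordingError(CalcinetError):
    """A recording file pair on disk failed validation."""


class NonPositiveFluorescenceError(CalcinetError):
    """Raw fluorescence contained zero/negative/non-finite values."""


class UndefinedMetricsError(CalcinetError):
    """Network metrics requested on fewer than two cells."""


class DegenerateVarianceError(CalcinetError):
    """ANOVA requested with zero within-group variance in every group."""


class InsufficientReplicatesError(CalcinetError):
    """Permutation test needs at least two replicates per condition."""


class MissingConditionError(CalcinetError):
    """A gene lacks Ct values for one of the two conditions."""


class IncompleteRunError(CalcinetError):
    """Report assembly found missing per-culture artifacts."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(
            "experiment output incomplete; missing: " + ", ".join(self.missing)
        )
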