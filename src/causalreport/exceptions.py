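"""Exception hierarchy.

Two branches matter downstream: :class:`InputError` (bad data or query,
CLI exit code 2) and :class:`EstimationError` (a model could not be fit,
CLI exit code 3).
"""


class CausalReportError(Exception):
    """Base class for all package errors."""


class InputError(CausalReportError):
    """Invalid user input: data file, query, or configuration."""


class MissingColumnError(InputError):
    """A query column is absent from the data table."""


class UnsupportedExposureError(InputError):
    """The exposure is not binary among complete cases."""


class EmptyDataError(InputError):
    """No complete cases remain after filtering."""


class ScenarioError(InputError):
    """Unknown synthetic-data scenario name."""


class EstimationError(CausalReportError):
    """A model fit failed in a way that invalidates the estimate."""


class CollinearityError(EstimationError):
    """Rank-deficient design matrix; names the offending columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )


class ArmSizeError(EstimationError):
    """An exposure arm is too small to fit its outcome model."""


class DegenerateWeightsError(EstimationError):
    """Inverse-probability weights concentrate on fewer than 2 units per arm."""


class DegenerateOutcomeError(EstimationError):
    """Outcome is constant, so the (0,1) scaling for targeting is undefined."""


class UnstableBootstrapError(EstimationError):
    """More than 20% of bootstrap replicates failed to produce an estimate."""
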