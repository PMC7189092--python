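"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A user-supplied configuration is malformed (bad column map, unknown
    stratification variable, invalid generator settings)."""


class DataError(ValueError):
    """The data themselves are unusable (no valid rows, empty groups)."""


class RankDeficiencyError(ValueError):
    """The design matrix is rank deficient on the weighted support."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; linearly dependent column(s): "
            + ", ".join(str(c) for c in self.columns)
        )


class UnidentifiedQuantileError(RuntimeError):
    """The requested quantile lies beyond the information in the data
    (the weighted check-loss program is unbounded)."""
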