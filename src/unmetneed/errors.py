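"""Exception hierarchy shared across the package."""


class UnmetNeedError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(UnmetNeedError, ValueError):
    """A table is missing required columns or has a malformed layout."""


class ConfigurationError(UnmetNeedError, ValueError):
    """A configuration object violates one of its invariants."""


class CollinearityError(UnmetNeedError, ValueError):
    """The regression design is rank deficient.

    Carries the names of the offending columns in ``terms``.
    """

    def __init__(self, terms, message=None):
        self.terms = list(terms)
        super().__init__(
            message
            or "design matrix is rank deficient; collinear terms: "
            + ", ".join(self.terms)
        )


class JoinError(UnmetNeedError, ValueError):
    """Strata in one table have no counterpart in another."""

    def __init__(self, strata, message=None):
        self.strata = list(strata)
        super().__init__(
            message
            or "no prevalence row for strata: "
            + "; ".join(map(str, self.strata))
        )


class NumericError(UnmetNeedError, ValueError):
    """A numerical precondition failed (e.g. covariance not PSD)."""
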