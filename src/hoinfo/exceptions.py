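"""Exception types shared across the package."""


class HoinfoError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(HoinfoError, ValueError):
    """An input matrix, label vector, or configuration violates its contract."""


class SingularCovarianceError(HoinfoError, ValueError):
    """A (sub)covariance matrix required by a closed-form measure is not
    positive definite.

    Singular minors are meaningful failures — typically duplicated or
    perfectly collinear variables — so they raise rather than return NaN.
    """


class GuardError(HoinfoError, ValueError):
    """A dataset failed the resampling exclusion rules (too few samples or
    strongly imbalanced classes)."""
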