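"""Typed errors raised by omnicount."""


class InvalidInputError(ValueError):
    """Malformed or inconsistent input (dimensions, signs, types)."""


class DegenerateResponseError(InvalidInputError):
    """Response vector carries no information (e.g. all counts zero).

    The intercept MLE diverges for an all-zero gene, and a constant gene
    yields a permutation-invariant statistic, so the test is undefined.
    Genome-wide drivers catch this and skip the gene with a warning.
    """


class DegenerateControlError(InvalidInputError):
    """Control statistic is permutation-invariant; control variates cannot help."""


class DegenerateSetError(InvalidInputError):
    """A covariate set whose permuted statistics have zero variance."""
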