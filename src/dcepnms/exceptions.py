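"""Exception hierarchy shared across the package."""


class DomainError(ValueError):
    """An argument is outside the physically/mathematically valid domain."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but carries no usable information
    (all-zero AIF, empty mask, all-identical training set, ...)."""


class ContractViolation(RuntimeError):
    """An internal invariant that should hold by construction was broken,
    e.g. nested residual sums of squares out of order. Indicates a bug
    upstream, not bad user input."""
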