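"""Exception hierarchy for the promid pipeline."""


class PromidError(Exception):
    """Base class for all promid errors."""


class ValidationError(PromidError):
    """Input data violates a structural invariant (duplicates, out-of-range grades, ...).

    Carries row-level diagnostics in ``problems`` so callers can report every
    offending row, not just the first.
    """

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class ScoringError(PromidError):
    """An item response is outside its declared response set."""


class DegenerateDataError(PromidError):
    """Data too degenerate for the requested estimate (single ordinal category,
    zero variance, too few observations)."""


class EstimationError(PromidError):
    """An estimate cannot be produced (empty change group, singular design)."""


class ConfigError(PromidError):
    """An infeasible or inconsistent configuration."""
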