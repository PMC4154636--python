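"""Signals used across the package.

These are deliberately fine-grained so that callers can distinguish "this
phenotype cannot be scored for this individual" (skip and continue) from a
genuine input error (abort).
"""


class PhenobayesError(Exception):
    """Base class for all package-specific errors."""


class NoPrevalence(PhenobayesError):
    """No prevalence entry exists for the requested phenotype.

    Mirrors the situation where a phenotype has to be dropped from
    prediction because no prior can be assigned.
    """


class NotPredictable(PhenobayesError):
    """Phenotype has neither knowledge-base annotations nor a prevalence."""


class NoEvidence(PhenobayesError):
    """An evidence combination was requested on an empty collection."""


class UndefinedAUC(PhenobayesError):
    """AUC requested for a phenotype with no cases or no controls."""


class NoOverlap(PhenobayesError):
    """A phenotypic profile shares no known-status phenotype with the
    posterior map it is being matched against."""


class MalformedInput(PhenobayesError):
    """A TSV/VCF input failed validation; message carries file/line/column."""
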