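"""Exception hierarchy for the costing pipeline."""


class CostModelError(Exception):
    """Base class for all domain errors raised by this package."""


class UnknownReferenceError(CostModelError):
    """A protocol, dataset or selector references an id that does not exist."""


class MissingInputError(CostModelError):
    """A required input (protocol, unit cost, epidemiological rate) is absent."""


class AllocationError(CostModelError):
    """Indirect-cost allocation has no basis (positive pool, zero technical minutes)."""


class DegenerateInputError(CostModelError):
    """A ratio or report is undefined for the given inputs (zero denominator)."""
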