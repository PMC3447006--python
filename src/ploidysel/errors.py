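"""Exception hierarchy shared across the package."""


class PloidyselError(Exception):
    """Base class for all package-specific errors."""


class PedigreeError(PloidyselError):
    """Base class for pedigree construction and query errors."""


class DuplicateIdError(PedigreeError):
    """An individual id appears more than once in a pedigree source."""


class DanglingParentError(PedigreeError):
    """A record references a parent id that is not in the pedigree."""


class PedigreeCycleError(PedigreeError):
    """An individual is its own ancestor."""


class UnknownIdError(PedigreeError):
    """A queried id does not exist in the pedigree."""


class SimulationError(PloidyselError):
    """Base class for breeding-simulator errors."""


class MatingError(SimulationError):
    """Invalid cross: selfing attempt or ploidy mismatch."""


class SelectionError(SimulationError):
    """Truncation selection cannot be satisfied (too few eligible plants)."""


class CrossingDesignError(SimulationError):
    """No valid k-regular non-relative mating design found within the retry budget."""


class EstimationError(PloidyselError):
    """Invalid input to a response or variation estimator."""
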