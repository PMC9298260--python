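"""Exception hierarchy shared across the package."""


class DendrimapError(ValueError):
    """Base class for all domain errors raised by this package."""


class NotationError(DendrimapError):
    """Base class for errors raised while parsing the linear notation."""


class BranchingError(NotationError):
    """A branching unit is misplaced or is not a lysine."""


class TopologyError(NotationError):
    """Segment multiplicities or overall topology are inconsistent."""


class VocabularyError(NotationError):
    """Unknown residue letter, cap tag, or modification without the data
    required for the requested computation."""


class DimerError(NotationError):
    """A disulfide homodimer lacks the unique bridging cysteine per monomer."""


class DegenerateCompositionError(DendrimapError):
    """Amino-acid ratio requested for an all-zero composition."""


class MixtureError(DendrimapError):
    """A single structure was requested for a stereorandomized mixture."""


class LabelledStructureError(DendrimapError):
    """A structure was requested for a compound whose label is modeled
    mass-only (no defined connectivity)."""


class StructureError(DendrimapError):
    """A SMILES string could not be parsed into a molecular graph."""


class EmptySketchError(DendrimapError):
    """MinHash requested for an empty shingle set."""


class SamplingExhaustedError(DendrimapError):
    """Library rejection sampling hit the attempt budget.

    Carries the number of attempts made in ``attempts``.
    """

    def __init__(self, message: str, attempts: int):
        super().__init__(message)
        self.attempts = attempts


class ConfigError(DendrimapError):
    """Invalid run or library configuration."""
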