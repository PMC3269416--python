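"""Exception hierarchy for homsite."""


class HomsiteError(Exception):
    """Base class for all homsite errors."""


class ParseError(HomsiteError):
    """A structure or alignment file could not be parsed."""


class EmptyModelError(HomsiteError):
    """A structure file contained no protein chains."""


class ValidationError(HomsiteError):
    """Input data violated a referential or format constraint."""


class LookupError_(HomsiteError):
    """A requested chain or residue does not exist in the model."""


class InvalidPairError(HomsiteError):
    """Two domains handed to contact detection share residues."""


class MappingError(HomsiteError):
    """A binding-site residue could not be located in its own chain."""


class CompositionError(HomsiteError):
    """Two alignments do not share the query chain they are composed through."""


class PairingError(HomsiteError):
    """Two mapped sites to be compared live on different queries."""


class ScoringError(HomsiteError):
    """A residue has no substitution-matrix row, or row lengths disagree."""


class DegenerateSiteError(HomsiteError):
    """A binding site scores non-positively against itself."""


class EmptyProfileError(HomsiteError):
    """All columns of a cluster alignment are gaps; no profile can be built."""


class GenerationError(HomsiteError):
    """A synthetic-family specification cannot be realised geometrically."""


class EvaluationError(HomsiteError):
    """A prediction could not be evaluated (empty set, unlabeled candidate)."""
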