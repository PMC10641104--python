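"""Exception hierarchy for phyloes."""


class PhyloesError(ValueError):
    """Base class for all phyloes errors."""


class InvalidTreeError(PhyloesError):
    """A tree violates the unrooted-binary structural invariants."""


class TreeCodeError(PhyloesError):
    """A step-wise tree code is malformed or has an out-of-range component."""


class InvalidMatrixError(PhyloesError):
    """A distance matrix violates symmetry, non-negativity, or zero diagonal."""


class LeafSetMismatchError(PhyloesError):
    """Two objects that must share a leaf/taxon set do not."""


class PhylipParseError(PhyloesError):
    """A PHYLIP square distance-matrix file could not be parsed."""


class NewickParseError(PhyloesError):
    """A Newick tree could not be parsed, or is not binary."""


class ConfigError(PhyloesError):
    """An evolution-strategy configuration violates its invariants."""
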