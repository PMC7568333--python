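"""Exception hierarchy for pterochron.

Each error class corresponds to one failure mode of the pipeline surface:
malformed alignments, malformed or non-ultrametric trees, table-schema
violations, configuration problems, and calibration/clade mapping failures.
"""


class PterochronError(Exception):
    """Base class for all package errors."""


class AlignmentError(PterochronError):
    """Ragged rows or otherwise invalid alignment."""


class FormatError(PterochronError):
    """Malformed input file (duplicate taxa, bad residues, unparseable)."""


class TreeError(PterochronError):
    """Non-ultrametric, unrooted, or non-binary tree."""


class SchemaError(PterochronError):
    """CSV missing a mandatory column for the requested schema."""


class ConfigError(PterochronError):
    """Invalid run configuration."""


class MappingError(PterochronError):
    """A calibration clade cannot be resolved on the tree."""


class RosterError(PterochronError):
    """A gene contains a taxon missing from the declared roster."""


class InitError(PterochronError):
    """MCMC could not find a valid starting state."""


class BinningError(PterochronError):
    """An occurrence record's stage cannot be resolved on the timescale."""
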