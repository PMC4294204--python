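"""Exception hierarchy for the CPD screening pipeline.

Every error raised deliberately by this package derives from
:class:`CpdScreenError`, so callers (and the pipeline orchestrator) can
distinguish domain failures from programming errors.
"""


class CpdScreenError(Exception):
    """Base class for all errors raised by cpdscreen."""


# --- alignment_io ---------------------------------------------------------

class AlignmentFormatError(CpdScreenError):
    """The input file is not a parseable FASTA alignment (or is empty)."""


class AlignmentShapeError(CpdScreenError):
    """Records in the alignment do not all have the same length."""


class MissingReferenceError(CpdScreenError):
    """The designated reference id is absent (or duplicated) in the alignment."""


class PositionRangeError(CpdScreenError):
    """A reference position or alignment column is out of range."""


# --- conservation ---------------------------------------------------------

class DegenerateAlignmentError(CpdScreenError):
    """No non-reference sequences to tally: the CI denominator is zero."""


class EmptySetError(CpdScreenError):
    """An operation requiring a non-empty position/CI set received none."""


class SampleSizeError(CpdScreenError):
    """A statistical comparison needs at least two values per group."""


class DegenerateVarianceError(CpdScreenError):
    """Pooled variance is zero; the t statistic is undefined."""


# --- fixation_dating ------------------------------------------------------

class TreeFormatError(CpdScreenError):
    """Newick failed to parse, or a branch length is negative/missing."""


class DatingError(CpdScreenError):
    """The tree is not ultrametric within tolerance, so node ages are undefined."""


class NoSingleGainError(CpdScreenError):
    """Derived tips cannot be explained by one gain with the allowed losses."""


class EmptyStateError(CpdScreenError):
    """No tip carries the derived state; there is nothing to date."""


# --- struct_proximity -----------------------------------------------------

class StructureParseError(CpdScreenError):
    """A coordinate file could not be parsed as fixed-column PDB."""


class ModelRangeError(CpdScreenError):
    """The requested model index does not exist in the coordinate file."""


class SelectionError(CpdScreenError):
    """An atom selection is empty (or degenerate) after filtering."""


class LowConfidenceMappingError(CpdScreenError):
    """Pairwise alignment covered too little of the query to trust the map."""


class MappingError(CpdScreenError):
    """A required position has no structural equivalent in the map."""


# --- synthetic_data / pipeline -------------------------------------------

class SpecError(CpdScreenError):
    """A synthetic-data specification violates its own invariants."""


class StageError(CpdScreenError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException | str):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
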