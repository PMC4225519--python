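"""Exception hierarchy for yhap.

All package errors derive from :class:`YHapError` so callers (and the CLI)
can catch one base class and report the concrete class name.
"""


class YHapError(Exception):
    """Base class for all yhap errors."""


class DuplicateLabelError(YHapError):
    """Two tree nodes share the same label."""


class MissingLabelError(YHapError):
    """A tree node (internal or leaf) has no label."""


class MalformedTreeError(YHapError):
    """Cycle, multiple roots, or otherwise invalid tree topology."""


class UnknownNodeError(YHapError):
    """A referenced node label does not exist in the tree."""


class DuplicateSiteError(YHapError):
    """Two markers share a genomic position without explicit permission."""


class FormatError(YHapError):
    """Input file lacks required fields (e.g. VCF without GT/PL/GL)."""


class EmptyInputError(YHapError):
    """No usable records remain after filtering."""


class BadGenotypeError(YHapError):
    """A hard-genotype entry is not 0, 1 or missing."""


class AlleleMismatchError(YHapError):
    """Ref/alt alleles disagree between marker table and likelihood input
    at a shared position."""


class ShapeError(YHapError):
    """Array dimensions disagree."""


class NumericalUnderflowError(YHapError):
    """A sample's likelihood underflowed to zero for every candidate
    haplogroup, so no posterior can be formed (only possible with the
    epsilon floor disabled)."""


class EmptyNodeSetError(YHapError):
    """The active haplogroup set is empty."""


class EMMonotonicityError(YHapError):
    """Observed-data log-likelihood decreased beyond numerical slack."""


class NotFittedError(YHapError):
    """Marker discovery requested on an augmented matrix whose free rows
    were never updated by EM."""


class DegenerateNodeWarning(UserWarning):
    """A haplogroup received zero total responsibility with smoothing
    disabled; its free-row parameters were left unchanged."""
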