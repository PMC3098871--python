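"""Exception hierarchy for the pipeline.

All package-specific failures derive from :class:`PromchipError` so callers
can catch pipeline problems without masking programming errors.
"""


class PromchipError(Exception):
    """Base class for all pipeline errors."""


class InsufficientDataError(PromchipError):
    """Too few probes/observations to fit the requested model."""


class LayoutConsistencyError(PromchipError):
    """Probe tables, truth tables or replicates disagree about the layout."""


class EmptyInputError(PromchipError):
    """A reader received an empty file or an operation an empty collection."""


class MotifFormatError(PromchipError):
    """A motif matrix file is malformed (ragged, negative, zero column)."""


class MissingSequenceError(PromchipError):
    """A bound region refers to a gene without a promoter sequence."""

    def __init__(self, gene_ids):
        self.gene_ids = sorted(gene_ids)
        super().__init__(
            f"no promoter sequence for {len(self.gene_ids)} gene(s): "
            + ", ".join(self.gene_ids[:10])
        )
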