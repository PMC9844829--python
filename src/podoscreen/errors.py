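"""Exception hierarchy shared across the package.

Every error raised deliberately by podoscreen derives from :class:`PodoscreenError`
so callers (and the CLI) can distinguish validation problems from genuine bugs.
"""


class PodoscreenError(Exception):
    """Base class for all errors raised by podoscreen."""


class MatrixFormatError(PodoscreenError, ValueError):
    """A GCT/TSV expression file is malformed (bad header, dimensions, cells)."""


class ValidationError(PodoscreenError, ValueError):
    """A domain object violates one of its invariants."""


class DuplicateGeneError(ValidationError):
    """Two rows map to the same gene after version stripping."""

    def __init__(self, duplicates):
        self.duplicates = sorted(duplicates)
        super().__init__(
            "duplicate genes after version stripping: " + ", ".join(self.duplicates)
        )


class GeneLookupError(PodoscreenError, KeyError):
    """A requested gene is absent from the matrix or panel."""

    def __init__(self, gene):
        self.gene = str(gene)
        super().__init__(f"gene not present in matrix: {self.gene}")

    def __str__(self):  # KeyError quotes its arg; keep the message readable
        return self.args[0]


class InsufficientSamplesError(PodoscreenError, ValueError):
    """Fewer samples selected than a correlation requires (minimum 3)."""


class DegenerateBaitError(PodoscreenError, ValueError):
    """The bait gene has zero variance over the selected samples."""


class ParameterError(PodoscreenError, ValueError):
    """A user-supplied parameter is outside its allowed range."""


class ConfigurationError(PodoscreenError, ValueError):
    """The input data cannot support the requested operation (e.g. no medulla)."""
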