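"""Exception hierarchy shared across the pipeline."""


class Fgfr2AxisError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(Fgfr2AxisError):
    """A simulation or pipeline configuration field is invalid."""


class MissingCoverageError(Fgfr2AxisError):
    """No genomic segment overlaps the requested locus for a sample."""

    def __init__(self, sample_id: str, gene: str):
        self.sample_id = sample_id
        self.gene = gene
        super().__init__(f"no segment overlaps {gene} for sample {sample_id!r}")


class MissingDataError(Fgfr2AxisError):
    """No usable measurement (probe, exon, value) was found."""


class AlignmentError(Fgfr2AxisError):
    """Sample identifiers do not line up between two inputs."""


class IntegrityError(Fgfr2AxisError):
    """Duplicate or inconsistent records within one modality."""


class DegenerateTableError(Fgfr2AxisError):
    """A contingency table or survival input cannot support the test."""
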