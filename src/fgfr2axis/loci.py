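"""Gene loci and promoter definitions for FGFR2 and ESRP1 (hg38).

The promoter of a gene is the window running from the transcription start
site (TSS) to 2000 bp upstream of it.  For the two genes of interest the
package carries explicit, published promoter coordinates which take
precedence over the computed window (the FGFR2 interval spans 2140 bp, a
little wider than the nominal 2 kb).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional


@dataclass(frozen=True)
class GenomicInterval:
    chromosome: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    def overlaps(self, chromosome: str, start: int, end: int) -> bool:
        return (
            chromosome == self.chromosome
            and start <= self.end
            and end >= self.start
        )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneLocus:
    """Genomic coordinates, strand, TSS and promoter window for one gene.

    ``promoter_start``/``promoter_end`` are optional explicit promoter
    coordinates; when present they override the TSS-derived window.
    """

    name: str
    chromosome: str
    start: int
    end: int
    strand: str
    tss: int
    promoter_start: Optional[int] = None
    promoter_end: Optional[int] = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"{self.name}: start {self.start} > end {self.end}")
        expected_tss = self.start if self.strand == "+" else self.end
        if self.tss != expected_tss:
            raise ValueError(
                f"{self.name}: tss {self.tss} inconsistent with strand "
                f"{self.strand} (expected {expected_tss})"
            )
        if (self.promoter_start is None) != (self.promoter_end is None):
            raise ValueError(f"{self.name}: promoter bounds must be given together")
        if self.promoter_start is not None and self.promoter_start > self.promoter_end:
            raise ValueError(f"{self.name}: promoter_start > promoter_end")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chromosome, self.start, self.end)


def promoter_region(locus: GeneLocus, length: int = 2000) -> GenomicInterval:
    """Promoter interval of ``locus``: TSS to ``length`` bp upstream.

    Upstream is relative to the strand, so the window sits at
    ``[tss - length, tss]`` for plus-strand genes and ``[tss, tss + length]``
    for minus-strand genes.  Explicit promoter coordinates stored on the
    locus take precedence over the computed window.
    """
    if length <= 0:
        raise ValueError(f"promoter length must be positive, got {length}")
    if locus.promoter_start is not None:
        return GenomicInterval(locus.chromosome, locus.promoter_start, locus.promoter_end)
    if locus.strand == "+":
        return GenomicInterval(locus.chromosome, locus.tss - length, locus.tss)
    return GenomicInterval(locus.chromosome, locus.tss, locus.tss + length)


# hg38 coordinates.  FGFR2 is transcribed on the minus strand of 10q26, so
# its TSS is the upper gene bound and the promoter extends above it; ESRP1
# sits on the plus strand of 8q22 with the promoter below its TSS.  Both
# promoter intervals are the published ones.
FGFR2 = GeneLocus(
    name="FGFR2",
    chromosome="chr10",
    start=121478334,
    end=121598458,
    strand="-",
    tss=121598458,
    promoter_start=121598458,
    promoter_end=121600598,
)

ESRP1 = GeneLocus(
    name="ESRP1",
    chromosome="chr8",
    start=94641136,
    end=94669707,
    strand="+",
    tss=94641136,
    promoter_start=94639136,
    promoter_end=94641136,
)

BUILTIN_LOCI = {"FGFR2": FGFR2, "ESRP1": ESRP1}
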