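"""Per-gene copy-number status calls.

Two sources are supported: SNP-array segment means (GDC masked-seg style
TSV) classified against a symmetric cutoff, and gene-level GISTIC 2.0
integer calls.  A tumor is *amplified* when its segment mean over the locus
is above the cutoff, *deleted* below minus the cutoff, and *normal* in
between (boundaries inclusive to normal).  When several segments overlap a
locus and disagree in category the sample is flagged *discordant* and
excluded from downstream joins rather than dropped silently.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import MissingCoverageError
from .loci import GeneLocus

logger = logging.getLogger(__name__)

AMPLIFIED = "amplified"
NORMAL = "normal"
DELETED = "deleted"
DISCORDANT = "discordant"

#: Segment-mean cutoff used by the pipeline when derivation is skipped.
DEFAULT_SEGMEAN_CUTOFF = 0.1

SEG_COLUMNS = ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean"]


@dataclass(frozen=True)
class CNCall:
    """Copy-number category of one gene in one sample, with provenance."""

    sample_id: str
    gene: str
    status: str
    source: str  # "segment_mean" | "gistic"
    evidence: tuple = field(default_factory=tuple)


def derive_segmean_cutoff(
    normal_values: Sequence[float],
    tumor_values: Sequence[float],
    grid: Sequence[float] | None = None,
    quantile: float = 0.99,
) -> float:
    """Smallest grid cutoff that contains the bulk of normal segment means.

    Scans a candidate grid (default 0.01..0.50, step 0.01) and returns the
    smallest cutoff ``c`` such that the ``quantile`` quantile of
    ``|normal_values|`` lies strictly below ``c``.  The tumor values are
    accepted for symmetry with how such cutoffs are chosen from the joint
    normal/tumor distribution but do not constrain the scan.  Falls back to
    the grid maximum with a warning when no candidate separates the normals.
    """
    normal_values = np.asarray(list(normal_values), dtype=float)
    tumor_values = np.asarray(list(tumor_values), dtype=float)
    if normal_values.size == 0 or tumor_values.size == 0:
        raise ValueError("derive_segmean_cutoff requires non-empty normal and tumor values")
    if grid is None:
        grid = np.round(np.arange(0.01, 0.50 + 1e-9, 0.01), 2)
    q = float(np.quantile(np.abs(normal_values), quantile))
    for c in grid:
        if q < c:
            return float(c)
    warnings.warn(
        f"no grid cutoff exceeds the {quantile:.0%} quantile of |normal| "
        f"({q:.3g}); returning grid maximum",
        stacklevel=2,
    )
    return float(grid[-1])


def classify_segment_mean(value: float, cutoff: float = DEFAULT_SEGMEAN_CUTOFF) -> str:
    """Classify one segment mean as amplified / normal / deleted.

    Values strictly above ``cutoff`` are amplified, strictly below
    ``-cutoff`` deleted; the closed interval ``[-cutoff, cutoff]`` is
    normal copy number.
    """
    if not math.isfinite(value):
        raise ValueError(f"segment mean must be finite, got {value!r}")
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff!r}")
    if value > cutoff:
        return AMPLIFIED
    if value < -cutoff:
        return DELETED
    return NORMAL


def classify_gistic(value, strict: bool = True) -> str:
    """Classify a gene-level GISTIC 2.0 integer call.

    Values >= 1 are amplified, <= -1 deleted, 0 normal copy number.  In
    lenient mode non-integers are rounded to the nearest valid integer and
    the coercion is logged.
    """
    valid = {-2, -1, 0, 1, 2}
    v = value
    if not (isinstance(v, (int, np.integer)) and int(v) in valid):
        if strict:
            raise ValueError(f"GISTIC call must be an integer in [-2, 2], got {value!r}")
        v = int(np.clip(round(float(value)), -2, 2))
        logger.warning("coerced GISTIC value %r to %d", value, v)
    v = int(v)
    if v >= 1:
        return AMPLIFIED
    if v <= -1:
        return DELETED
    return NORMAL


def call_gene_cn(
    segments: pd.DataFrame,
    locus: GeneLocus,
    cutoff: float = DEFAULT_SEGMEAN_CUTOFF,
) -> CNCall:
    """Call the copy-number status of ``locus`` from one sample's segments.

    Segments overlapping the locus (1-based inclusive on both ends) are
    each classified; unanimous agreement gives the shared status, any
    disagreement gives *discordant*.  All segments must belong to one
    sample.
    """
    samples = segments["Sample"].unique()
    if len(samples) != 1:
        raise ValueError(f"expected one sample, got {sorted(map(str, samples))}")
    sample_id = str(samples[0])
    mask = (
        (segments["Chromosome"].astype(str) == locus.chromosome)
        & (segments["Start"] <= locus.end)
        & (segments["End"] >= locus.start)
    )
    hits = segments.loc[mask]
    if hits.empty:
        raise MissingCoverageError(sample_id, locus.name)
    means = tuple(float(v) for v in hits["Segment_Mean"])
    categories = {classify_segment_mean(v, cutoff) for v in means}
    status = categories.pop() if len(categories) == 1 else DISCORDANT
    return CNCall(sample_id, locus.name, status, "segment_mean", evidence=means)


def read_seg(path) -> pd.DataFrame:
    """Read a GDC-style masked segment TSV (1-based inclusive coordinates)."""
    df = pd.read_csv(path, sep="\t", dtype={"Sample": str, "Chromosome": str})
    missing = [c for c in SEG_COLUMNS if c not in df.columns and c != "Num_Probes"]
    if missing:
        raise ValueError(f"segment file missing columns: {missing}")
    return df


def read_gistic(path) -> pd.DataFrame:
    """Read a gene × sample GISTIC integer TSV indexed by gene symbol."""
    return pd.read_csv(path, sep="\t", index_col=0)


def call_cohort_segmean(
    segments: pd.DataFrame,
    loci: Iterable[GeneLocus],
    cutoff: float = DEFAULT_SEGMEAN_CUTOFF,
    on_missing: str = "skip",
) -> pd.DataFrame:
    """Call every sample × locus from a pooled segment table.

    ``on_missing`` chooses between skipping samples with no overlapping
    segment for a locus ("skip", logged) and raising ("error").
    """
    loci = list(loci)
    rows = []
    for sample_id, group in segments.groupby("Sample", sort=True):
        for locus in loci:
            try:
                call = call_gene_cn(group, locus, cutoff)
            except MissingCoverageError:
                if on_missing == "error":
                    raise
                logger.info("no %s coverage for sample %s; skipped", locus.name, sample_id)
                continue
            rows.append(
                {
                    "sample_id": call.sample_id,
                    "gene": call.gene,
                    "status": call.status,
                    "source": call.source,
                    "evidence": ";".join(f"{v:g}" for v in call.evidence),
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "gene", "status", "source", "evidence"])


def call_cohort_gistic(gistic: pd.DataFrame, genes: Iterable[str] | None = None,
                       strict: bool = True) -> pd.DataFrame:
    """Tidy per-sample calls from a gene × sample GISTIC matrix."""
    genes = list(genes) if genes is not None else list(gistic.index)
    rows = []
    for gene in genes:
        if gene not in gistic.index:
            raise KeyError(f"gene {gene!r} absent from GISTIC table")
        for sample_id, value in gistic.loc[gene].items():
            rows.append(
                {
                    "sample_id": str(sample_id),
                    "gene": gene,
                    "status": classify_gistic(value, strict=strict),
                    "source": "gistic",
                    "evidence": f"{int(value)}",
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "gene", "status", "source", "evidence"])
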