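"""Promoter methylation status calls.

Two assay styles are handled:

* **Array beta-values** — probes falling in a gene's promoter are averaged
  per sample and the mean beta classified as demethylated (<= 0.33),
  hemimethylated (strictly between 0.33 and 0.66) or methylated (>= 0.66).
* **Paired RRBS counts** — for each tumor/normal pair the promoter
  methylation level is the number of methylated CpG sites; the tumor/normal
  ratio classifies the pair as hypermethylated (>= 1.5), hypomethylated
  (<= 0.66) or normal (in between).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MissingDataError
from .loci import GeneLocus, GenomicInterval, promoter_region

logger = logging.getLogger(__name__)

DEMETHYLATED = "demethylated"
HEMIMETHYLATED = "hemimethylated"
METHYLATED = "methylated"

HYPERMETHYLATED = "hypermethylated"
HYPOMETHYLATED = "hypomethylated"
RRBS_NORMAL = "normal"
RRBS_UNDEFINED = "undefined"

#: Fraction at or above which an RRBS CpG site counts as methylated.
CPG_METHYLATED_FRACTION = 0.5

# Array probes overlapping the FGFR2/ESRP1 promoter CpG islands.  The short
# lists are the probes with paired normal/tumor data on the 27k platform;
# the long lists are the full 450k CpG-island sets.
PROBES_27K = {
    "FGFR2": ["cg17028039", "cg09772154"],
    "ESRP1": ["cg26350286"],
}
PROBES_450K = {
    "FGFR2": [
        "cg03471571", "cg05368033", "cg12835048", "cg17028039", "cg06657142",
        "cg17794169", "cg22762615", "cg02179499", "cg09772154",
    ],
    "ESRP1": ["cg14154651", "cg26350286", "cg07473471"],
}


@dataclass(frozen=True)
class MethylationCall:
    sample_id: str
    gene: str
    mean_beta: float
    status: str
    probes_used: tuple


@dataclass(frozen=True)
class PairedMethylationChange:
    pair_id: str
    gene: str
    tumor_methylated_cpg: int
    normal_methylated_cpg: int
    ratio: float  # nan when undefined (N = 0)
    change: str


def classify_beta(mean_beta: float) -> str:
    """Three-way promoter methylation class from a mean beta-value."""
    if not (0.0 <= mean_beta <= 1.0):
        raise ValueError(f"mean beta-value must lie in [0, 1], got {mean_beta!r}")
    if mean_beta <= 0.33:
        return DEMETHYLATED
    if mean_beta >= 0.66:
        return METHYLATED
    return HEMIMETHYLATED


def probes_in_region(manifest: pd.DataFrame, region: GenomicInterval) -> list[str]:
    """Probe ids from a (probe_id, chrom, pos) manifest falling in ``region``."""
    mask = (
        (manifest["chrom"].astype(str) == region.chromosome)
        & (manifest["pos"] >= region.start)
        & (manifest["pos"] <= region.end)
    )
    return [str(p) for p in manifest.loc[mask, "probe_id"]]


def mean_promoter_beta(
    betas: Mapping[str, float] | pd.Series,
    probe_ids: Sequence[str],
    sample_id: str = "?",
) -> float:
    """Arithmetic mean beta over the given probes, ignoring missing values."""
    values = []
    for probe in probe_ids:
        try:
            v = betas[probe]
        except KeyError:
            continue
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"beta for probe {probe} out of [0, 1]: {v!r}")
        values.append(float(v))
    if not values:
        raise MissingDataError(
            f"no usable beta-value among probes {list(probe_ids)} for sample {sample_id!r}"
        )
    return float(np.mean(values))


def call_beta_cohort(
    beta_matrix: pd.DataFrame,
    loci: Iterable[GeneLocus],
    manifest: pd.DataFrame | None = None,
    probe_sets: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Per-sample promoter methylation calls from a probe × sample matrix.

    Probes per gene come either from an explicit ``probe_sets`` mapping
    (e.g. :data:`PROBES_450K`) or from intersecting a coordinate manifest
    with each gene's promoter.  Samples without any usable probe for a gene
    are skipped with a log message.
    """
    if probe_sets is None:
        if manifest is None:
            raise ValueError("either a manifest or explicit probe_sets is required")
        probe_sets = {
            locus.name: probes_in_region(manifest, promoter_region(locus))
            for locus in loci
        }
    rows = []
    for locus in loci:
        probes = list(probe_sets[locus.name])
        for sample_id in beta_matrix.columns:
            try:
                mean = mean_promoter_beta(beta_matrix[sample_id], probes, sample_id)
            except MissingDataError:
                logger.info("no usable %s promoter probe for %s; skipped", locus.name, sample_id)
                continue
            rows.append(
                {
                    "sample_id": str(sample_id),
                    "gene": locus.name,
                    "mean_beta": mean,
                    "status": classify_beta(mean),
                    "probes_used": ";".join(probes),
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "gene", "mean_beta", "status", "probes_used"])


def rrbs_change(
    tumor_methylated_cpg: int,
    normal_methylated_cpg: int,
    pair_id: str = "?",
    gene: str = "?",
) -> PairedMethylationChange:
    """Classify a tumor/normal promoter methylation change from CpG counts.

    The ratio tumor/normal is hypermethylated at or above 1.5 and
    hypomethylated at or below 0.66 (a roughly two-fold decrease in the
    tumor).  A pair with no methylated CpG in either sample is undefined;
    methylation appearing in the tumor over a fully unmethylated normal is
    reported hypermethylated with an undefined ratio.
    """
    t, n = tumor_methylated_cpg, normal_methylated_cpg
    for label, v in (("tumor", t), ("normal", n)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{label} methylated-CpG count must be a non-negative integer, got {v!r}")
    t, n = int(t), int(n)
    if n == 0:
        if t == 0:
            return PairedMethylationChange(pair_id, gene, t, n, float("nan"), RRBS_UNDEFINED)
        logger.warning(
            "pair %s gene %s: methylated CpGs in tumor only (T=%d, N=0); "
            "classified hypermethylated with undefined ratio", pair_id, gene, t,
        )
        return PairedMethylationChange(pair_id, gene, t, n, float("nan"), HYPERMETHYLATED)
    ratio = t / n
    if ratio >= 1.5:
        change = HYPERMETHYLATED
    elif ratio <= 0.66:
        change = HYPOMETHYLATED
    else:
        change = RRBS_NORMAL
    return PairedMethylationChange(pair_id, gene, t, n, ratio, change)


def count_methylated_cpgs(fractions: Sequence[float],
                          threshold: float = CPG_METHYLATED_FRACTION) -> int:
    """Number of CpG sites whose methylation fraction reaches ``threshold``."""
    arr = np.asarray(list(fractions), dtype=float)
    if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
        raise ValueError("CpG methylation fractions must lie in [0, 1]")
    return int(np.nansum(arr >= threshold))


def call_rrbs_cohort(counts: pd.DataFrame) -> pd.DataFrame:
    """Classify every (pair, gene) row of an RRBS count table."""
    rows = []
    for rec in counts.itertuples(index=False):
        change = rrbs_change(
            rec.tumor_methylated_cpg,
            rec.normal_methylated_cpg,
            pair_id=str(rec.pair_id),
            gene=str(rec.gene),
        )
        rows.append(
            {
                "pair_id": change.pair_id,
                "gene": change.gene,
                "tumor_methylated_cpg": change.tumor_methylated_cpg,
                "normal_methylated_cpg": change.normal_methylated_cpg,
                "ratio": change.ratio,
                "change": change.change,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["pair_id", "gene", "tumor_methylated_cpg",
                 "normal_methylated_cpg", "ratio", "change"],
    )


def read_beta_matrix(path) -> pd.DataFrame:
    """Probe × sample beta-value TSV, probes in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})


def read_rrbs_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"pair_id": str, "gene": str})
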