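"""Expression quantification of FGFR2 isoform surrogates and ESRP1.

FGFR2-IIIb and FGFR2-IIIc are mutually exclusive splice isoforms; the RPKM
of each isoform-specific exon serves as a surrogate for isoform abundance.
The IIIb-specific exon is exon 8 of RefSeq transcript NM_022970 and the
IIIc-specific exon is exon 6 of NM_001144916; their immediate neighbours
are carried along as shared-exon controls.  Tumors are dichotomized per
feature against the median expression of normal stomach samples.  A
qRT-PCR layer provides 2^-ddCt relative quantification and tumor/normal
ratio categories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MissingDataError

ABOVE = "above"
BELOW = "below"

TN_UP = "up"
TN_DOWN = "down"
TN_UNCHANGED = "unchanged"

#: Normal-stomach median thresholds reported for the TCGA reference cohort
#: (27 normal samples).  Documented constants for real-data use; the
#: pipeline recomputes thresholds from whatever normals it is given.
REFERENCE_NORMAL_MEDIANS = {"FGFR2-IIIb": 2.89, "FGFR2-IIIc": 1.53, "ESRP1": 13.26}


@dataclass(frozen=True)
class ExonKey:
    transcript: str
    exon_index: int

    def feature_name(self) -> str:
        return f"exon:{self.transcript}:{self.exon_index}"


@dataclass(frozen=True)
class ExonSurrogateMap:
    """Isoform-specific exons plus their flanking control exons."""

    iiib: ExonKey = ExonKey("NM_022970", 8)
    iiic: ExonKey = ExonKey("NM_001144916", 6)

    @property
    def iiib_upstream(self) -> ExonKey:
        return ExonKey(self.iiib.transcript, self.iiib.exon_index - 1)

    @property
    def iiib_downstream(self) -> ExonKey:
        return ExonKey(self.iiib.transcript, self.iiib.exon_index + 1)

    @property
    def iiic_upstream(self) -> ExonKey:
        return ExonKey(self.iiic.transcript, self.iiic.exon_index - 1)

    @property
    def iiic_downstream(self) -> ExonKey:
        return ExonKey(self.iiic.transcript, self.iiic.exon_index + 1)


DEFAULT_SURROGATES = ExonSurrogateMap()

#: Feature-table keys used throughout the pipeline.
FEATURES = {
    "FGFR2": "gene:FGFR2",
    "ESRP1": "gene:ESRP1",
    "FGFR2-IIIb": DEFAULT_SURROGATES.iiib.feature_name(),
    "FGFR2-IIIc": DEFAULT_SURROGATES.iiic.feature_name(),
    "FGFR2-upstream": DEFAULT_SURROGATES.iiib_upstream.feature_name(),
    "FGFR2-downstream": DEFAULT_SURROGATES.iiib_downstream.feature_name(),
}

CATEGORIZED_FEATURES = ("FGFR2-IIIb", "FGFR2-IIIc", "ESRP1",
                       "FGFR2-upstream", "FGFR2-downstream")


@dataclass(frozen=True)
class ExpressionProfile:
    """Gene FPKM and exon RPKM measurements of one sample."""

    sample_id: str
    gene_fpkm: Mapping[str, float] = field(default_factory=dict)
    exon_rpkm: Mapping[ExonKey, float] = field(default_factory=dict)

    def __post_init__(self):
        for name, v in {**dict(self.gene_fpkm),
                        **{k.feature_name(): v for k, v in self.exon_rpkm.items()}}.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{self.sample_id}: expression of {name} must be finite and >= 0, got {v!r}")


def normal_median_threshold(normal_values: Sequence[float]) -> float:
    """Sample median of normal-tissue expression values."""
    values = np.asarray(list(normal_values), dtype=float)
    if values.size == 0:
        raise ValueError("cannot take the median of an empty normal set")
    return float(np.median(values))


def categorize_expression(value: float, threshold: float) -> str:
    """Dichotomize one expression value against a normal-median threshold.

    Strictly greater than the threshold is "above"; ties go to "below" so
    that "above" always means exceedance of the normal median.
    """
    if not math.isfinite(value) or not math.isfinite(threshold):
        raise ValueError("value and threshold must be finite")
    return ABOVE if value > threshold else BELOW


def tn_ratio_category(tumor: float, normal: float) -> str:
    """Tumor/normal expression ratio category: up (>= 1.50), down (< 0.67)."""
    if not (tumor > 0 and normal > 0):
        raise ValueError(f"tumor and normal expression must be positive, got ({tumor!r}, {normal!r})")
    ratio = tumor / normal
    if ratio >= 1.50:
        return TN_UP
    if ratio < 0.67:
        return TN_DOWN
    return TN_UNCHANGED


def relative_quantification(
    ct_target: float,
    ct_housekeeping: float,
    ref_ct_target: float,
    ref_ct_housekeeping: float,
) -> float:
    """qRT-PCR relative quantification, RQ = 2^-ddCt.

    ddCt is the sample's target-minus-housekeeping delta-Ct minus the
    reference sample's; one PCR cycle corresponds to a doubling.
    """
    cts = (ct_target, ct_housekeeping, ref_ct_target, ref_ct_housekeeping)
    if any(not math.isfinite(c) for c in cts):
        return float("nan")
    ddct = (ct_target - ct_housekeeping) - (ref_ct_target - ref_ct_housekeeping)
    return float(2.0 ** (-ddct))


def extract_surrogates(
    profile: ExpressionProfile,
    surrogates: ExonSurrogateMap = DEFAULT_SURROGATES,
) -> dict[str, float]:
    """Pull the six features of interest out of one expression profile."""
    missing = []
    out: dict[str, float] = {}
    exon_wanted = {
        "FGFR2-IIIb": surrogates.iiib,
        "FGFR2-IIIc": surrogates.iiic,
        "FGFR2-upstream": surrogates.iiib_upstream,
        "FGFR2-downstream": surrogates.iiib_downstream,
    }
    for name, key in exon_wanted.items():
        if key in profile.exon_rpkm:
            out[name] = float(profile.exon_rpkm[key])
        else:
            missing.append(key.feature_name())
    for gene in ("FGFR2", "ESRP1"):
        if gene in profile.gene_fpkm:
            out[gene] = float(profile.gene_fpkm[gene])
        else:
            missing.append(f"gene:{gene}")
    if missing:
        raise MissingDataError(f"{profile.sample_id}: missing expression features {missing}")
    return out


def read_expression(path) -> pd.DataFrame:
    """Feature × sample TSV with keys ``gene:<symbol>`` / ``exon:<tx>:<i>``."""
    return pd.read_csv(path, sep="\t", index_col=0)


def profile_from_table(table: pd.DataFrame, sample_id: str) -> ExpressionProfile:
    """Build one sample's :class:`ExpressionProfile` from a feature table."""
    if sample_id not in table.columns:
        raise KeyError(f"sample {sample_id!r} absent from expression table")
    gene_fpkm: dict[str, float] = {}
    exon_rpkm: dict[ExonKey, float] = {}
    for feature, value in table[sample_id].items():
        if feature.startswith("gene:"):
            gene_fpkm[feature.split(":", 1)[1]] = float(value)
        elif feature.startswith("exon:"):
            _, tx, idx = feature.split(":")
            exon_rpkm[ExonKey(tx, int(idx))] = float(value)
    return ExpressionProfile(sample_id, gene_fpkm, exon_rpkm)


def categorize_cohort(
    table: pd.DataFrame,
    normal_samples: Sequence[str] | None = None,
    thresholds: Mapping[str, float] | None = None,
    tumor_samples: Sequence[str] | None = None,
    features: Sequence[str] = CATEGORIZED_FEATURES,
) -> pd.DataFrame:
    """Dichotomize tumors against normal-median thresholds, per feature.

    Thresholds are either supplied directly or computed as the median of
    the listed normal samples for each feature.  Returns a tidy frame with
    one row per (sample, feature).
    """
    if thresholds is None:
        if not normal_samples:
            raise ValueError("either thresholds or a non-empty normal sample list is required")
        thresholds = {
            f: normal_median_threshold(table.loc[FEATURES[f], list(normal_samples)])
            for f in features
        }
    if tumor_samples is None:
        tumor_samples = [c for c in table.columns if not normal_samples or c not in set(normal_samples)]
    rows = []
    for sample in tumor_samples:
        for f in features:
            value = float(table.loc[FEATURES[f], sample])
            thr = float(thresholds[f])
            rows.append(
                {
                    "sample_id": str(sample),
                    "feature": f,
                    "value": value,
                    "threshold": thr,
                    "category": categorize_expression(value, thr),
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "feature", "value", "threshold", "category"])
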