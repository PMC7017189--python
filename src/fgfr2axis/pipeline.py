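"""End-to-end convenience layer: cohort files in, integrated states out.

Runs the chain segment/GISTIC copy-number calls → promoter methylation
calls → normal-median expression categories → integrated per-tumor states,
on the TSV formats the individual modules read (which are also the formats
the synthetic generator writes).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import cnv, methylation, expression, integrate
from .loci import FGFR2, ESRP1


@dataclass(frozen=True)
class PipelineResult:
    cn_calls: pd.DataFrame
    methylation_calls: pd.DataFrame
    expression_categories: pd.DataFrame
    rrbs_changes: pd.DataFrame | None
    states: pd.DataFrame
    thresholds: dict


def run_pipeline(
    segment_file=None,
    gistic_file=None,
    beta_matrix=None,
    manifest_file=None,
    rrbs_counts=None,
    expression_file=None,
    clinical_file=None,
    cutoff: float = cnv.DEFAULT_SEGMEAN_CUTOFF,
    join: str = "inner",
    normal_suffix: str = "-N",
) -> PipelineResult:
    """Run the integrated analysis over a set of cohort files.

    Normal samples are recognized by ``normal_suffix`` on their identifier;
    they feed the segment-mean sanity checks and the normal-median
    expression thresholds, while calls and states are reported for tumors.
    """
    loci = [FGFR2, ESRP1]

    if segment_file is not None:
        segments = cnv.read_seg(segment_file)
        cn_calls = cnv.call_cohort_segmean(segments, loci, cutoff=cutoff)
    elif gistic_file is not None:
        cn_calls = cnv.call_cohort_gistic(cnv.read_gistic(gistic_file), [l.name for l in loci])
    else:
        cn_calls = pd.DataFrame(columns=["sample_id", "gene", "status", "source", "evidence"])
    cn_tumor = cn_calls[~cn_calls["sample_id"].str.endswith(normal_suffix)]

    meth_calls = pd.DataFrame(columns=["sample_id", "gene", "mean_beta", "status", "probes_used"])
    if beta_matrix is not None:
        manifest = methylation.read_manifest(manifest_file) if manifest_file is not None else None
        meth_calls = methylation.call_beta_cohort(
            methylation.read_beta_matrix(beta_matrix), loci,
            manifest=manifest,
            probe_sets=None if manifest is not None else methylation.PROBES_450K,
        )
    meth_tumor = meth_calls[~meth_calls["sample_id"].str.endswith(normal_suffix)]

    rrbs_changes = None
    if rrbs_counts is not None:
        rrbs_changes = methylation.call_rrbs_cohort(methylation.read_rrbs_counts(rrbs_counts))

    expr_cats = pd.DataFrame(columns=["sample_id", "feature", "value", "threshold", "category"])
    thresholds: dict = {}
    if expression_file is not None:
        table = expression.read_expression(expression_file)
        normal_samples = [c for c in table.columns if c.endswith(normal_suffix)]
        tumor_samples = [c for c in table.columns if not c.endswith(normal_suffix)]
        expr_cats = expression.categorize_cohort(
            table, normal_samples=normal_samples, tumor_samples=tumor_samples
        )
        thresholds = (
            expr_cats.drop_duplicates("feature").set_index("feature")["threshold"].to_dict()
        )

    clinical = None
    if clinical_file is not None:
        # keep the literal stage level "NA" distinct from genuinely empty cells
        clinical = pd.read_csv(clinical_file, sep="\t", dtype={"sample_id": str},
                               keep_default_na=False, na_values=[""])

    states = integrate.assemble_cohort(
        cn_calls=cn_tumor if not cn_tumor.empty else None,
        methylation_calls=meth_tumor if not meth_tumor.empty else None,
        expression_categories=expr_cats[expr_cats["feature"].isin(
            ["FGFR2-IIIb", "FGFR2-IIIc", "ESRP1"])] if not expr_cats.empty else None,
        clinical=clinical,
        join=join,
    )
    return PipelineResult(
        cn_calls=cn_tumor.reset_index(drop=True),
        methylation_calls=meth_tumor.reset_index(drop=True),
        expression_categories=expr_cats,
        rrbs_changes=rrbs_changes,
        states=states,
        thresholds=thresholds,
    )


def run_on_cohort(cohort, cutoff: float = cnv.DEFAULT_SEGMEAN_CUTOFF,
                  join: str = "inner") -> PipelineResult:
    """Run the pipeline on a :class:`~fgfr2axis.simulate.SyntheticCohort`."""
    return run_pipeline(
        segment_file=cohort.segment_file,
        beta_matrix=cohort.beta_matrix,
        manifest_file=cohort.manifest_file,
        rrbs_counts=cohort.rrbs_counts,
        expression_file=cohort.expression_file,
        clinical_file=cohort.clinical_file,
        cutoff=cutoff,
        join=join,
    )
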