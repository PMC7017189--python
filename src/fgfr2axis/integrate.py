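"""Per-tumor integration of copy number, methylation and expression calls.

Each tumor receives one integrated state: FGFR2/ESRP1 copy-number
category, FGFR2/ESRP1 promoter methylation category, above/below-normal-
median categories for the IIIb and IIIc surrogate exons and ESRP1, and the
axis flag marking the ESRP1-amplified / FGFR2-copy-normal / FGFR2-IIIc-high
combination.  Samples with discordant copy-number evidence are excluded
from joins that require copy number; any other absent modality is carried
as the explicit category "missing".
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .errors import IntegrityError
from . import cnv

MISSING = "missing"

CN_FIELDS = ("fgfr2_cn", "esrp1_cn")
METH_FIELDS = ("fgfr2_meth", "esrp1_meth")
EXPR_FIELDS = ("iiib_cat", "iiic_cat", "esrp1_expr_cat")
STATE_FIELDS = CN_FIELDS + METH_FIELDS + EXPR_FIELDS

_EXPR_FEATURE_TO_FIELD = {
    "FGFR2-IIIb": "iiib_cat",
    "FGFR2-IIIc": "iiic_cat",
    "ESRP1": "esrp1_expr_cat",
}


def _pivot_modality(tidy: pd.DataFrame, key_col: str, value_col: str,
                    mapping: dict[str, str], modality: str) -> pd.DataFrame:
    dupes = tidy.duplicated(subset=["sample_id", key_col])
    if dupes.any():
        offender = tidy.loc[dupes, ["sample_id", key_col]].iloc[0]
        raise IntegrityError(
            f"duplicate {modality} record for sample {offender['sample_id']!r}, "
            f"{key_col} {offender[key_col]!r}"
        )
    sub = tidy[tidy[key_col].isin(mapping)]
    wide = sub.pivot(index="sample_id", columns=key_col, values=value_col)
    wide = wide.rename(columns=mapping)
    for field in mapping.values():
        if field not in wide.columns:
            wide[field] = pd.NA
    return wide[list(dict.fromkeys(mapping.values()))]


def assign_axis(fgfr2_cn: str, esrp1_cn: str, iiic_cat: str):
    """Axis flag of one tumor: ESRP1 amplified, FGFR2 copy-normal, IIIc high.

    Returns True/False, or the string "missing" when any constituent call
    is missing.
    """
    values = (fgfr2_cn, esrp1_cn, iiic_cat)
    if any(pd.isna(v) or v == MISSING for v in values):
        return MISSING
    return bool(
        esrp1_cn == cnv.AMPLIFIED
        and fgfr2_cn == cnv.NORMAL
        and iiic_cat == "above"
    )


def assemble_cohort(
    cn_calls: pd.DataFrame | None = None,
    methylation_calls: pd.DataFrame | None = None,
    expression_categories: pd.DataFrame | None = None,
    clinical: pd.DataFrame | None = None,
    join: str = "inner",
    base: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join per-modality call tables into one integrated-state frame.

    ``join="inner"`` keeps tumors covered by every supplied modality
    (excluding CN-discordant samples); ``join="outer"`` keeps every tumor
    seen anywhere, with "missing" where a modality is absent.  Passing the
    result back through ``base`` with no new modalities is the identity.
    """
    if join not in ("inner", "outer"):
        raise ValueError(f"join must be 'inner' or 'outer', got {join!r}")
    frames: list[pd.DataFrame] = []
    if base is not None:
        frames.append(base.set_index("sample_id")[[c for c in base.columns if c != "sample_id"]])
    if cn_calls is not None and not cn_calls.empty:
        cn = cn_calls.copy()
        discordant = set(cn.loc[cn["status"] == cnv.DISCORDANT, "sample_id"])
        cn.loc[cn["status"] == cnv.DISCORDANT, "status"] = pd.NA
        wide = _pivot_modality(
            cn, "gene", "status",
            {"FGFR2": "fgfr2_cn", "ESRP1": "esrp1_cn"}, "copy-number",
        )
        if join == "inner":
            wide = wide.drop(index=[s for s in discordant if s in wide.index])
        frames.append(wide)
    if methylation_calls is not None and not methylation_calls.empty:
        frames.append(
            _pivot_modality(
                methylation_calls, "gene", "status",
                {"FGFR2": "fgfr2_meth", "ESRP1": "esrp1_meth"}, "methylation",
            )
        )
    if expression_categories is not None and not expression_categories.empty:
        frames.append(
            _pivot_modality(
                expression_categories, "feature", "category",
                _EXPR_FEATURE_TO_FIELD, "expression",
            )
        )
    if not frames:
        raise ValueError("assemble_cohort needs at least one modality or a base frame")

    how = "inner" if join == "inner" else "outer"
    states = frames[0]
    for frame in frames[1:]:
        states = states.join(frame, how=how)
    if join == "inner":
        modality_cols = [c for c in states.columns if c in STATE_FIELDS]
        states = states.dropna(subset=modality_cols)

    for field in STATE_FIELDS:
        if field not in states.columns:
            states[field] = MISSING
    states = states.fillna(MISSING)

    states["axis_flag"] = [
        assign_axis(r.fgfr2_cn, r.esrp1_cn, r.iiic_cat) for r in states.itertuples()
    ]

    states = states.reset_index().rename(columns={"index": "sample_id"})
    if clinical is not None:
        if clinical["sample_id"].duplicated().any():
            raise IntegrityError("duplicate sample_id in clinical table")
        states = states.merge(clinical, on="sample_id", how="left")
    ordered = ["sample_id", *STATE_FIELDS, "axis_flag"]
    rest = [c for c in states.columns if c not in ordered]
    return states[ordered + rest].sort_values("sample_id").reset_index(drop=True)


def state_frequencies(states: pd.DataFrame, keys: Sequence[str]) -> pd.DataFrame:
    """Counts and proportions of key combinations among complete samples.

    The denominator is the number of samples non-missing on every grouping
    key; proportions over those combinations sum to 1.
    """
    keys = list(keys)
    unknown = [k for k in keys if k not in states.columns]
    if unknown:
        raise ValueError(f"unknown state field(s): {unknown}")
    usable = states.copy()
    for k in keys:
        usable = usable[(usable[k] != MISSING) & usable[k].notna()]
    denominator = len(usable)
    counts = (
        usable.groupby(keys, sort=True, observed=True).size().rename("count").reset_index()
    )
    counts["proportion"] = counts["count"] / denominator if denominator else 0.0
    counts["denominator"] = denominator
    return counts
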