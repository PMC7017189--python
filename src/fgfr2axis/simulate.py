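"""Synthetic paired tumor/normal multi-omic cohort generator.

Emulates the statistical structure the downstream pipeline assumes — per
tumor latent copy-number states for FGFR2 and ESRP1 at configurable
frequencies, near-zero segment means in normals, predominantly
demethylated promoters with bimodal array beta-values, tumor expression
shifts (FGFR2-IIIb up, FGFR2-IIIc down) driven by ESRP1 amplification, and
survival times whose hazard rises for diffuse-histotype tumors with
FGFR2-IIIc expression above the normal median.  Output files use the same
TSV dialects the real-mode readers consume, plus a latent truth table for
recovery tests.

One integer seed feeds one root random stream, deterministically split per
modality so that adding a modality never perturbs the draws of another.
Identical (config, seed) therefore yields byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError
from .loci import FGFR2, ESRP1, promoter_region
from . import cnv, methylation, expression as expr
from .expression import FEATURES

_STREAMS = ("latent", "segments", "gistic", "beta", "rrbs", "expression", "clinical")

GENES = ("FGFR2", "ESRP1")
_LOCI = {"FGFR2": FGFR2, "ESRP1": ESRP1}

# ratio windows per latent paired-RRBS change, kept clear of the 0.66/1.5
# category boundaries so that integer rounding cannot flip the class
_RRBS_RATIO_WINDOWS = {
    "hypomethylated": (0.20, 0.60),
    "normal": (0.80, 1.20),
    "hypermethylated": (1.60, 2.40),
}

_META_STATES = ("demethylated", "hemimethylated", "methylated")


def _default_expr_params() -> dict[str, tuple[float, float]]:
    # location = log of the normal-stomach median for each feature
    return {
        "FGFR2-IIIb": (math.log(2.89), 0.5),
        "FGFR2-IIIc": (math.log(1.53), 0.5),
        "ESRP1": (math.log(13.26), 0.5),
        "FGFR2": (math.log(10.0), 0.5),
        "FGFR2-upstream": (math.log(5.0), 0.5),
        "FGFR2-downstream": (math.log(5.0), 0.5),
    }


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults mirror the reference cohorts.

    Amplification/deletion frequencies default to the unpaired TCGA-style
    rates (FGFR2 amplified 19%, deleted 12%; ESRP1 amplified 62%); Lauren
    and molecular-subtype margins mirror the 198-tumor clinical dataset;
    expression locations put the normal medians at 2.89 / 1.53 / 13.26 for
    IIIb / IIIc / ESRP1; the survival contrast applies a hazard ratio of 2
    to diffuse tumors with above-median IIIc.
    """

    n_pairs: int = 27
    n_unpaired_tumors: int = 311
    fgfr2_amp_freq: float = 0.19
    esrp1_amp_freq: float = 0.62
    fgfr2_del_freq: float = 0.12
    esrp1_del_freq: float = 0.05
    normal_segmean_sd: float = 0.02
    amp_shift: float = 0.5
    del_shift: float = -0.5
    beta_demeth_params: tuple[float, float] = (2.0, 18.0)
    beta_hemi_params: tuple[float, float] = (30.0, 30.0)
    beta_meth_params: tuple[float, float] = (18.0, 2.0)
    meth_freqs: Mapping[str, float] = field(
        default_factory=lambda: {"demethylated": 0.85, "hemimethylated": 0.10, "methylated": 0.05}
    )
    rrbs_change_freqs: Mapping[str, float] = field(
        default_factory=lambda: {"hypomethylated": 0.5, "normal": 0.5, "hypermethylated": 0.0}
    )
    expr_lognormal_params: Mapping[str, tuple[float, float]] = field(
        default_factory=_default_expr_params
    )
    esrp1_amp_iiic_effect: float = 0.4
    esrp1_amp_iiib_effect: float = 2.0
    esrp1_amp_expr_effect: float = 2.0
    fgfr2_amp_expr_effect: float = 2.0
    diffuse_freq: float = 0.25
    intestinal_freq: float = 0.67
    mixed_freq: float = 0.08
    subtype_freqs: Mapping[str, float] = field(
        default_factory=lambda: {"CIN": 0.51, "EBV": 0.09, "MSI": 0.19, "GS": 0.21}
    )
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    hr_diffuse_iiic_high: float = 2.0
    censoring_rate: float = 1.0 / 1500.0
    seed: int = 0

    def __post_init__(self):
        def bad(name, why):
            raise ConfigurationError(f"{name}: {why}")

        if self.n_pairs < 0:
            bad("n_pairs", "must be non-negative")
        if self.n_unpaired_tumors < 0:
            bad("n_unpaired_tumors", "must be non-negative")
        for name in ("fgfr2_amp_freq", "esrp1_amp_freq", "fgfr2_del_freq",
                     "esrp1_del_freq", "diffuse_freq", "intestinal_freq", "mixed_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                bad(name, f"probability out of [0, 1]: {v!r}")
        if self.fgfr2_amp_freq + self.fgfr2_del_freq > 1.0:
            bad("fgfr2_del_freq", "fgfr2 amplification + deletion frequency exceeds 1")
        if self.esrp1_amp_freq + self.esrp1_del_freq > 1.0:
            bad("esrp1_del_freq", "esrp1 amplification + deletion frequency exceeds 1")
        for name, freqs, keys in (
            ("meth_freqs", self.meth_freqs, set(_META_STATES)),
            ("rrbs_change_freqs", self.rrbs_change_freqs, set(_RRBS_RATIO_WINDOWS)),
            ("subtype_freqs", self.subtype_freqs, {"CIN", "EBV", "MSI", "GS"}),
        ):
            if set(freqs) != keys:
                bad(name, f"keys must be {sorted(keys)}")
            if any(not 0.0 <= p <= 1.0 for p in freqs.values()):
                bad(name, "probabilities out of [0, 1]")
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                bad(name, f"probabilities sum to {sum(freqs.values())!r}, not 1")
        if abs(self.diffuse_freq + self.intestinal_freq + self.mixed_freq - 1.0) > 1e-9:
            bad("diffuse_freq", "histotype frequencies must sum to 1")
        if self.normal_segmean_sd <= 0:
            bad("normal_segmean_sd", "must be positive")
        if not self.amp_shift > 0:
            bad("amp_shift", "must be positive")
        if not self.del_shift < 0:
            bad("del_shift", "must be negative")
        for name in ("beta_demeth_params", "beta_hemi_params", "beta_meth_params"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                bad(name, "beta-distribution shapes must be positive")
        if not self.esrp1_amp_iiic_effect < 1 or self.esrp1_amp_iiic_effect <= 0:
            bad("esrp1_amp_iiic_effect", "must lie in (0, 1)")
        for name in ("esrp1_amp_iiib_effect", "esrp1_amp_expr_effect", "fgfr2_amp_expr_effect"):
            if not getattr(self, name) > 1:
                bad(name, "must exceed 1")
        if self.baseline_hazard <= 0:
            bad("baseline_hazard", "must be positive")
        if self.hr_diffuse_iiic_high < 1:
            bad("hr_diffuse_iiic_high", "hazard ratio must be >= 1")
        if self.censoring_rate <= 0:
            bad("censoring_rate", "must be positive")
        required = set(FEATURES)
        if not required <= set(self.expr_lognormal_params):
            bad("expr_lognormal_params",
                f"missing features {sorted(required - set(self.expr_lognormal_params))}")


@dataclass(frozen=True)
class SyntheticCohort:
    """Paths of one generated cohort plus its latent truth table."""

    out_dir: Path
    segment_file: Path
    gistic_file: Path
    beta_matrix: Path
    manifest_file: Path
    rrbs_counts: Path
    expression_file: Path
    clinical_file: Path
    truth_table: Path

    def truth(self) -> pd.DataFrame:
        return pd.read_csv(self.truth_table, sep="\t", dtype={"sample_id": str})


def _streams(seed: int) -> dict[str, np.random.Generator]:
    return {
        name: np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        for i, name in enumerate(_STREAMS)
    }


def _probe_manifest() -> pd.DataFrame:
    rows = []
    for gene, probes in methylation.PROBES_450K.items():
        region = promoter_region(_LOCI[gene])
        positions = np.linspace(region.start + 50, region.end - 50, len(probes)).astype(int)
        for probe, pos in zip(probes, positions):
            rows.append({"probe_id": probe, "chrom": region.chromosome, "pos": int(pos)})
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "pos"])


def _draw_cn(rng, amp, dele):
    return rng.choice(
        [cnv.AMPLIFIED, cnv.DELETED, cnv.NORMAL], p=[amp, dele, 1.0 - amp - dele]
    )


def simulate_cohort(config: SimulationConfig, out_dir: str | Path) -> SyntheticCohort:
    """Generate a full synthetic cohort under ``config`` into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rngs = _streams(config.seed)

    pair_ids = [f"P{i + 1:04d}" for i in range(config.n_pairs)]
    normal_ids = [f"{p}-N" for p in pair_ids]
    paired_tumor_ids = [f"{p}-T" for p in pair_ids]
    unpaired_ids = [f"U{i + 1:04d}-T" for i in range(config.n_unpaired_tumors)]
    tumor_ids = paired_tumor_ids + unpaired_ids
    all_ids = normal_ids + tumor_ids

    # ---- latent states -------------------------------------------------
    rl = rngs["latent"]
    latent: dict[str, dict] = {}
    for sid in all_ids:
        is_tumor = sid.endswith("-T")
        rec = {"sample_type": "tumor" if is_tumor else "normal",
               "pair_id": sid[:-2] if sid.startswith("P") else ""}
        for gene, amp, dele in (
            ("FGFR2", config.fgfr2_amp_freq, config.fgfr2_del_freq),
            ("ESRP1", config.esrp1_amp_freq, config.esrp1_del_freq),
        ):
            rec[f"{gene.lower()}_cn"] = _draw_cn(rl, amp, dele) if is_tumor else cnv.NORMAL
        for gene in GENES:
            rec[f"{gene.lower()}_meth"] = rl.choice(
                _META_STATES, p=[config.meth_freqs[s] for s in _META_STATES]
            )
        if is_tumor:
            rec["lauren"] = rl.choice(
                ["Diffuse", "Intestinal", "Mixed"],
                p=[config.diffuse_freq, config.intestinal_freq, config.mixed_freq],
            )
            subtypes = sorted(config.subtype_freqs)
            rec["molecular_subtype"] = rl.choice(
                subtypes, p=[config.subtype_freqs[s] for s in subtypes]
            )
        latent[sid] = rec
    rrbs_latent: dict[tuple[str, str], str] = {}
    changes = sorted(_RRBS_RATIO_WINDOWS)
    for pid in pair_ids:
        for gene in GENES:
            rrbs_latent[(pid, gene)] = rl.choice(
                changes, p=[config.rrbs_change_freqs[c] for c in changes]
            )

    # ---- copy number: segment file and GISTIC calls --------------------
    rs = rngs["segments"]
    seg_rows = []
    shift = {cnv.AMPLIFIED: config.amp_shift, cnv.DELETED: config.del_shift, cnv.NORMAL: 0.0}
    for sid in all_ids:
        for gene in GENES:
            locus = _LOCI[gene]
            mean = shift[latent[sid][f"{gene.lower()}_cn"]] + rs.normal(0.0, config.normal_segmean_sd)
            seg_rows.append(
                {
                    "Sample": sid,
                    "Chromosome": locus.chromosome,
                    "Start": locus.start - 10000,
                    "End": locus.end + 10000,
                    "Num_Probes": int(rs.integers(50, 500)),
                    "Segment_Mean": round(float(mean), 6),
                }
            )
        # decoy segment away from either locus
        seg_rows.append(
            {
                "Sample": sid,
                "Chromosome": "chr1",
                "Start": 1_000_000,
                "End": 2_000_000,
                "Num_Probes": int(rs.integers(50, 500)),
                "Segment_Mean": round(float(rs.normal(0.0, config.normal_segmean_sd)), 6),
            }
        )
    segments = pd.DataFrame(seg_rows, columns=cnv.SEG_COLUMNS)

    rg = rngs["gistic"]
    gistic_values = {
        cnv.AMPLIFIED: (1, 2),
        cnv.DELETED: (-1, -2),
        cnv.NORMAL: (0, 0),
    }
    gistic = pd.DataFrame(
        {
            sid: [
                int(rg.choice(gistic_values[latent[sid][f"{g.lower()}_cn"]]))
                for g in GENES
            ]
            for sid in tumor_ids
        },
        index=pd.Index(GENES, name="gene"),
    )

    # ---- methylation: beta matrix and RRBS counts ----------------------
    rb = rngs["beta"]
    manifest = _probe_manifest()
    beta_params = {
        "demethylated": config.beta_demeth_params,
        "hemimethylated": config.beta_hemi_params,
        "methylated": config.beta_meth_params,
    }
    beta = pd.DataFrame(
        index=pd.Index(manifest["probe_id"], name="probe_id"), columns=all_ids, dtype=float
    )
    for gene in GENES:
        probes = methylation.PROBES_450K[gene]
        for sid in all_ids:
            a, b = beta_params[latent[sid][f"{gene.lower()}_meth"]]
            beta.loc[probes, sid] = np.round(rb.beta(a, b, size=len(probes)), 6)

    rr = rngs["rrbs"]
    rrbs_rows = []
    for pid in pair_ids:
        for gene in GENES:
            change = rrbs_latent[(pid, gene)]
            lo, hi = _RRBS_RATIO_WINDOWS[change]
            n_count = int(rr.integers(20, 41))
            t_count = int(round(n_count * rr.uniform(lo, hi)))
            rrbs_rows.append(
                {
                    "pair_id": pid,
                    "gene": gene,
                    "tumor_methylated_cpg": t_count,
                    "normal_methylated_cpg": n_count,
                }
            )
    rrbs = pd.DataFrame(
        rrbs_rows,
        columns=["pair_id", "gene", "tumor_methylated_cpg", "normal_methylated_cpg"],
    )

    # ---- expression -----------------------------------------------------
    re_ = rngs["expression"]
    feature_keys = [FEATURES[f] for f in FEATURES]
    values = pd.DataFrame(index=pd.Index(feature_keys, name="feature"),
                          columns=all_ids, dtype=float)
    pop_median = {f: math.exp(mu) for f, (mu, _) in config.expr_lognormal_params.items()}
    fgfr2_features = {"FGFR2", "FGFR2-IIIb", "FGFR2-IIIc", "FGFR2-upstream", "FGFR2-downstream"}
    for sid in all_ids:
        rec = latent[sid]
        is_tumor = rec["sample_type"] == "tumor"
        for fname in FEATURES:
            mu, sigma = config.expr_lognormal_params[fname]
            m = 1.0
            if is_tumor:
                if rec["fgfr2_cn"] == cnv.AMPLIFIED and fname in fgfr2_features:
                    m *= config.fgfr2_amp_expr_effect
                if rec["esrp1_cn"] == cnv.AMPLIFIED:
                    if fname == "FGFR2-IIIc":
                        m *= config.esrp1_amp_iiic_effect
                    elif fname == "FGFR2-IIIb":
                        m *= config.esrp1_amp_iiib_effect
                    elif fname == "ESRP1":
                        m *= config.esrp1_amp_expr_effect
            v = float(re_.lognormal(mu + math.log(m), sigma))
            values.loc[FEATURES[fname], sid] = round(v, 6)
        for fname, field_name in (
            ("FGFR2-IIIb", "iiib_cat"),
            ("FGFR2-IIIc", "iiic_cat"),
            ("ESRP1", "esrp1_expr_cat"),
        ):
            rec[field_name] = expr.categorize_expression(
                float(values.loc[FEATURES[fname], sid]), pop_median[fname]
            )

    # ---- clinical and survival -----------------------------------------
    rc = rngs["clinical"]
    clin_rows = []
    for sid in tumor_ids:
        rec = latent[sid]
        high_risk = rec["lauren"] == "Diffuse" and rec["iiic_cat"] == "above"
        hazard = config.baseline_hazard * (config.hr_diffuse_iiic_high if high_risk else 1.0)
        t_event = rc.exponential(1.0 / hazard)
        t_censor = rc.exponential(1.0 / config.censoring_rate)
        dead = t_event <= t_censor
        time = int(math.ceil(min(t_event, t_censor)))
        clin_rows.append(
            {
                "sample_id": sid,
                "gender": rc.choice(["Female", "Male"], p=[0.37, 0.63]),
                "age": int(rc.integers(40, 86)),
                "vital_status": "Dead" if dead else "Alive",
                "days_to_death": time if dead else "",
                "days_to_last_follow_up": "" if dead else time,
                "lauren": rec["lauren"],
                "stage": rc.choice(["I/II", "III/IV", "NA"], p=[0.48, 0.44, 0.08]),
                "molecular_subtype": rec["molecular_subtype"],
            }
        )
        rec["high_risk"] = high_risk
    clinical = pd.DataFrame(
        clin_rows,
        columns=["sample_id", "gender", "age", "vital_status", "days_to_death",
                 "days_to_last_follow_up", "lauren", "stage", "molecular_subtype"],
    )

    # ---- truth table ----------------------------------------------------
    truth_rows = []
    for sid in all_ids:
        rec = latent[sid]
        pid = rec["pair_id"]
        is_paired_tumor = sid.endswith("-T") and pid
        truth_rows.append(
            {
                "sample_id": sid,
                "sample_type": rec["sample_type"],
                "pair_id": pid,
                "fgfr2_cn": rec["fgfr2_cn"],
                "esrp1_cn": rec["esrp1_cn"],
                "fgfr2_meth": rec["fgfr2_meth"],
                "esrp1_meth": rec["esrp1_meth"],
                "fgfr2_rrbs_change": rrbs_latent[(pid, "FGFR2")] if is_paired_tumor else "",
                "esrp1_rrbs_change": rrbs_latent[(pid, "ESRP1")] if is_paired_tumor else "",
                "iiib_cat": rec["iiib_cat"],
                "iiic_cat": rec["iiic_cat"],
                "esrp1_expr_cat": rec["esrp1_expr_cat"],
                "lauren": rec.get("lauren", ""),
                "molecular_subtype": rec.get("molecular_subtype", ""),
                "high_risk": rec.get("high_risk", ""),
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "sample_type", "pair_id", "fgfr2_cn", "esrp1_cn",
                 "fgfr2_meth", "esrp1_meth", "fgfr2_rrbs_change",
                 "esrp1_rrbs_change", "iiib_cat", "iiic_cat", "esrp1_expr_cat",
                 "lauren", "molecular_subtype", "high_risk"],
    )

    paths = SyntheticCohort(
        out_dir=out,
        segment_file=out / "segments.tsv",
        gistic_file=out / "gistic.tsv",
        beta_matrix=out / "beta_values.tsv",
        manifest_file=out / "probe_manifest.tsv",
        rrbs_counts=out / "rrbs_counts.tsv",
        expression_file=out / "expression.tsv",
        clinical_file=out / "clinical.tsv",
        truth_table=out / "truth.tsv",
    )
    segments.to_csv(paths.segment_file, sep="\t", index=False)
    gistic.to_csv(paths.gistic_file, sep="\t")
    beta.to_csv(paths.beta_matrix, sep="\t")
    manifest.to_csv(paths.manifest_file, sep="\t", index=False)
    rrbs.to_csv(paths.rrbs_counts, sep="\t", index=False)
    values.to_csv(paths.expression_file, sep="\t")
    clinical.to_csv(paths.clinical_file, sep="\t", index=False)
    truth.to_csv(paths.truth_table, sep="\t", index=False)
    return paths


@dataclass(frozen=True)
class RecoveryReport:
    """Latent-state recovery per modality: confusion tables and accuracy."""

    confusion: Mapping[str, pd.DataFrame]
    accuracy: Mapping[str, float]


def _confusion(pairs: Sequence[tuple[str, str]]) -> tuple[pd.DataFrame, float]:
    df = pd.DataFrame(pairs, columns=["latent", "called"])
    table = pd.crosstab(df["latent"], df["called"])
    hits = int((df["latent"] == df["called"]).sum())
    return table, hits / len(df)


def recover_truth(
    cohort: SyntheticCohort,
    cn_calls: pd.DataFrame | None = None,
    methylation_calls: pd.DataFrame | None = None,
    expression_categories: pd.DataFrame | None = None,
    rrbs_changes: pd.DataFrame | None = None,
) -> RecoveryReport:
    """Compare downstream calls on this cohort's files with its truth table."""
    truth = cohort.truth().fillna("")
    by_sample = truth.set_index("sample_id")
    confusion: dict[str, pd.DataFrame] = {}
    accuracy: dict[str, float] = {}

    def check_samples(ids, what):
        unknown = sorted(set(ids) - set(by_sample.index))
        if unknown:
            raise AlignmentError(f"{what} calls contain samples not in truth_table: {unknown[:5]}")

    if cn_calls is not None and not cn_calls.empty:
        check_samples(cn_calls["sample_id"], "copy-number")
        pairs = [
            (by_sample.loc[r.sample_id, f"{r.gene.lower()}_cn"], r.status)
            for r in cn_calls.itertuples()
        ]
        confusion["cn"], accuracy["cn"] = _confusion(pairs)
    if methylation_calls is not None and not methylation_calls.empty:
        check_samples(methylation_calls["sample_id"], "methylation")
        pairs = [
            (by_sample.loc[r.sample_id, f"{r.gene.lower()}_meth"], r.status)
            for r in methylation_calls.itertuples()
        ]
        confusion["methylation"], accuracy["methylation"] = _confusion(pairs)
    if expression_categories is not None and not expression_categories.empty:
        check_samples(expression_categories["sample_id"], "expression")
        field_of = {"FGFR2-IIIb": "iiib_cat", "FGFR2-IIIc": "iiic_cat", "ESRP1": "esrp1_expr_cat"}
        pairs = [
            (by_sample.loc[r.sample_id, field_of[r.feature]], r.category)
            for r in expression_categories.itertuples()
            if r.feature in field_of
        ]
        confusion["expression"], accuracy["expression"] = _confusion(pairs)
    if rrbs_changes is not None and not rrbs_changes.empty:
        tumor_of_pair = truth[truth["pair_id"].astype(bool) & (truth["sample_type"] == "tumor")]
        by_pair = tumor_of_pair.set_index("pair_id")
        unknown = sorted(set(rrbs_changes["pair_id"]) - set(by_pair.index))
        if unknown:
            raise AlignmentError(f"RRBS calls contain pairs not in truth_table: {unknown[:5]}")
        pairs = [
            (by_pair.loc[r.pair_id, f"{r.gene.lower()}_rrbs_change"], r.change)
            for r in rrbs_changes.itertuples()
        ]
        confusion["rrbs"], accuracy["rrbs"] = _confusion(pairs)
    if not confusion:
        raise ValueError("recover_truth received no calls")
    return RecoveryReport(confusion=confusion, accuracy=accuracy)
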