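import dataclasses

import numpy as np
import pandas as pd
import pytest

from fgfr2axis import (
    AlignmentError,
    ConfigurationError,
    SimulationConfig,
    recover_truth,
    run_on_cohort,
    simulate_cohort,
)
from fgfr2axis import cnv, methylation, expression


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field, value",
        [
            ("fgfr2_amp_freq", 1.5),
            ("normal_segmean_sd", 0.0),
            ("amp_shift", -0.1),
            ("del_shift", 0.1),
            ("esrp1_amp_iiic_effect", 1.2),
            ("hr_diffuse_iiic_high", 0.5),
            ("censoring_rate", -1.0),
            ("n_pairs", -1),
        ],
    )
    def test_invalid_field_error_names_the_field(self, field, value):
        with pytest.raises(ConfigurationError, match=field):
            SimulationConfig(**{field: value})

    def test_histotype_frequencies_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(diffuse_freq=0.5, intestinal_freq=0.5, mixed_freq=0.5)


class TestDeterminismAndDegenerate:
    def test_empty_cohort_writes_headers_only(self, tmp_path):
        cohort = simulate_cohort(
            SimulationConfig(n_pairs=0, n_unpaired_tumors=0, seed=3), tmp_path)
        for path in (cohort.segment_file, cohort.rrbs_counts,
                     cohort.clinical_file, cohort.truth_table):
            df = pd.read_csv(path, sep="\t")
            assert df.empty and len(df.columns) >= 1

    def test_same_config_and_seed_yield_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(n_pairs=5, n_unpaired_tumors=20, seed=7)
        a = simulate_cohort(cfg, tmp_path / "a")
        b = simulate_cohort(dataclasses.replace(cfg), tmp_path / "b")
        for fa, fb in zip(dataclasses.astuple(a)[1:], dataclasses.astuple(b)[1:]):
            assert fa.read_bytes() == fb.read_bytes(), fa.name

    def test_different_seeds_differ(self, tmp_path):
        a = simulate_cohort(SimulationConfig(n_pairs=3, n_unpaired_tumors=10, seed=1), tmp_path / "a")
        b = simulate_cohort(SimulationConfig(n_pairs=3, n_unpaired_tumors=10, seed=2), tmp_path / "b")
        assert a.segment_file.read_bytes() != b.segment_file.read_bytes()


class TestLatentStructure:
    def test_amplification_frequency_within_three_binomial_se(self, tmp_path):
        cfg = SimulationConfig(n_pairs=0, n_unpaired_tumors=2000,
                               fgfr2_amp_freq=0.19, seed=13)
        truth = simulate_cohort(cfg, tmp_path).truth()
        tumors = truth[truth["sample_type"] == "tumor"]
        observed = (tumors["fgfr2_cn"] == "amplified").mean()
        se = np.sqrt(0.19 * 0.81 / len(tumors))
        assert abs(observed - 0.19) < 3 * se

    def test_normals_have_near_zero_segment_means(self, small_cohort, small_config):
        segs = cnv.read_seg(small_cohort.segment_file)
        normal_means = segs.loc[segs["Sample"].str.endswith("-N"), "Segment_Mean"]
        assert np.abs(normal_means).max() < 6 * small_config.normal_segmean_sd

    def test_esrp1_amplification_suppresses_iiic(self, small_cohort):
        truth = small_cohort.truth()
        tumors = truth[truth["sample_type"] == "tumor"]
        expr_table = expression.read_expression(small_cohort.expression_file)
        iiic = expr_table.loc[expression.FEATURES["FGFR2-IIIc"]]
        amp = iiic[tumors.loc[tumors["esrp1_cn"] == "amplified", "sample_id"]]
        not_amp = iiic[tumors.loc[tumors["esrp1_cn"] == "normal", "sample_id"]]
        assert amp.median() < not_amp.median()

    def test_every_tumor_sample_appears_in_clinical(self, small_cohort):
        clinical = pd.read_csv(small_cohort.clinical_file, sep="\t")
        truth = small_cohort.truth()
        tumor_ids = set(truth.loc[truth["sample_type"] == "tumor", "sample_id"])
        assert tumor_ids == set(clinical["sample_id"])

    def test_file_round_trip_preserves_values(self, small_cohort):
        # written files re-read through the real-mode readers match exactly
        beta = methylation.read_beta_matrix(small_cohort.beta_matrix)
        assert float(beta.iloc[0, 0]) == float(
            pd.read_csv(small_cohort.beta_matrix, sep="\t", index_col=0).iloc[0, 0])
        expr_table = expression.read_expression(small_cohort.expression_file)
        assert (expr_table >= 0).all().all()


class TestRecoverTruth:
    def test_truth_calls_recover_perfectly(self, small_cohort):
        truth = small_cohort.truth()
        tumors = truth[truth["sample_type"] == "tumor"]
        calls = pd.concat(
            [
                tumors[["sample_id", "fgfr2_cn"]]
                .rename(columns={"fgfr2_cn": "status"}).assign(gene="FGFR2"),
                tumors[["sample_id", "esrp1_cn"]]
                .rename(columns={"esrp1_cn": "status"}).assign(gene="ESRP1"),
            ]
        )
        report = recover_truth(small_cohort, cn_calls=calls)
        assert report.accuracy["cn"] == 1.0

    def test_inverted_binary_calls_score_zero(self, small_cohort):
        truth = small_cohort.truth()
        tumors = truth[truth["sample_type"] == "tumor"].copy()
        inverted = tumors["iiic_cat"].map({"above": "below", "below": "above"})
        calls = pd.DataFrame(
            {"sample_id": tumors["sample_id"], "feature": "FGFR2-IIIc",
             "category": inverted})
        report = recover_truth(small_cohort, expression_categories=calls)
        assert report.accuracy["expression"] == 0.0

    def test_unknown_sample_raises_alignment_error(self, small_cohort):
        calls = pd.DataFrame(
            [{"sample_id": "GHOST-T", "gene": "FGFR2", "status": "normal"}])
        with pytest.raises(AlignmentError):
            recover_truth(small_cohort, cn_calls=calls)

    def test_pipeline_recovery_exceeds_bound_under_separation(self, small_cohort, small_result):
        report = recover_truth(
            small_cohort,
            cn_calls=small_result.cn_calls,
            methylation_calls=small_result.methylation_calls,
            expression_categories=small_result.expression_categories[
                small_result.expression_categories["feature"].isin(
                    ["FGFR2-IIIb", "FGFR2-IIIc", "ESRP1"])],
            rrbs_changes=small_result.rrbs_changes,
        )
        # amp/del shifts sit 25 normal-noise sd from zero: a Gaussian tail
        # bound puts per-call CN error below 1e-100, so any miss is a bug
        assert report.accuracy["cn"] == 1.0
        assert report.accuracy["methylation"] > 0.95
        assert report.accuracy["rrbs"] == 1.0
        assert report.accuracy["expression"] > 0.9


class TestNullSurvivalExchangeability:
    def test_logrank_p_uniform_when_hazard_ratio_is_one(self):
        # under HR = 1 the diffuse/IIIc-high contrast is exchangeable with
        # the rest: log-rank p over seeded replicates should be uniform
        from scipy import stats as sps
        from fgfr2axis.stats import logrank

        rng = np.random.default_rng(2024)
        pvals = []
        for _ in range(200):
            n = 60
            times = rng.exponential(1000.0, n)
            censor = rng.exponential(1500.0, n)
            obs = np.minimum(times, censor)
            events = (times <= censor).astype(int)
            groups = rng.integers(0, 2, n)
            if events[groups == 0].sum() == 0 or events[groups == 1].sum() == 0:
                continue
            pvals.append(logrank(obs, events, groups).p_value)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
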