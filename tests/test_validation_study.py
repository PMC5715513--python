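"""Review sampling, PPV estimation with exact intervals, and reporting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import phenoval as pv
from phenoval.errors import EmptyArmError, MissingLabelError, OverlappingStrataError
from phenoval.validation_study import (
    STRATUM_PRIMARY,
    STRATUM_SECONDARY,
    round_half_away,
)


def records_frame(n, primary_fraction=0.07):
    k = round(n * primary_fraction)
    return pd.DataFrame({
        "record_id": [f"r{i:04d}" for i in range(n)],
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "position": ["primary"] * k + ["secondary"] * (n - k),
    })


def labels_for(records, positives, category="history_of_stroke"):
    truth = ["acute_cvd" if i < positives else "not_acute_cvd"
             for i in range(len(records))]
    return pd.DataFrame({
        "record_id": records["record_id"],
        "truth": truth,
        "category": ["" if t == "acute_cvd" else category for t in truth],
        "mimic_subtype": "",
    })


class TestSampling:
    def test_fixed_seed_is_reproducible_and_distinct(self):
        arm = records_frame(912)
        design = pv.ReviewDesign(sample_size=100, seed=42)
        a = pv.draw_review_sample(arm, design)
        b = pv.draw_review_sample(arm, design)
        assert list(a["record_id"]) == list(b["record_id"])
        assert a["record_id"].is_unique and len(a) == 100

    def test_small_arm_returns_everything_with_warning(self):
        arm = records_frame(50)
        with pytest.warns(UserWarning, match="only 50"):
            out = pv.draw_review_sample(arm, pv.ReviewDesign(100, seed=1))
        assert sorted(out["record_id"]) == sorted(arm["record_id"])

    def test_different_seeds_give_different_samples(self):
        arm = records_frame(912)
        for s in range(5):
            a = pv.draw_review_sample(arm, pv.ReviewDesign(100, seed=s))
            b = pv.draw_review_sample(arm, pv.ReviewDesign(100, seed=s + 1000))
            assert set(a["record_id"]) != set(b["record_id"])

    def test_empty_arm_raises(self):
        with pytest.raises(EmptyArmError):
            pv.draw_review_sample(records_frame(0), pv.ReviewDesign(100, seed=0))


class TestEstimation:
    @pytest.mark.parametrize("positives,n,percent", [
        (4, 7, 57), (18, 93, 19), (47, 93, 51), (6, 8, 75),
        (78, 92, 85), (6, 7, 86), (84, 93, 90), (0, 100, 0), (7, 100, 7),
    ])
    def test_report_percent_rounds_stratum_counts(self, positives, n, percent):
        est = pv.PpvEstimate("all", n, positives)
        assert est.report_percent == percent
        assert 0 <= est.ci_low <= est.ppv <= est.ci_high <= 1

    def test_zero_positive_interval_starts_at_zero(self):
        est = pv.PpvEstimate("all", 100, 0)
        assert est.ci_low == 0.0

    def test_estimate_ppv_stratifies_by_position(self):
        sample = records_frame(100, primary_fraction=0.07)
        labels = labels_for(sample, 22)  # positives land in the primary rows
        primary = pv.estimate_ppv(sample, labels, STRATUM_PRIMARY)
        secondary = pv.estimate_ppv(sample, labels, STRATUM_SECONDARY)
        assert primary.n_sampled == 7 and secondary.n_sampled == 93
        assert primary.n_positive + secondary.n_positive == 22

    def test_missing_labels_are_named(self):
        sample = records_frame(10)
        labels = labels_for(sample, 3).iloc[:6]
        with pytest.raises(MissingLabelError, match="r0006"):
            pv.estimate_ppv(sample, labels)

    def test_wilson_interval_available(self):
        exact = pv.PpvEstimate("all", 100, 90)
        wilson = pv.PpvEstimate("all", 100, 90, ci_method="wilson")
        assert wilson.ci_low != exact.ci_low
        assert 0 < wilson.ci_low < 0.9 < wilson.ci_high < 1


class TestPooling:
    @pytest.mark.parametrize("strata,expected", [
        ([(4, 7), (18, 93)], 22),
        ([(4, 7), (47, 93)], 51),
        ([(6, 8), (78, 92)], 84),
        ([(6, 7), (84, 93)], 90),
    ])
    def test_pooling_position_strata_reproduces_overall_percent(self, strata,
                                                                expected):
        ests = [pv.PpvEstimate(name, n, k) for (k, n), name in
                zip(strata, (STRATUM_PRIMARY, STRATUM_SECONDARY))]
        pooled = pv.pooled_ppv(ests)
        assert pooled.report_percent == expected
        assert pooled.n_sampled == sum(n for _, n in strata)

    def test_single_stratum_pool_is_identity(self):
        only = pv.PpvEstimate(STRATUM_PRIMARY, 7, 4)
        pooled = pv.pooled_ppv([only])
        assert (pooled.n_sampled, pooled.n_positive) == (7, 4)

    def test_overlapping_strata_rejected(self):
        with pytest.raises(OverlappingStrataError):
            pv.pooled_ppv([pv.PpvEstimate("primary", 7, 4),
                           pv.PpvEstimate("primary", 93, 18)])

    @pytest.mark.parametrize("seed", range(5))
    def test_pooled_equals_sample_size_weighted_mean(self, seed):
        rng = np.random.default_rng(seed)
        ns = rng.integers(1, 200, size=3)
        ks = [int(rng.integers(0, n + 1)) for n in ns]
        ests = [pv.PpvEstimate(f"s{i}", int(n), k)
                for i, (n, k) in enumerate(zip(ns, ks))]
        pooled = pv.pooled_ppv(ests)
        weighted = sum(e.ppv * e.n_sampled for e in ests) / sum(ns)
        assert pooled.ppv == pytest.approx(weighted, abs=1e-12)


def test_round_half_away_from_zero():
    assert round_half_away(84.5) == 85
    assert round_half_away(0.4999) == 0
    assert round_half_away(-2.5) == -3


class TestNonDiseaseTally:
    def test_breakdown_counts_by_category(self):
        records = records_frame(100)
        labels = labels_for(records, 22)
        labels.loc[22:62, "category"] = "history_of_stroke"
        labels.loc[63:84, "category"] = "stroke_mimic"
        labels.loc[63:84, "mimic_subtype"] = "seizure"
        labels.loc[85:, "category"] = "blood_or_imaging_tests"
        tally = pv.tally_nondisease(labels)
        assert tally.as_dict() == {"history_of_stroke": 41, "stroke_mimic": 22,
                                   "blood_or_imaging_tests": 15}
        assert tally.total == 78
        assert tally.mimic_subtypes == {"seizure": 22}

    def test_all_positive_review_has_empty_tally(self):
        records = records_frame(10)
        tally = pv.tally_nondisease(labels_for(records, 10))
        assert tally.total == 0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_tally_total_equals_nonpositive_count(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        records = records_frame(n)
        labels = labels_for(records, int(rng.integers(0, n)))
        neg = labels["truth"] == "not_acute_cvd"
        labels.loc[neg, "category"] = rng.choice(
            ["history_of_stroke", "stroke_mimic", "blood_or_imaging_tests"],
            size=int(neg.sum()))
        assert pv.tally_nondisease(labels).total == int(neg.sum())


def test_clopper_pearson_coverage_exceeds_nominal():
    """Exact intervals are conservative: >= 95% coverage at review scale."""
    rng = np.random.default_rng(12345)
    n = 100
    ci = {k: pv.PpvEstimate("all", n, k) for k in range(n + 1)}
    for p in (0.07, 0.22, 0.51, 0.84, 0.90):
        draws = rng.binomial(n, p, size=2000)
        covered = sum(ci[k].ci_low <= p <= ci[k].ci_high for k in draws)
        assert covered / 2000 >= 0.95, f"coverage at p={p}"


class TestReport:
    def _results(self):
        primary = pv.PpvEstimate(STRATUM_PRIMARY, 7, 4)
        secondary = pv.PpvEstimate(STRATUM_SECONDARY, 93, 18)
        overall = pv.pooled_ppv([primary, secondary])
        records = records_frame(100)
        tally = pv.tally_nondisease(labels_for(records, 22))
        return {
            "definite": {"n_records": 912,
                         "estimates": [overall, primary, secondary],
                         "tally": tally},
            "definite_any": {"n_records": 438},
        }

    def test_report_has_arm_by_stratum_grid_and_breakdown(self, tmp_path):
        paths = pv.render_report(self._results(), tmp_path, seed=7,
                                 config_note="demo")
        table = pd.read_csv(paths["csv"])
        assert set(table["arm"]) == {"definite", "definite_any"}
        assert list(table.loc[table["arm"] == "definite", "stratum"]) == [
            "all", "primary", "secondary_or_others"]
        md = open(paths["markdown"]).read()
        assert "Seed: 7" in md and "| arm |" in md
        breakdown = pd.read_csv(paths["breakdown_csv"])
        assert breakdown["count"].sum() >= 78

    def test_identical_inputs_produce_identical_files(self, tmp_path):
        a = pv.render_report(self._results(), tmp_path / "a", seed=1)
        b = pv.render_report(self._results(), tmp_path / "b", seed=1)
        for key in a:
            assert open(a[key]).read() == open(b[key]).read()

    def test_counts_only_report_without_labels(self, tmp_path):
        paths = pv.render_report({"definite": {"n_records": 912}}, tmp_path)
        table = pd.read_csv(paths["csv"])
        assert table.at[0, "n_records"] == 912
        assert "breakdown_csv" not in paths


def test_exact_interval_matches_beta_quantiles():
    """Cross-check the CI route against direct beta-distribution quantiles."""
    k, n = 22, 100
    est = pv.PpvEstimate("all", n, k)
    assert est.ci_low == pytest.approx(stats.beta.ppf(0.025, k, n - k + 1))
    assert est.ci_high == pytest.approx(stats.beta.ppf(0.975, k + 1, n - k))
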