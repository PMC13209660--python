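"""Tests for ROI and channel-wise analyses and the pipeline driver."""

import hashlib

import numpy as np
import pandas as pd
import pytest

from nirsleep.analysis import (
    ROI_REGISTRY,
    PipelineConfig,
    ROIDefinition,
    channelwise_analysis,
    data_quality_table,
    roi_group_comparison,
    roi_mean,
    run_pipeline,
)
from nirsleep.stats import StatsParams
from nirsleep.synthetic import CohortConfig

FAST = StatsParams(n_permutations=200, n_bootstrap=200, rng_seed=0)


def test_roi_registry_channel_lists():
    """The shipped registry reproduces the full-cohort activation and
    contrast channel maps the sleep-stage analyses inherit."""
    expect = {
        ("UK", "social_activation"): {"HbO": {9, 15, 16, 18}, "HbR": {15, 18}},
        ("GM", "social_activation"): {
            "HbO": {15, 16, 18},
            "HbR": {6, 7, 9, 10, 13, 15, 16, 18},
        },
        ("UK", "fam1_activation"): {"HbO": {4, 7}, "HbR": {7, 15, 18}},
        ("GM", "fam1_activation"): {"HbO": {1, 4, 7, 13}, "HbR": {4, 7, 13}},
        ("UK", "nv_contrast"): {
            "HbO": {4, 13, 14, 15, 16},
            "HbR": {4, 7, 9, 13, 14, 15, 16, 17, 18},
        },
        ("UK", "habituation"): {"HbO": {4, 7}, "HbR": {7}},
        ("GM", "habituation"): {"HbO": {1, 7}, "HbR": {4, 7, 13}},
    }
    assert set(ROI_REGISTRY) == set(expect)
    for key, chans in expect.items():
        for chrom, ids in chans.items():
            assert set(ROI_REGISTRY[key].channels[chrom]) == ids


def _tidy(subject_values: dict, channel_values: dict, condition="N", chrom="HbO"):
    rows = []
    for sid, base in subject_values.items():
        for ch, v in channel_values.items():
            rows.append(
                {
                    "subject_id": sid,
                    "channel": ch,
                    "chromophore": chrom,
                    "condition": condition,
                    "value": base + v,
                }
            )
    return pd.DataFrame(rows)


class TestRoiMean:
    def test_single_channel_identity(self):
        df = _tidy({"s1": 1.0, "s2": 2.0}, {7: 0.0})
        roi = ROIDefinition("UK", "x", {"HbO": (7,)})
        vals = roi_mean(df, roi, "N", "HbO")
        assert vals["s1"] == 1.0 and vals["s2"] == 2.0

    def test_mean_and_order_invariance(self):
        df = _tidy({"s1": 0.0}, {4: 1.0, 7: 3.0})
        a = roi_mean(df, ROIDefinition("UK", "x", {"HbO": (4, 7)}), "N", "HbO")
        b = roi_mean(df, ROIDefinition("UK", "x", {"HbO": (7, 4)}), "N", "HbO")
        assert a["s1"] == 2.0 == b["s1"]

    def test_missing_channel_rejected(self):
        df = _tidy({"s1": 0.0}, {4: 1.0})
        with pytest.raises(KeyError):
            roi_mean(df, ROIDefinition("UK", "x", {"HbO": (4, 7)}), "N", "HbO")


class TestRoiGroupComparison:
    def test_null_groups_give_small_d(self):
        rng = np.random.default_rng(0)
        res = roi_group_comparison(rng.normal(0, 1, 30), rng.normal(0, 1, 30), FAST)
        assert abs(res.effect_size_d) < 0.6
        assert res.p_permutation is not None  # contract: both p values present
        assert res.d_ci is not None

    def test_iqr_filter_applied_per_group(self):
        rng = np.random.default_rng(1)
        qs = np.concatenate([rng.normal(0, 0.1, 15), [50.0]])
        as_ = rng.normal(0, 0.1, 15)
        res = roi_group_comparison(qs, as_, FAST)
        # the gross outlier is dropped from QS; filtering is per group
        assert res.extra["n_removed"]["QS"] >= 1
        n_as, n_qs = res.n_per_group
        assert n_as == 15 - res.extra["n_removed"]["AS"]
        assert n_qs == 16 - res.extra["n_removed"]["QS"]

    def test_direction_is_as_minus_qs(self):
        qs = np.array([1.0, 1.1, 0.9, 1.0, 1.05, 0.95])
        as_ = qs - 1.0
        res = roi_group_comparison(qs, as_, FAST)
        assert res.statistic < 0  # AS below QS -> negative t, as in reports


class TestChannelwise:
    def _responses(self, rng, effect_channels=(), n=20, effect=1.0, conds=("N",)):
        rows = []
        for cond in conds:
            for sid in range(n):
                for ch in range(1, 19):
                    for chrom, scale in (("HbO", 1.0), ("HbR", -0.4)):
                        mu = effect * scale if (ch in effect_channels and cond == conds[0]) else 0.0
                        rows.append(
                            {
                                "subject_id": f"s{sid:02d}",
                                "channel": ch,
                                "chromophore": chrom,
                                "condition": cond,
                                "value": rng.normal(mu, 0.5),
                            }
                        )
        return pd.DataFrame(rows)

    def test_planted_channels_detected_with_correct_calls(self):
        rng = np.random.default_rng(2)
        df = self._responses(rng, effect_channels=(4, 7), n=24, effect=1.2)
        calls, table = channelwise_analysis(df, "N", params=FAST)
        sig_hbo = {
            c.channel for c in calls if c.chromophore == "HbO" and c.activated
        }
        assert {4, 7} <= sig_hbo
        assert len(sig_hbo - {4, 7}) <= 2  # rare false positives only

    def test_contrast_only_on_baseline_significant_channels(self):
        rng = np.random.default_rng(3)
        df = self._responses(rng, effect_channels=(4,), n=24, effect=1.5,
                             conds=("N", "V"))
        calls, table = channelwise_analysis(df, "N", comparison_condition="V",
                                            params=FAST)
        act = table[(table["stage"] == "activation") & (table["chromophore"] == "HbO")]
        sig_set = set(act[act["significant"]]["channel"])
        contrast = table[(table["stage"] == "contrast") & (table["chromophore"] == "HbO")]
        assert set(contrast["channel"]) == sig_set

    def test_atypical_same_direction_flagged(self):
        rng = np.random.default_rng(4)
        rows = []
        for sid in range(24):
            for ch in range(1, 19):
                for chrom in ("HbO", "HbR"):
                    mu = 1.5 if ch == 9 else 0.0  # both chromophores UP on ch 9
                    rows.append(
                        {
                            "subject_id": f"s{sid}",
                            "channel": ch,
                            "chromophore": chrom,
                            "condition": "N",
                            "value": rng.normal(mu, 0.4),
                        }
                    )
        calls, _ = channelwise_analysis(pd.DataFrame(rows), "N", params=FAST)
        ch9 = [c for c in calls if c.channel == 9]
        assert all(c.atypical for c in ch9)
        assert not any(c.activated for c in ch9)

    def test_null_data_rarely_significant(self):
        rng = np.random.default_rng(5)
        n_sig = []
        for _ in range(30):
            df = self._responses(rng, effect_channels=(), n=20)
            _, table = channelwise_analysis(df, "N", params=FAST)
            n_sig.append(int(table["significant"].sum()))
        assert np.mean(n_sig) < 1.0


class TestDataQualityTable:
    def test_planted_as_artifact_excess_gives_negative_t(self):
        rng = np.random.default_rng(6)
        rows = []
        groups = []
        for i in range(16):
            g = "AS" if i < 8 else "QS"
            clean = rng.normal(95.5 if g == "AS" else 99.5, 1.0)
            rows.append({"subject_id": f"s{i}", "metric": "percent_clean_data",
                         "value": clean})
            groups.append({"subject_id": f"s{i}", "analysis": "social",
                           "group": g, "stage_constant": True})
        out = data_quality_table(pd.DataFrame(rows), pd.DataFrame(groups), FAST)
        row = out.iloc[0]
        assert row["t"] < 0 and row["p"] < 0.05
        assert row["AS_mean"] < row["QS_mean"]

    def test_equal_rates_null_behavior(self):
        rng = np.random.default_rng(7)
        rows, groups = [], []
        for i in range(20):
            g = "AS" if i < 10 else "QS"
            rows.append({"subject_id": f"s{i}", "metric": "percent_clean_data",
                         "value": rng.normal(98.0, 1.0)})
            groups.append({"subject_id": f"s{i}", "analysis": "social",
                           "group": g, "stage_constant": True})
        out = data_quality_table(pd.DataFrame(rows), pd.DataFrame(groups), FAST)
        assert abs(out.iloc[0]["cohens_d"]) < 1.0


class TestPipeline:
    def _config(self, tmp_path=None, paradigm="social_selectivity", seed=11):
        return PipelineConfig(
            cohort=CohortConfig(paradigm=paradigm, group_sizes={"QS": 5, "AS": 5}),
            seed=seed,
            stats=FAST,
            out_dir=tmp_path,
        )

    def test_end_to_end_writes_reports(self, tmp_path):
        bundle = run_pipeline(self._config(tmp_path))
        for name in ("manifest.csv", "responses.csv", "qc_metrics.csv",
                     "allocations.csv", "qc_reports.json", "run_log.json"):
            assert (tmp_path / name).exists()
        ledger = bundle["exclusion_ledger"]
        parts = ("low_codability", "low_quality", "too_few_trials", "analyzed")
        assert sum(ledger[k] for k in parts) == ledger["total"] == 10

    def test_rerun_same_seed_identical_outputs(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        run_pipeline(self._config(d1))
        run_pipeline(self._config(d2))
        for name in ("manifest.csv", "responses.csv", "allocations.csv"):
            h1 = hashlib.sha256((d1 / name).read_bytes()).hexdigest()
            h2 = hashlib.sha256((d2 / name).read_bytes()).hexdigest()
            assert h1 == h2, name

    def test_hand_paradigm_pipeline(self):
        bundle = run_pipeline(self._config(paradigm="hand", seed=12))
        assert bundle["exclusion_ledger"]["analyzed"] >= 8
        assert {"hand_fam1", "hand_habituation", "hand_novelty"} <= set(
            bundle["groups"]["analysis"].unique()
        )


def test_planted_stage_by_amplitude_interaction_recovered():
    """At study-like group sizes the pipeline recovers the planted
    direction of the habituation effect: stronger Fam1-Fam3 decrement in
    active sleep than in quiet sleep (positive AS-QS contrast difference)."""
    config = PipelineConfig(
        cohort=CohortConfig(paradigm="hand", group_sizes={"QS": 16, "AS": 15}),
        seed=5,
        stats=FAST,
    )
    bundle = run_pipeline(config)
    res = bundle["roi_results"]["habituation_HbO"]
    assert res.statistic > 0
    assert res.p_parametric < 0.05
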