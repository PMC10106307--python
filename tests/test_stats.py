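"""Statistical pipeline: MAD outliers, the latency mixed model, apathy
regressions, rod fixing and the correlation battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest, spearmanr

from fisherman.stats import (
    apathy_regression,
    correlation_battery,
    fit_latency_lmm,
    mad_outlier_mask,
    prepare_long_table,
    rod_fix_comparison,
)


def brute_force_mad_mask(y, k=3.0):
    """Literal transcription of the outlier rule."""
    y = list(y)
    med = sorted(y)[len(y) // 2] if len(y) % 2 else 0.5 * (
        sorted(y)[len(y) // 2 - 1] + sorted(y)[len(y) // 2]
    )
    abs_dev = sorted(abs(v - med) for v in y)
    mad = abs_dev[len(y) // 2] if len(y) % 2 else 0.5 * (
        abs_dev[len(y) // 2 - 1] + abs_dev[len(y) // 2]
    )
    scaled = 1.4826 * mad
    return [abs(v - med) > k * scaled for v in y]


class TestMadOutlierMask:
    def test_single_spike_flagged(self):
        mask = mad_outlier_mask([1.0, 1.0, 1.0, 1.0, 100.0])
        assert mask.tolist() == [False, False, False, False, True]

    def test_constant_vector_flags_nothing(self):
        assert not mad_outlier_mask([2.0] * 10).any()

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(77)
        for _ in range(300):
            n = rng.integers(3, 40)
            y = rng.lognormal(0.0, 0.5, size=n)
            if rng.random() < 0.3:
                y[rng.integers(n)] *= 30
            assert mad_outlier_mask(y).tolist() == brute_force_mad_mask(y)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mad_outlier_mask([])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        y=st.lists(st.floats(0.01, 1e4), min_size=3, max_size=40),
        c=st.floats(0.01, 1e3),
    )
    def test_scale_equivariance(self, y, c):
        base = mad_outlier_mask(y)
        scaled = mad_outlier_mask(np.asarray(y) * c)
        assert base.tolist() == scaled.tolist()


class TestPrepareLongTable:
    def test_extreme_latency_removed(self, session_record):
        spiked = session_record.copy()
        idx = spiked[spiked["action_type"] == "fish"].index[10]
        spiked.loc[idx, "latency_s"] = 500.0
        table = prepare_long_table(spiked)
        assert (table["latency_s"] < 500.0).all()

    def test_bookkeeping(self, session_record):
        fish = session_record[session_record["action_type"] == "fish"]
        straddling = int(fish["straddles_boundary"].sum())
        flagged = sum(
            mad_outlier_mask(g["latency_s"].to_numpy()).sum()
            for _, g in fish[fish["straddles_boundary"] == 0].groupby(
                ["participant_id", "environment"]
            )
        )
        table = prepare_long_table(session_record)
        assert len(table) == len(fish) - straddling - flagged
        assert (table["action_type"] == "fish").all()
        assert (table["straddles_boundary"] == 0).all()

    def test_log_column(self, session_record):
        table = prepare_long_table(session_record)
        np.testing.assert_allclose(table["log_latency"], np.log(table["latency_s"]))


@pytest.fixture(scope="module")
def lmm_result(coupled_cohort):
    return fit_latency_lmm(prepare_long_table(coupled_cohort["records"]))


class TestLatencyLmm:
    def test_sign_pattern(self, lmm_result):
        fe = lmm_result.fixed_effects
        assert fe.loc["price", "estimate"] < 0
        assert fe.loc["environment", "estimate"] < 0
        assert fe.loc["price", "ci_high"] < 0
        assert fe.loc["environment", "ci_high"] < 0
        # generative fatigue drift is positive on average
        assert fe.loc["cumulative_taps", "estimate"] > -1e-4

    def test_one_slope_row_per_participant(self, lmm_result, coupled_cohort):
        slopes = lmm_result.subject_slopes
        assert set(slopes["participant_id"]) == set(
            coupled_cohort["records"]["participant_id"]
        )
        assert len(slopes) == len(coupled_cohort["subjects"])

    def test_cis_bracket_estimates(self, lmm_result):
        fe = lmm_result.fixed_effects
        assert (fe["ci_low"] <= fe["estimate"]).all()
        assert (fe["estimate"] <= fe["ci_high"]).all()

    def test_mean_total_slope_near_fixed_effect(self, lmm_result):
        fe = lmm_result.fixed_effects
        slopes = lmm_result.subject_slopes
        for name, col in [("price", "price_slope"), ("environment", "environment_slope")]:
            assert abs(slopes[col].mean() - fe.loc[name, "estimate"]) < 2 * fe.loc[name, "se"]

    def test_price_slopes_track_true_sensitivity(self, lmm_result, coupled_cohort):
        merged = lmm_result.subject_slopes.merge(
            coupled_cohort["subjects"], on="participant_id"
        )
        rho = spearmanr(
            merged["true_reward_sensitivity"], merged["price_slope"]
        ).statistic
        assert rho <= -0.8  # more negative slope <-> larger sensitivity


class TestRodFixComparison:
    def test_null_when_identical(self):
        rec = pd.DataFrame(
            {
                "participant_id": np.repeat([f"s{i}" for i in range(8)], 4),
                "environment": ["high", "high", "low", "low"] * 8,
                "action_type": "rod",
                "latency_s": np.tile([0.5, 0.7, 0.5, 0.7], 8),
            }
        )
        res = rod_fix_comparison(rec)
        assert res.t == pytest.approx(0.0, abs=1e-12)

    def test_faster_in_high_environment(self, coupled_cohort):
        res = rod_fix_comparison(coupled_cohort["records"])
        assert res.t < 0
        assert res.p < 0.05
        assert res.df == len(coupled_cohort["subjects"]) - 1

    def test_label_swap_flips_sign(self, coupled_cohort):
        rec = coupled_cohort["records"].copy()
        swapped = rec.assign(
            environment=rec["environment"].map({"high": "low", "low": "high"})
        )
        assert rod_fix_comparison(swapped).t == pytest.approx(
            -rod_fix_comparison(rec).t
        )

    def test_subject_missing_one_environment_dropped(self, coupled_cohort):
        rec = coupled_cohort["records"]
        drop_pid = rec["participant_id"].iloc[0]
        broken = rec[
            ~((rec["participant_id"] == drop_pid) & (rec["environment"] == "low"))
        ]
        with pytest.warns(UserWarning, match="without rod episodes"):
            res = rod_fix_comparison(broken)
        assert res.df == len(coupled_cohort["subjects"]) - 2


class TestApathyRegression:
    def test_coupled_cohort_negative_beta(self, lmm_result, coupled_cohort):
        res = apathy_regression(
            lmm_result.subject_slopes, coupled_cohort["subjects"],
            outcome="bAMI", predictor="price_slope", age_band="young",
        )
        assert res.beta < 0
        assert res.n == len(coupled_cohort["subjects"])
        assert res.ci_low <= res.beta <= res.ci_high

    def test_constant_outcome_rejected(self, lmm_result, coupled_cohort):
        subjects = coupled_cohort["subjects"].copy()
        subjects["bAMI"] = 2.0
        with pytest.raises(ValueError, match="constant"):
            apathy_regression(lmm_result.subject_slopes, subjects, age_band="young")

    def test_band_too_small_rejected(self, lmm_result, coupled_cohort):
        with pytest.raises(ValueError, match="band"):
            apathy_regression(
                lmm_result.subject_slopes, coupled_cohort["subjects"], age_band="older"
            )


class TestCorrelationBattery:
    def test_sign_pattern(self, lmm_result, coupled_cohort):
        table = correlation_battery(
            coupled_cohort["fits"], lmm_result.subject_slopes,
            coupled_cohort["subjects"], age_band="young",
        ).set_index("measure")
        assert table.loc["price_slope", "rho"] < 0
        assert table.loc["reward_sensitivity_hat", "rho"] > 0
        assert table.loc["delta_oct", "rho"] > 0
        assert table.loc["median_latency_highest_state", "rho"] < 0

    def test_permutation_null(self, lmm_result, coupled_cohort):
        """With permuted apathy labels the correlations vanish and their
        p-values look uniform."""
        rng = np.random.default_rng(123)
        pvals = []
        for _ in range(50):
            shuffled = coupled_cohort["subjects"].copy()
            shuffled["bAMI"] = rng.permutation(shuffled["bAMI"].to_numpy())
            table = correlation_battery(
                coupled_cohort["fits"], lmm_result.subject_slopes, shuffled,
                age_band="young",
            )
            pvals.append(table.set_index("measure").loc["price_slope", "p"])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_too_few_pairs_rejected(self, lmm_result, coupled_cohort):
        small = coupled_cohort["subjects"].head(5)
        with pytest.raises(ValueError, match="fewer than 10"):
            correlation_battery(
                coupled_cohort["fits"], lmm_result.subject_slopes, small, age_band="young"
            )
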