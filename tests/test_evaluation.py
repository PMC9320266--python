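import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vancomipd.evaluation import (
    bias,
    ci95_mean,
    classification_accuracy,
    classify_exposure,
    exposure_summary,
    icc_absolute_agreement,
    individually_acceptable,
    performance_table,
    rbias,
    rrmse,
    wilcoxon_paired,
)

PREDS = np.array([10.0, 20.0])
OBS = np.array([10.0, 25.0])


class TestMetrics:
    def test_worked_two_point_example(self):
        assert bias(PREDS, OBS) == pytest.approx(-2.5)
        assert rbias(PREDS, OBS) == pytest.approx(-10.0)
        assert rrmse(PREDS, OBS) == pytest.approx(np.sqrt(0.04 / 2) * 100)

    def test_exact_predictions_zero_everything(self):
        x = np.array([5.0, 15.0, 30.0])
        assert bias(x, x) == 0.0
        assert rbias(x, x) == 0.0
        assert rrmse(x, x) == 0.0

    def test_bias_antisymmetry(self):
        assert bias(OBS, PREDS) == -bias(PREDS, OBS)

    def test_rbias_scale_invariance(self):
        assert rbias(3 * PREDS, 3 * OBS) == pytest.approx(rbias(PREDS, OBS))

    def test_single_record_rrmse_equals_abs_rbias(self):
        assert rrmse([18.0], [20.0]) == pytest.approx(abs(rbias([18.0], [20.0])))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(1, 40), st.integers(0, 10_000))
    def test_matches_brute_force_loop(self, n, seed):
        """Vectorized metrics agree with an element-by-element recomputation."""
        rng = np.random.default_rng(seed)
        p = rng.uniform(1, 40, n)
        o = rng.uniform(1, 40, n)
        b = sum(pi - oi for pi, oi in zip(p, o)) / n
        rb = sum((pi - oi) / oi for pi, oi in zip(p, o)) / n * 100
        rr = (sum(((pi - oi) / oi) ** 2 for pi, oi in zip(p, o)) / n) ** 0.5 * 100
        assert bias(p, o) == pytest.approx(b, abs=1e-12)
        assert rbias(p, o) == pytest.approx(rb, abs=1e-12)
        assert rrmse(p, o) == pytest.approx(rr, abs=1e-12)

    def test_rejects_nonpositive_observed(self):
        with pytest.raises(ValueError):
            rbias([1.0], [0.0])


class TestCi95:
    def test_constant_vector_degenerate_interval(self):
        lo, hi = ci95_mean([7.0, 7.0, 7.0])
        assert lo == hi == 7.0

    def test_symmetric_about_mean(self):
        lo, hi = ci95_mean([1.0, 2.0, 3.0, 4.0])
        assert (lo + hi) / 2 == pytest.approx(2.5)

    def test_frozen_t_quantile_case(self):
        # hand computation: mean 3, sd sqrt(2.5), n=5, t_{.975,4}=2.776445...
        lo, hi = ci95_mean([1.0, 2.0, 3.0, 4.0, 5.0])
        assert lo == pytest.approx(1.0367568385224428, rel=1e-12)
        assert hi == pytest.approx(4.963243161477557, rel=1e-12)


class TestAcceptability:
    @pytest.mark.parametrize(
        "pred, obs, ok",
        [
            (18.0, 19.0, True),   # |err| 1 <= 2 mg/L below 20
            (23.0, 20.0, False),  # 15% > 10% at >= 20
            (22.0, 20.0, True),   # 10% boundary inclusive
            (17.0, 19.9, False),  # |err| 2.9 > 2
            (22.5, 19.9, False),  # observed < 20: absolute 2 mg/L rule applies
        ],
    )
    def test_rule(self, pred, obs, ok):
        assert individually_acceptable(pred, obs) is ok


class TestExposureClassification:
    @pytest.mark.parametrize(
        "conc, mode, expected",
        [
            (15.7, "intermittent", "therapeutic"),
            (22.1, "continuous", "therapeutic"),
            (12.5, "intermittent", "therapeutic"),   # boundary inclusive
            (17.5, "intermittent", "therapeutic"),
            (12.4, "intermittent", "subtherapeutic"),
            (17.6, "intermittent", "supratherapeutic"),
            (19.9, "continuous", "subtherapeutic"),
            (25.1, "continuous", "supratherapeutic"),
        ],
    )
    def test_ranges(self, conc, mode, expected):
        assert classify_exposure(conc, mode) == expected

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            classify_exposure(15.0, "oral")

    def test_accuracy_all_exact_is_100(self):
        o = [13.0, 21.0, 16.0]
        assert classification_accuracy(o, o, ["intermittent", "continuous",
                                              "intermittent"]) == 100.0

    def test_accuracy_hand_counted_fixture(self):
        # categories (observed): ther, sub, supra, ther; predictions move
        # records 2 and 3 across a boundary -> 2/4 agree
        p = [15.0, 13.0, 16.0, 14.0]
        o = [16.0, 12.0, 18.0, 13.0]
        modes = ["intermittent"] * 4
        assert classification_accuracy(p, o, modes) == pytest.approx(50.0)

    def test_empty_subgroup_is_an_error(self):
        with pytest.raises(ValueError):
            classification_accuracy([], [], [])


class TestExposureSummary:
    def test_published_cohort_percentages(self):
        cats = (["therapeutic"] * 148 + ["supratherapeutic"] * 94
                + ["subtherapeutic"] * 66)
        out = exposure_summary(cats)
        assert out.loc["therapeutic", "percent"] == 48.1
        assert out.loc["supratherapeutic", "percent"] == 30.5
        assert out.loc["subtherapeutic", "percent"] == 21.4
        assert int(out["count"].sum()) == 308

    def test_single_category(self):
        out = exposure_summary(["therapeutic"] * 7)
        assert out.loc["therapeutic", "percent"] == 100.0

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        cats = ["therapeutic"] * 3 + ["subtherapeutic"] * 5 + ["supratherapeutic"] * 2
        shuffled = list(cats)
        rng.shuffle(shuffled)
        assert exposure_summary(cats).equals(exposure_summary(shuffled))


class TestIcc:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert icc_absolute_agreement(x, x) == pytest.approx(1.0)

    def test_offset_penalized_below_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = x + 50.0
        assert icc_absolute_agreement(x, y) < 0.2
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(1.0)

    def test_frozen_anova_hand_computation(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 3.0, 5.0, 4.0, 8.0]
        assert icc_absolute_agreement(x, y) == pytest.approx(0.6842105263157894, rel=1e-12)

    def test_matches_pingouin_icc2(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        x = rng.normal(1000, 250, 40)
        y = x + rng.normal(50, 150, 40)
        ours = icc_absolute_agreement(x, y)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(40), 2),
            "raters": np.tile(["a", "b"], 40),
            "score": np.column_stack([x, y]).ravel(),
        })
        ref = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="score")
        icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert ours == pytest.approx(icc2, abs=1e-9)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            icc_absolute_agreement([1.0, 2.0], [1.0, 2.0])


class TestWilcoxon:
    def test_identical_vectors_degenerate(self):
        assert wilcoxon_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_antisymmetric_in_shift_direction(self):
        rng = np.random.default_rng(2)
        x = rng.normal(10, 1, 50)
        assert wilcoxon_paired(x, x + 0.5) == pytest.approx(
            wilcoxon_paired(x, x - 0.5), rel=1e-9)

    def test_power_above_ninety_percent_for_one_sd_shift(self):
        """At n = 100 pairs and a shift of one sd the test should almost
        always reject at alpha = 0.05."""
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 60
        for _ in range(reps):
            x = rng.normal(0, 1, 100)
            y = x + rng.normal(1.0, 0.3, 100)
            if wilcoxon_paired(x, y) <= 0.05:
                rejections += 1
        assert rejections / reps > 0.9


class TestPerformanceTable:
    def test_assembles_all_subgroups_without_dropping_records(self):
        import pandas as pd

        rng = np.random.default_rng(3)
        n = 40
        records = pd.DataFrame({
            "approach": ["GOTI"] * n,
            "predicted": rng.uniform(8, 30, n),
            "observed": rng.uniform(8, 30, n),
            "mode": ["intermittent"] * 25 + ["continuous"] * 15,
            "icu": [True] * 10 + [False] * 30,
        })
        table = performance_table(records)
        overall = table[table["subgroup"] == "overall"].iloc[0]
        assert overall["n"] == n
        by_mode = table[table["subgroup"].isin(["intermittent", "continuous"])]
        assert by_mode["n"].sum() == n
        assert (table["rrmse"] >= 0).all()
        assert overall["rbias_lo"] <= overall["rbias"] <= overall["rbias_hi"]
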