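import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegretest import (
    ICCReliability,
    InsufficientDataError,
    ValidationError,
    anova_mean_squares,
    classify_reliability,
    icc_a1,
    icc_confidence_interval,
    pair_sessions,
    reliability_table,
)
from eegretest.tables import FEATURE_NAMES


def _matrix_strategy():
    return st.tuples(
        st.integers(3, 12), st.integers(2, 4), st.integers(0, 2**31 - 1)
    ).map(
        lambda t: np.random.default_rng(t[2]).normal(0, 1, (t[0], t[1]))
        + np.random.default_rng(t[2] + 1).normal(0, 1, (t[0], 1))
    )


class TestAnova:
    def test_pure_subject_variance(self):
        """[[1,1],[2,2],[3,3]]: all variance between subjects."""
        ms = anova_mean_squares([[1, 1], [2, 2], [3, 3]])
        assert ms.rms == pytest.approx(0.0)
        assert ms.ems == pytest.approx(0.0)
        assert ms.bms == pytest.approx(2.0)

    def test_pure_visit_shift(self):
        """[[1,2],[1,2],[1,2]]: all variance between visits."""
        ms = anova_mean_squares([[1, 2], [1, 2], [1, 2]])
        assert ms.bms == pytest.approx(0.0)
        assert ms.ems == pytest.approx(0.0)
        assert ms.rms == pytest.approx(1.5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(_matrix_strategy())
    def test_decomposition_identity(self, X):
        """(n-1)BMS + (k-1)RMS + (n-1)(k-1)EMS == total SS on any matrix."""
        n, k = X.shape
        ms = anova_mean_squares(X)
        total = ((X - X.mean()) ** 2).sum()
        recomposed = (
            (n - 1) * ms.bms + (k - 1) * ms.rms + (n - 1) * (k - 1) * ms.ems
        )
        assert recomposed == pytest.approx(total, rel=1e-10, abs=1e-12)

    def test_zero_variance_flagged_degenerate(self):
        ms = anova_mean_squares(np.full((4, 2), 3.0))
        assert ms.degenerate
        assert ms.bms == ms.rms == ms.ems == 0.0

    def test_too_small_design_rejected(self):
        with pytest.raises(InsufficientDataError):
            anova_mean_squares(np.zeros((1, 2)))

    def test_missing_cells_rejected(self):
        X = np.ones((3, 2))
        X[0, 1] = np.nan
        with pytest.raises(ValidationError):
            anova_mean_squares(X)


class TestICCEstimate:
    def test_perfect_agreement_is_one(self):
        assert icc_a1(anova_mean_squares([[1, 1], [2, 2], [3, 3]])) == pytest.approx(1.0)

    def test_visit_shift_and_disagreement_penalised(self):
        """Absolute agreement: visit offsets and residual noise pull the
        estimate to zero and below."""
        # pure visit shift, no subject or residual variance: the numerator
        # BMS - EMS is exactly 0, so the estimate is 0 by hand ANOVA
        est = icc_a1(anova_mean_squares([[1, 2], [1, 2], [1, 2]]))
        assert est == pytest.approx(0.0)
        # pure disagreement (no subject or visit variance): negative
        est_neg = icc_a1(anova_mean_squares([[0, 2], [2, 0], [1, 1]]))
        assert est_neg < 0.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(_matrix_strategy())
    def test_matches_variance_ratio_oracle(self, X):
        """Moment formula == brute-force ratio from the ANOVA identity."""
        n, k = X.shape
        ms = anova_mean_squares(X)
        # independent oracle: unbiased component estimates from expected
        # mean squares of the two-way random model, then the agreement ratio
        s2_r = (ms.bms - ms.ems) / k
        s2_c = (ms.rms - ms.ems) / n
        oracle = s2_r / (s2_r + s2_c + ms.ems)
        assert icc_a1(ms) == pytest.approx(oracle, rel=1e-10, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(_matrix_strategy(), st.floats(-5, 5), st.floats(0.1, 10))
    def test_affine_invariance(self, X, shift, scale):
        """ICC(A,1) unchanged by common shift and positive scaling."""
        a = icc_a1(anova_mean_squares(X))
        b = icc_a1(anova_mean_squares(scale * X + shift))
        assert a == pytest.approx(b, rel=1e-8, abs=1e-10)

    def test_single_column_offset_decreases_estimate(self, rng):
        X = rng.normal(0, 1, (20, 2)) + rng.normal(0, 2, (20, 1))
        base = icc_a1(anova_mean_squares(X))
        shifted = X.copy()
        shifted[:, 1] += 1.5
        assert icc_a1(anova_mean_squares(shifted)) < base

    def test_printed_variant_differs(self, rng):
        """The (k+1)EMS audit variant gives a strictly smaller estimate."""
        X = rng.normal(0, 1, (15, 2)) + rng.normal(0, 1, (15, 1))
        ms = anova_mean_squares(X)
        assert icc_a1(ms, formula="as-printed") < icc_a1(ms)
        with pytest.raises(ValidationError):
            icc_a1(ms, formula="bogus")

    def test_matches_pingouin_on_random_matrices(self, rng):
        pg = pytest.importorskip("pingouin")
        for _ in range(20):
            n, k = int(rng.integers(4, 20)), int(rng.integers(2, 5))
            X = rng.normal(0, 1, (n, k)) + rng.normal(0, 1.5, (n, 1))
            ms = anova_mean_squares(X)
            df = pd.DataFrame(
                {
                    "t": np.repeat(np.arange(n), k),
                    "r": np.tile(np.arange(k), n),
                    "y": X.ravel(),
                }
            )
            row = (
                pg.intraclass_corr(df, "t", "r", "y")
                .query("Type == 'ICC(A,1)'")
                .iloc[0]
            )
            assert icc_a1(ms) == pytest.approx(row.ICC, abs=1e-9)
            lo, hi = icc_confidence_interval(ms)
            assert lo == pytest.approx(row.CI95[0], abs=0.011)
            assert hi == pytest.approx(row.CI95[1], abs=0.011)


class TestConfidenceInterval:
    def test_perfect_agreement_tight(self):
        lo, hi = icc_confidence_interval(anova_mean_squares([[1, 1], [2, 2], [3, 3]]))
        assert lo > 0.99
        assert hi <= 1.0

    def test_degenerate_gives_uninformative_interval(self):
        ms = anova_mean_squares(np.full((4, 2), 1.0))
        assert icc_confidence_interval(ms) == (-1.0, 1.0)

    def test_interval_brackets_estimate(self, rng):
        for _ in range(30):
            X = rng.normal(0, 1, (10, 2)) + rng.normal(0, 1, (10, 1))
            ms = anova_mean_squares(X)
            lo, hi = icc_confidence_interval(ms)
            assert lo <= icc_a1(ms) <= hi

    def test_wider_at_smaller_n(self, rng):
        """Matched simulations: CI width at n=10 exceeds width at n=30."""
        widths = {}
        for n in (10, 30):
            w = []
            for _ in range(100):
                X = rng.normal(0, np.sqrt(0.15), (n, 2)) + rng.normal(
                    0, np.sqrt(0.85), (n, 1)
                )
                lo, hi = icc_confidence_interval(anova_mean_squares(X))
                w.append(hi - lo)
            widths[n] = np.mean(w)
        assert widths[10] > widths[30]


class TestClassification:
    @pytest.mark.parametrize(
        "estimate,expected",
        [
            (0.959, "excellent"),
            (0.9, "excellent"),
            (0.89, "good"),
            (0.75, "good"),
            (0.74, "moderate"),
            (0.5, "moderate"),
            (0.49, "poor"),
            (-0.2, "poor"),
            (1.0, "excellent"),
        ],
    )
    def test_boundaries_left_closed(self, estimate, expected):
        assert classify_reliability(estimate) == expected

    def test_above_one_invalid(self):
        with pytest.raises(ValidationError):
            classify_reliability(1.01)


def _study_tables(n_subjects=4, missing_second_visit=()):
    feats, sess = [], []
    rng = np.random.default_rng(9)
    for i in range(n_subjects):
        sid = f"sub{i:03d}"
        for j, interval in enumerate(("baseline", "same_day")):
            ses = f"ses{j+1:02d}"
            if interval == "same_day" and sid in missing_second_visit:
                continue
            sess.append(
                dict(subject_id=sid, session_id=ses,
                     session_datetime=f"2024-01-0{j+1}T09:00:00",
                     interval_label=interval)
            )
            for name in FEATURE_NAMES:
                value = 10.0 + 0.1 * i if name == "ipf" else rng.uniform(0.05, 0.2)
                feats.append(
                    dict(subject_id=sid, session_id=ses, feature_name=name, value=value)
                )
    return pd.DataFrame(feats), pd.DataFrame(sess)


class TestPairingAndTable:
    def test_listwise_deletion(self):
        feats, sess = _study_tables(3, missing_second_visit=("sub001",))
        paired = pair_sessions(feats, sess, "same_day")
        values, ids = paired["rbp_alpha"]
        assert values.shape == (2, 2)
        assert "sub001" not in ids

    def test_absent_interval_rejected(self):
        feats, sess = _study_tables(3)
        with pytest.raises(InsufficientDataError):
            pair_sessions(feats, sess, "6wk")

    def test_full_design_shape(self):
        feats, sess = _study_tables(30)
        paired = pair_sessions(feats, sess, "same_day")
        assert set(paired) == set(FEATURE_NAMES)
        assert all(v.shape == (30, 2) for v, _ in paired.values())

    def test_model_from_feature_table_fits(self):
        feats, sess = _study_tables(10)
        res = ICCReliability.from_feature_table(feats, sess, "ipf", "same_day").fit()
        assert res.n == 10 and res.k == 2
        assert res.ci_low <= res.estimate <= res.ci_high
        assert "ICC" in res.summary()

    def test_reliability_table_grid(self):
        feats, sess = _study_tables(6)
        table = reliability_table(feats, sess, intervals=("same_day",))
        assert len(table) == len(FEATURE_NAMES)
        assert set(table["feature"]) == set(FEATURE_NAMES)
        assert (table["n"] == 6).all()

    def test_empty_feature_table_rejected(self):
        feats, sess = _study_tables(3)
        empty = feats.iloc[0:0]
        with pytest.raises(InsufficientDataError):
            reliability_table(empty, sess, intervals=("same_day",))
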