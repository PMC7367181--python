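"""Strength estimation, rate prediction, the noise line, and matched comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crisprar.errors import (
    DegenerateFitError,
    IncompleteEstimationError,
    InsufficientDataError,
    NotAnActivatorError,
    NotARepressorError,
    SaturationWarning,
)
from crisprar.estimation import (
    LinearNoiseFit,
    NoisePoint,
    average_deviation,
    estimate_activation_strength,
    estimate_repression_strength,
    fit_noise_line,
    matched_mean_comparison,
    predict_construct_rates,
    predicted_summaries,
)
from crisprar.library import default_library
from crisprar.telegraph import CrisprParams, PromoterKinetics, apply_crisprar, mean_expression


def _forward_repression_fold(k_r: float) -> float:
    """Fold change of a saturated repressor under unit wild-type rates."""
    return ((1 - k_r) / (2 - k_r)) / 0.5


def _forward_activation_fold(k_a: float) -> float:
    """Fold change of a saturated activator under unit wild-type rates."""
    return (1 / (2 - k_a)) / 0.5


class TestStrengthEstimation:
    @pytest.mark.parametrize("fold,expected", [(1.0, 0.0), (0.5, 2 / 3), (1e-9, 1.0)])
    def test_repression_closed_form(self, fold, expected):
        assert estimate_repression_strength(fold) == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("fold,expected", [(1.0, 0.0), (2.0, 1.0), (4 / 3, 0.5)])
    def test_activation_closed_form(self, fold, expected):
        assert estimate_activation_strength(fold) == pytest.approx(expected, rel=1e-12)

    def test_wrong_direction_rejected(self):
        with pytest.raises(NotARepressorError):
            estimate_repression_strength(1.2)
        with pytest.raises(NotAnActivatorError):
            estimate_activation_strength(0.8)
        with pytest.raises(InsufficientDataError):
            estimate_repression_strength(0.0)

    def test_fold_beyond_model_ceiling_warns_and_clamps(self):
        with pytest.warns(SaturationWarning):
            assert estimate_activation_strength(2.5) == 1.0

    @given(k_r=st.floats(min_value=0, max_value=1 - 1e-9))
    @settings(max_examples=101, deadline=None)
    def test_repression_round_trip_identity(self, k_r):
        assert estimate_repression_strength(_forward_repression_fold(k_r)) == pytest.approx(
            k_r, abs=1e-12
        )

    @given(k_a=st.floats(min_value=0, max_value=1))
    @settings(max_examples=101, deadline=None)
    def test_activation_round_trip_identity(self, k_a):
        assert estimate_activation_strength(_forward_activation_fold(k_a)) == pytest.approx(
            k_a, abs=1e-12
        )

    def test_recovery_under_replicate_noise(self, rng):
        """5% multiplicative noise on n=6 fold replicates recovers strengths
        within 5% median relative error over 100 trials."""
        true = {"k_r": 0.85, "k_a": 0.7}
        errs = {"k_r": [], "k_a": []}
        for _ in range(100):
            noise = rng.lognormal(0, 0.05, size=6)
            f_r = _forward_repression_fold(true["k_r"]) * noise.mean()
            noise = rng.lognormal(0, 0.05, size=6)
            f_a = _forward_activation_fold(true["k_a"]) * noise.mean()
            errs["k_r"].append(
                abs(estimate_repression_strength(min(f_r, 1.0)) - true["k_r"]) / true["k_r"]
            )
            errs["k_a"].append(
                abs(estimate_activation_strength(max(f_a, 1.0)) - true["k_a"]) / true["k_a"]
            )
        assert np.median(errs["k_r"]) < 0.05
        assert np.median(errs["k_a"]) < 0.05


class TestPredictConstructRates:
    def test_null_regulation_returns_wild_type(self, wt, params):
        lib = default_library(regulation={"A1": 0.0, "A2": 0.0, "R2": 0.0, "R3": 0.0})
        kin, mean, noise = predict_construct_rates(lib[0], params, wt)
        assert (kin.k_on, kin.k_off) == (1.0, 1.0)
        assert mean == pytest.approx(wt.C / 2)
        assert noise == pytest.approx(2 / wt.C + 1 / 3)

    def test_same_strand_hand_arithmetic(self, wt, params):
        lib = default_library(regulation={"A1": 0.9, "A2": 0.9, "R2": 0.9, "R3": 0.9})
        # A1:pStr+R2:pStr -- same strand (both coding), equal promoters
        c = next(x for x in lib if x.construct_id == "A1:pStr+R2:pStr")
        kin, _, _ = predict_construct_rates(c, params, wt)
        K_r = 0.01 * (1 + 0.5 / 10)
        K_a = 0.02 * (1 + 0.5 / 10)
        assert kin.k_on == pytest.approx(1 - 0.9 * 0.5 / (K_r + 0.5), rel=1e-12)
        assert kin.k_off == pytest.approx(1 - 0.9 * 0.5 / (K_a + 0.5), rel=1e-12)

    def test_transcription_order_has_no_model_term(self, wt, params, library):
        by_pair = {}
        for c in library:
            by_pair.setdefault((c.act_module.key, c.rep_module.key), []).append(c)
        swapped = [v for v in by_pair.values() if len(v) == 2]
        assert swapped, "library should contain order-swapped duplicates"
        for pair in swapped:
            p0 = predict_construct_rates(pair[0], params, wt)
            p1 = predict_construct_rates(pair[1], params, wt)
            assert p0[1] == pytest.approx(p1[1])
            assert p0[2] == pytest.approx(p1[2])

    def test_missing_strength_rejected(self, wt, params):
        lib = default_library(regulation={})
        with pytest.raises(IncompleteEstimationError):
            predict_construct_rates(lib[0], params, wt)

    def test_predicted_summaries_table(self, wt, params, library):
        df = predicted_summaries(library, params, wt)
        assert len(df) == 48
        assert (df["mean"] > 0).all() and (df["noise"] > 0).all()
        assert np.allclose(df["inv_norm_mean"] * df["norm_mean"], 1.0)


class TestNoiseLine:
    def test_exact_line_recovered(self):
        pts = [NoisePoint(f"c{i}", x, 2 * x + 0.1) for i, x in enumerate((0.5, 1.0, 2.0, 4.0))]
        fit = fit_noise_line(pts)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.1)
        assert fit.r_squared == pytest.approx(1.0)

    def test_hand_computed_ols(self):
        # points (0,0),(1,1),(2,1): slope 1/2, intercept 1/6, R^2 = 3/4;
        # tiny positive offsets keep the points in the valid (positive) domain
        pts = [NoisePoint("a", 1e-9, 1e-9), NoisePoint("b", 1.0, 1.0), NoisePoint("c", 2.0, 1.0)]
        fit = fit_noise_line(pts)
        assert fit.slope == pytest.approx(0.5, abs=1e-6)
        assert fit.intercept == pytest.approx(1 / 6, abs=1e-6)
        assert fit.r_squared == pytest.approx(0.75, abs=1e-6)

    def test_matches_numpy_normal_equations(self, rng):
        x = rng.uniform(0.5, 5.0, size=12)
        y = 0.7 * x + 0.2 + rng.normal(0, 0.05, size=12)
        pts = [NoisePoint(f"c{i}", xi, yi) for i, (xi, yi) in enumerate(zip(x, y))]
        fit = fit_noise_line(pts)
        slope, intercept = np.polyfit(x, y, 1)
        assert fit.slope == pytest.approx(slope, rel=1e-9)
        assert fit.intercept == pytest.approx(intercept, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_noise_line([NoisePoint("a", 1, 1), NoisePoint("b", 2, 2)])
        with pytest.raises(DegenerateFitError):
            fit_noise_line([NoisePoint(c, 1.0, v) for c, v in zip("abc", (1.0, 2.0, 3.0))])


class TestAverageDeviation:
    def test_on_line_zero_everywhere(self):
        fit = LinearNoiseFit(slope=2.0, intercept=0.1, r_squared=1.0, n_points=3)
        pts = [NoisePoint("a", 1.0, 2.1, "low_expression"),
               NoisePoint("b", 2.0, 4.1, "high_expression")]
        d = average_deviation(pts, fit)
        assert d["low_expression"] == pytest.approx(0.0)
        assert d["high_expression"] == pytest.approx(0.0)

    def test_mean_absolute_residual(self):
        fit = LinearNoiseFit(slope=1.0, intercept=0.0, r_squared=1.0, n_points=3)
        pts = [NoisePoint("a", 1.0, 1.1, "low_expression"),
               NoisePoint("b", 2.0, 1.7, "low_expression")]
        assert average_deviation(pts, fit)["low_expression"] == pytest.approx(0.2)

    def test_empty_region_absent(self):
        fit = LinearNoiseFit(slope=1.0, intercept=0.0, r_squared=1.0, n_points=3)
        d = average_deviation([NoisePoint("a", 1.0, 1.0, "high_expression")], fit)
        assert "low_expression" not in d


class TestMatchedMeanComparison:
    def test_identical_groups_fully_matched(self):
        pts = [NoisePoint(f"c{i}", x, 0.5) for i, x in enumerate((0.5, 1.0, 2.0))]
        rep = matched_mean_comparison(pts, pts)
        assert rep.n_matched == 3
        assert rep.mean_noise_diff == pytest.approx(0.0)

    def test_tolerance_gate(self):
        a = [NoisePoint("a1", 0.50, 1.0), NoisePoint("a2", 0.80, 1.0)]
        b = [NoisePoint("b1", 0.52, 0.9), NoisePoint("b2", 1.00, 0.9)]
        rep = matched_mean_comparison(a, b, match_tolerance=0.03)
        assert rep.n_matched == 1
        assert list(rep.pairs["id_a"]) == ["a1"]

    def test_symmetric_up_to_sign(self):
        a = [NoisePoint(f"a{i}", x, n) for i, (x, n) in
             enumerate([(0.5, 1.2), (1.0, 1.5), (2.0, 2.0)])]
        b = [NoisePoint(f"b{i}", x, n) for i, (x, n) in
             enumerate([(0.51, 1.0), (1.02, 1.1), (1.99, 1.4)])]
        ab = matched_mean_comparison(a, b)
        ba = matched_mean_comparison(b, a)
        assert ab.n_matched == ba.n_matched == 3
        assert ab.mean_noise_diff == pytest.approx(-ba.mean_noise_diff)
        assert ab.f_statistic == pytest.approx(ba.f_statistic, rel=1e-9)

    def test_no_overlap_signal(self):
        rep = matched_mean_comparison(
            [NoisePoint("a", 0.5, 1.0)], [NoisePoint("b", 5.0, 1.0)]
        )
        assert rep.n_matched == 0
        assert np.isnan(rep.mean_noise_diff)
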