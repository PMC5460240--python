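"""Exposure metrics, RMSE measures, cohort statistics and histology scoring."""

import itertools

import numpy as np
import pytest

from translearn.evalstats import (
    NasComponents,
    nas_score,
    nca,
    normalized_rmse,
    pearson_correlation,
    two_sample_t,
    weighted_rmse,
)
from translearn.pbpk.types import ConcentrationProfile, ValidationError


def _profile(times, conc, compound="c", iid="i1"):
    return ConcentrationProfile(iid, compound, np.asarray(times, float),
                                np.asarray(conc, float))


class TestNca:
    def test_triangle_profile(self):
        out = nca(_profile([0, 1, 2], [0, 2, 0]))
        assert out["cmax"] == 2.0
        assert out["tmax"] == 1.0
        assert out["auc_0_t"] == pytest.approx(2.0)

    def test_constant_profile_auc(self):
        out = nca(_profile([0, 1, 2, 5], [3, 3, 3, 3]))
        assert out["auc_0_t"] == pytest.approx(3.0 * 5.0)

    def test_tmax_earliest_on_ties(self):
        out = nca(_profile([0, 1, 2, 3], [0, 5, 5, 1]))
        assert out["tmax"] == 1.0

    def test_weight_normalization(self):
        out = nca(_profile([0, 1, 2], [0, 2, 0]), body_weight=80.0)
        assert out["auc_per_kg"] == pytest.approx(2.0 / 80.0)
        assert out["cmax_per_kg"] == pytest.approx(2.0 / 80.0)

    def test_trapezoid_matches_analytic_exposure_on_dense_grid(self):
        # one-compartment bolus: AUC(0..T) = D/CL · (1 - e^(-kT))
        dose, volume, clearance = 100.0, 10.0, 2.0
        k = clearance / volume
        t = np.linspace(0, 24, 2000)
        c = dose / volume * np.exp(-k * t)
        out = nca(_profile(t, c))
        analytic = dose / clearance * (1 - np.exp(-k * 24))
        assert out["auc_0_t"] == pytest.approx(analytic, rel=0.02)

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValidationError, match="increasing"):
            _profile([0, 2, 1], [1, 1, 1])

    def test_single_point_rejected(self):
        with pytest.raises(ValidationError):
            nca(_profile([1.0], [1.0]))

    def test_auc_additive_over_contiguous_intervals(self):
        t = np.array([0.0, 0.7, 1.3, 2.0, 3.5, 5.0])
        c = np.array([0.0, 2.0, 1.7, 1.2, 0.6, 0.2])
        whole = nca(_profile(t, c))["auc_0_t"]
        left = nca(_profile(t[:4], c[:4]))["auc_0_t"]
        right = nca(_profile(t[3:], c[3:]))["auc_0_t"]
        assert whole == pytest.approx(left + right, rel=1e-12)


class TestWeightedRmse:
    def test_perfect_fit_scores_zero(self):
        assert weighted_rmse(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0

    def test_hand_computed_relative_value(self):
        value = weighted_rmse(np.array([2.0, 2.0]), np.array([1.0, 2.0]))
        assert value == pytest.approx(np.sqrt(0.5), rel=1e-12)  # 0.7071

    def test_relative_weighting_scale_invariant(self):
        sim = np.array([1.2, 2.8, 4.1])
        obs = np.array([1.0, 3.0, 4.0])
        assert weighted_rmse(10 * sim, 10 * obs) == pytest.approx(
            weighted_rmse(sim, obs), rel=1e-12
        )

    def test_zero_observation_switches_to_additive_weight(self):
        value = weighted_rmse(np.array([0.5, 2.0]), np.array([0.0, 2.0]))
        assert value == pytest.approx(np.sqrt(0.5**2 / 2))


class TestNormalizedRmse:
    def _datasets(self):
        t = np.array([0.5, 1, 2, 4])
        return [
            _profile(t, [1.0, 2.0, 1.5, 0.8], iid="a"),
            _profile(t, [1.2, 1.8, 1.4, 0.9], iid="b"),
        ], t

    def test_reference_scores_exactly_one(self):
        datasets, t = self._datasets()
        ref = np.array([1.1, 1.9, 1.45, 0.85])
        assert normalized_rmse(ref, datasets, ref, t) == 1.0

    def test_interpolating_curve_scores_zero(self):
        t = np.array([0.5, 1, 2, 4])
        data = [_profile(t, [1.0, 2.0, 1.5, 0.8])]
        ref = np.array([2.0, 3.0, 2.0, 1.0])
        assert normalized_rmse(np.array([1.0, 2.0, 1.5, 0.8]), data, ref, t) == 0.0

    def test_zero_reference_rmse_is_an_error(self):
        t = np.array([0.5, 1, 2, 4])
        obs = np.array([1.0, 2.0, 1.5, 0.8])
        data = [_profile(t, obs)]
        with pytest.raises(ValidationError, match="undefined"):
            normalized_rmse(obs * 1.1, data, obs, t)

    def test_grid_mismatch_rejected(self):
        datasets, t = self._datasets()
        with pytest.raises(ValidationError, match="grid"):
            normalized_rmse(np.ones(3), datasets, np.ones(3), np.array([1.0, 2, 3]))


class TestCohortStatistics:
    def test_perfect_linear_relation(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert pearson_correlation(x, 2 * x)["r"] == pytest.approx(1.0)
        assert pearson_correlation(x, -x + 7)["r"] == pytest.approx(-1.0)

    def test_matches_brute_force_covariance_formula(self):
        x = np.array([1.2, 3.4, 2.2, 5.0, 4.1])
        y = np.array([0.9, 2.8, 2.5, 4.4, 3.3])
        r_brute = (np.sum((x - x.mean()) * (y - y.mean()))
                   / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        assert pearson_correlation(x, y)["r"] == pytest.approx(r_brute, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_identical_samples_not_significant(self):
        a = np.array([1.0, 2.0, 3.0, 2.5])
        out = two_sample_t(a, a.copy())
        assert out["t"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)
        assert not out["significant"]

    def test_swapping_samples_negates_t(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1.2, 25)
        ab, ba = two_sample_t(a, b), two_sample_t(b, a)
        assert ab["t"] == pytest.approx(-ba["t"])
        assert ab["p"] == pytest.approx(ba["p"])

    def test_separated_samples_significant(self):
        rng = np.random.default_rng(1)
        out = two_sample_t(rng.normal(0, 1, 200), rng.normal(2, 1, 200))
        assert out["significant"]
        assert out["p"] < 1e-10


class TestNasScore:
    def test_category_examples(self):
        assert nas_score(NasComponents(3, 1, 1)) == {"score": 5, "category": "NASH"}
        assert nas_score(NasComponents(2, 1, 0)) == {
            "score": 3, "category": "mild steatosis"
        }
        assert nas_score(NasComponents(0, 0, 0)) == {"score": 0, "category": "not NASH"}

    def test_out_of_range_grades_rejected(self):
        with pytest.raises(ValidationError):
            NasComponents(4, 0, 0)
        with pytest.raises(ValidationError):
            NasComponents(0, 0, 3)
        with pytest.raises(ValidationError):
            NasComponents(-1, 0, 0)

    def test_exhaustive_categories_consistent_and_exclusive(self):
        """All 4·4·3 = 48 valid grade triples classify by the published
        thresholds with no gaps or overlaps."""
        seen = 0
        for s, li, b in itertools.product(range(4), range(4), range(3)):
            out = nas_score(NasComponents(s, li, b))
            total = s + li + b
            expected = ("NASH" if total >= 5
                        else "mild steatosis" if total >= 3 else "not NASH")
            assert out["score"] == total
            assert out["category"] == expected
            seen += 1
        assert seen == 48
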