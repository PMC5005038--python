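"""Angular errors, chance testing, behavioral controls and visual features."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hexdir import behavior
from hexdir.behavior import (
    accuracy_correlations,
    angular_error,
    chance_performance_test,
    combined_error_contrast,
    image_feature_similarity,
    make_view_image,
    map_test_score,
    visual_similarity_tests,
)


class TestAngularError:
    @pytest.mark.parametrize(
        "a,b,expected", [(350, 10, 20), (90, 90, 0), (0, 180, 180), (30, 330, 60)]
    )
    def test_known_values(self, a, b, expected):
        assert angular_error(a, b) == pytest.approx(expected)

    @settings(max_examples=200, deadline=None)
    @given(a=st.floats(0, 720, allow_nan=False), b=st.floats(0, 720, allow_nan=False))
    def test_symmetric_bounded_and_wrap_invariant(self, a, b):
        e = angular_error(a, b)
        assert 0 <= e <= 180
        assert np.isclose(e, angular_error(b, a))
        assert np.isclose(e, angular_error(a + 360, b), atol=1e-9)


class TestChanceTest:
    def test_uniform_responder_excluded(self, rng):
        errors = rng.uniform(0, 180, size=96)
        res = chance_performance_test(errors)
        assert not res.below_chance

    def test_accurate_responder_included(self):
        res = chance_performance_test(np.full(96, 5.0) + np.arange(96) * 0.01)
        assert res.below_chance

    def test_exactly_at_chance_is_degenerate(self):
        res = chance_performance_test(np.full(20, 90.0))
        assert res.degenerate and not res.below_chance

    def test_minimum_sample(self):
        with pytest.raises(ValueError):
            chance_performance_test([10, 20])


class TestCombinedError:
    def test_pair_product(self, labels):
        errors = np.zeros(96)
        errors[labels.i.iloc[0]] = 10.0
        errors[labels.j.iloc[0]] = 20.0
        # the single nonzero product lands in that pair's condition
        c = combined_error_contrast(errors, labels)
        pair_rem = labels.rem60.iloc[0]
        assert (c > 0) == (pair_rem == 0)
        assert abs(c) == pytest.approx(
            200.0 / (labels.rem60 == pair_rem).sum(), rel=1e-12
        )

    def test_all_zero_errors(self, labels):
        assert combined_error_contrast(np.zeros(96), labels) == 0.0

    def test_direction_independent_errors_have_zero_expectation(self, labels):
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(400):
            errors = rng.uniform(0, 180, size=96)
            vals.append(combined_error_contrast(errors, labels))
        m = np.mean(vals)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(m) < 4 * se + 1e-6

    def test_missing_responses_dropped(self, labels):
        errors = np.full(96, 30.0)
        errors[:5] = np.nan
        assert np.isfinite(combined_error_contrast(errors, labels))


class TestAccuracyCorrelations:
    def test_perfect_and_chance_accuracy_levels(self):
        # accuracy = pi - mean error (radians): perfect -> pi, chance -> pi/2
        assert np.pi - np.deg2rad(0.0) == pytest.approx(np.pi)
        assert np.pi - np.deg2rad(90.0) == pytest.approx(np.pi / 2)

    def test_latent_factor_recovered(self, rng):
        n = 24
        skill = rng.normal(size=n)
        df = pd.DataFrame(
            {
                "mean_error_deg": 60 - 20 * skill + rng.normal(0, 4, n),
                "buildings_found": 30 + 5 * skill + rng.normal(0, 1, n),
                "training_error_deg": 40 - 10 * skill + rng.normal(0, 2, n),
                "training_time": rng.normal(80, 5, n),
            }
        )
        rep = accuracy_correlations(df)
        found = rep.set_index("covariate")
        assert found.loc["buildings_found", "r"] > 0.7
        assert found.loc["training_error_deg", "r"] < -0.7
        assert found.loc["buildings_found", "partial_r"] > 0.7

    def test_zero_variance_covariate_errors(self):
        df = pd.DataFrame(
            {"mean_error_deg": [30.0, 40.0, 50.0], "flat": [1.0, 1.0, 1.0]}
        )
        with pytest.raises(ValueError):
            accuracy_correlations(df, control=None)


class TestMapTest:
    def test_distances(self):
        assert map_test_score([0, 0], [3, 4])[0] == pytest.approx(5.0)
        assert map_test_score([2, 2], [2, 2])[0] == 0.0

    def test_zscored_scores_standardised(self, rng):
        scores = rng.uniform(0, 10, size=24)
        z = (scores - scores.mean()) / scores.std(ddof=0)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=0) == pytest.approx(1.0)


class TestImageFeatures:
    def test_identical_images_fully_correlated(self):
        im = make_view_image((1.0, 0.0), 90.0)
        tab = image_feature_similarity([im, im.copy()])
        for name in ("fft_magnitude", "fft_phase", "L", "a", "b"):
            val = tab[name].iloc[0]
            assert np.isnan(val) or val > 15.0  # capped z for r = 1

    def test_luminance_inversion_anticorrelates_L(self):
        # RGB inversion flips luminance up to the nonlinearity of the
        # sRGB -> CIELAB transform, so the L correlation is near (not at) -1
        im = make_view_image((0.0, 1.0), 0.0)
        neg = 1.0 - im
        tab = image_feature_similarity([im, neg])
        assert np.tanh(tab["L"].iloc[0]) < -0.9

    def test_circular_shift_preserves_magnitude_not_phase(self):
        im = make_view_image((1.0, 0.0), 30.0)
        shifted = np.roll(im, 13, axis=1)
        tab = image_feature_similarity([im, shifted])
        assert np.tanh(tab["fft_magnitude"].iloc[0]) > 0.999
        assert np.tanh(tab["fft_phase"].iloc[0]) < 0.9

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            image_feature_similarity(
                [np.zeros((8, 8, 3)), np.zeros((9, 8, 3))]
            )


class TestVisualSimilarityTests:
    def _labels(self, directions, starts):
        n = len(directions)
        i, j = np.triu_indices(n, k=1)
        th = np.asarray(directions, float)
        d = np.abs(th[i] - th[j]) % 360
        d = np.minimum(d, 360 - d)
        s = np.asarray(starts)
        return pd.DataFrame(
            {"i": i, "j": j, "delta_deg": d.astype(int),
             "same_start": s[i] == s[j]}
        )

    def test_identical_features_nothing_significant(self):
        labels = self._labels([0, 30, 90, 180], [1, 2, 3, 4])
        feat = pd.DataFrame(
            {"i": labels.i, "j": labels.j,
             **{k: 0.5 for k in behavior.FEATURE_NAMES}}
        )
        rep = visual_similarity_tests(feat, labels)
        assert not rep.lower_for_similar.any()

    def test_planted_lower_similarity_detected(self, rng):
        directions = list(range(0, 360, 30)) * 4
        starts = rng.integers(0, 6, size=len(directions))
        labels = self._labels(directions, starts)
        d = labels.delta_deg.to_numpy()
        sim = (d <= 30) & ~labels.same_start.to_numpy()
        feat = {k: rng.normal(0.5, 0.05, size=len(labels)) for k in behavior.FEATURE_NAMES}
        feat["fft_phase"] = feat["fft_phase"] - 0.2 * sim
        feat_df = pd.DataFrame({"i": labels.i, "j": labels.j, **feat})
        rep = visual_similarity_tests(feat_df, labels).set_index("dimension")
        assert rep.loc["fft_phase", "lower_for_similar"]
        assert not rep.loc["L", "lower_for_similar"]
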