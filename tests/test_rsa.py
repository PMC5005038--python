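"""Pairwise similarity, condition contrasts, filters and distance controls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hexdir import rsa
from hexdir.rsa import (
    ContrastError,
    ContrastSpec,
    Z_CAP,
    condition_contrast,
    filter_pairs,
    pairwise_similarity,
    residualize_distance,
    similarity_matrix,
)


def _labels_for_directions(directions):
    n = len(directions)
    i, j = np.triu_indices(n, k=1)
    th = np.asarray(directions, float)
    d = np.abs(th[i] - th[j]) % 360
    d = np.minimum(d, 360 - d).astype(int)
    card = np.isin(th, (0, 90, 180, 270))
    false = np.zeros(len(i), bool)
    return pd.DataFrame(
        {
            "i": i, "j": j, "delta_deg": d, "rem60": d % 60, "rem90": d % 90,
            "same_start": false, "same_target": false, "same_combo": false,
            "same_block": false, "both_inner_target": false,
            "both_cardinal": card[i] & card[j], "both_ns_street": false,
            "dist_mean": np.ones(len(i)), "dist_absdiff": np.zeros(len(i)),
            "dist_neighborhood": np.ones(len(i)),
        }
    )


def _sim_from_z(z_by_pair, labels):
    z = np.asarray(z_by_pair, float)
    return pd.DataFrame(
        {
            "i": labels.i, "j": labels.j, "r": np.tanh(z), "z": z,
            "valid": np.ones(len(z), bool), "capped": np.zeros(len(z), bool),
        }
    )


class TestPairwiseSimilarity:
    def test_matches_bruteforce_pearson(self, rng):
        pats = rng.normal(size=(10, 7))
        sim = pairwise_similarity(pats)
        for row in sim.itertuples(index=False):
            r_ref = stats.pearsonr(pats[row.i], pats[row.j]).statistic
            assert row.r == pytest.approx(r_ref, abs=1e-12)
            assert row.z == pytest.approx(np.arctanh(r_ref), abs=1e-9)

    def test_identical_patterns_capped(self, rng):
        p = rng.normal(size=6)
        sim = pairwise_similarity(np.stack([p, p]))
        assert sim.capped.all()
        assert sim.z.iloc[0] == pytest.approx(Z_CAP)

    def test_orthogonal_centered_patterns_zero(self):
        sim = pairwise_similarity(np.array([[1.0, -1.0, 1.0, -1.0],
                                            [1.0, 1.0, -1.0, -1.0]]))
        assert sim.z.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_flagged_invalid(self, rng):
        pats = np.vstack([np.full(5, 2.0), rng.normal(size=(2, 5))])
        sim = pairwise_similarity(pats)
        bad = sim[(sim.i == 0) | (sim.j == 0)]
        assert (~bad.valid).all() and bad.z.isna().all()

    def test_affine_invariance_per_trial(self, rng):
        pats = rng.normal(size=(8, 12))
        gains = rng.uniform(0.5, 2.0, size=8)[:, None]
        offsets = rng.normal(size=8)[:, None]
        a = pairwise_similarity(pats)
        b = pairwise_similarity(gains * pats + offsets)
        assert np.allclose(a.z, b.z, atol=1e-10)

    def test_too_few_voxels(self):
        with pytest.raises(ValueError):
            pairwise_similarity(np.ones((3, 1)))


class TestConditionContrast:
    def test_hand_enumerated_mod60_example(self):
        labels = _labels_for_directions([0, 60, 30, 90])
        z = []
        for row in labels.itertuples(index=False):
            pair = {row.i, row.j}
            if pair == {0, 1}:
                z.append(0.5)
            elif pair == {2, 3}:
                z.append(0.3)
            else:
                z.append(0.1)
        res = condition_contrast(_sim_from_z(z, labels), labels, ContrastSpec("mod60"))
        assert res.difference == pytest.approx(0.3)
        assert (res.n_a, res.n_b) == (2, 4)

    @pytest.mark.parametrize("scheme", ["onefold", "mod60", "mod90", "cardinal"])
    def test_equal_z_gives_zero_for_every_scheme(self, scheme):
        labels = _labels_for_directions(list(range(0, 360, 30)))
        sim = _sim_from_z(np.full(len(labels), 0.37), labels)
        res = condition_contrast(sim, labels, ContrastSpec(scheme))
        assert res.difference == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry_under_condition_swap(self):
        labels = _labels_for_directions(list(range(0, 360, 30)) * 2)
        rng = np.random.default_rng(0)
        sim = _sim_from_z(rng.normal(size=len(labels)), labels)
        res = condition_contrast(sim, labels, ContrastSpec("mod60"))
        flipped = labels.assign(rem60=30 - labels.rem60)
        res_f = condition_contrast(sim, flipped, ContrastSpec("mod60"))
        assert res_f.difference == pytest.approx(-res.difference)

    def test_noiseless_sixfold_reaches_cap_extremes(self, trials):
        from hexdir.cohort import SignalModel, simulate_trial_patterns

        model = SignalModel(kind="grid", grid_orientation_deg=0.0, noise_sd=0.0,
                            baseline_sd=0.0, grid_amp_sd=1.0)
        pats = simulate_trial_patterns(trials, model, 24, seed=0)
        sim = pairwise_similarity(pats)
        from hexdir.city import label_pairs, build_city_layout
        labels = label_pairs(trials, build_city_layout())
        res = condition_contrast(sim, labels, ContrastSpec("mod60"))
        assert res.difference == pytest.approx(2 * Z_CAP, rel=1e-12)

    def test_empty_condition_errors(self):
        labels = _labels_for_directions([0, 0, 0])
        sim = _sim_from_z([0.1, 0.1, 0.1], labels)
        with pytest.raises(ContrastError):
            condition_contrast(sim, labels, ContrastSpec("mod60"))


class TestFilters:
    def test_same_block_count_on_design(self, labels):
        keep = filter_pairs(labels, ["same_block"])
        assert keep.sum() == 4560 - 4 * (24 * 23 // 2)

    def test_inner_target_exclusion_only_hits_zero_condition(self, labels):
        keep = filter_pairs(labels, ["inner_target"])
        lost_a = ((labels.rem60 == 0) & ~keep).sum()
        lost_b = ((labels.rem60 == 30) & ~keep).sum()
        assert (lost_a, lost_b) == (276, 0)

    def test_empty_exclusion_is_identity(self, labels):
        assert filter_pairs(labels, []).all()

    def test_unknown_name(self, labels):
        with pytest.raises(ContrastError, match="bogus"):
            filter_pairs(labels, ["bogus"])


class TestDistanceResidualization:
    @pytest.fixture()
    def sim_and_labels(self, trials, labels, rng):
        z = rng.normal(0.2, 0.1, size=len(labels))
        return _sim_from_z(z, labels), labels

    def test_constant_predictor_preserves_contrast(self, sim_and_labels):
        sim, labels = sim_and_labels
        const = labels.assign(dist_mean=np.ones(len(labels)))
        out = residualize_distance(sim, const, "mean")
        before = condition_contrast(sim, labels, ContrastSpec("mod60")).difference
        after = condition_contrast(out, labels, ContrastSpec("mod60")).difference
        assert after == pytest.approx(before, abs=1e-12)
        assert np.allclose(out.z, sim.z - sim.z.mean(), atol=1e-12)

    def test_predictor_equal_to_z_zeroes_everything(self, sim_and_labels):
        sim, labels = sim_and_labels
        rigged = labels.assign(dist_mean=sim.z.to_numpy())
        out = residualize_distance(sim, rigged, "mean")
        assert np.max(np.abs(out.z)) < 1e-10

    def test_frisch_waugh_orthogonal_predictor(self, sim_and_labels, rng):
        sim, labels = sim_and_labels
        a = (labels.rem60 == 0).to_numpy(float)
        x = rng.normal(size=len(labels))
        # jointly orthogonalise to span{intercept, condition indicator}
        for basis in (np.ones_like(a), a - a.mean()):
            x = x - (x @ basis) / (basis @ basis) * basis
        rigged = labels.assign(dist_mean=x)
        out = residualize_distance(sim, rigged, "mean")
        before = condition_contrast(sim, labels, ContrastSpec("mod60")).difference
        after = condition_contrast(out, labels, ContrastSpec("mod60")).difference
        assert after == pytest.approx(before, abs=1e-6)

    def test_binary_split_and_constant_error(self, sim_and_labels):
        sim, labels = sim_and_labels
        out = residualize_distance(sim, labels, "neighborhood", binary=True)
        assert np.isfinite(out.z).all()
        with pytest.raises(ContrastError):
            residualize_distance(sim, labels.assign(dist_mean=1.0), "mean", binary=True)

    def test_unknown_measure(self, sim_and_labels):
        sim, labels = sim_and_labels
        with pytest.raises(ContrastError):
            residualize_distance(sim, labels, "hamming")
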