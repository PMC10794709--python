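"""Neural RDMs, RDM regression, searchlight, delay windows."""

import numpy as np
import pytest

from calcmvpa.design import PREDICTOR_NAMES
from calcmvpa.glm import FIRModel
from calcmvpa.rsa import (RDMRegression, RSAEffects, neural_rdm, rdm_regression,
                          roi_rsa, searchlight_rsa, sphere_offsets, window_average)
from calcmvpa.scenarios import rsa_recovery_model
from calcmvpa.simulate import NoiseModel, make_voxel_population, simulate_subject_runs


def zscore(v):
    return (v - v.mean()) / v.std()


def normal_equations_betas(X, y):
    """Oracle: explicit (X'X)^-1 X'y with intercept, both sides z-scored."""
    Xz = np.column_stack([np.ones(len(y))] + [zscore(X[:, j]) for j in range(X.shape[1])])
    yz = zscore(y)
    return np.linalg.solve(Xz.T @ Xz, Xz.T @ yz)


class TestNeuralRDM:
    def test_identical_patterns_distance_zero(self):
        p = np.random.default_rng(0).standard_normal(20)
        patterns = np.vstack([p, p, p + 1])  # third differs only by a constant
        rdm = neural_rdm(patterns)
        assert rdm.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_negated_centered_pattern_distance_two(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(30)
        patterns = np.vstack([base, -base])
        rdm = neural_rdm(patterns)
        assert rdm.matrix[0, 1] == pytest.approx(2.0)

    def test_orthogonal_centered_patterns_distance_one(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        patterns = np.vstack([a, b, -a])  # mean across conditions: a/3... not zero
        # remove the condition mean contribution by construction: use pairs whose
        # across-condition mean is zero for every voxel
        patterns = np.vstack([a, b, -a, -b])
        rdm = neural_rdm(patterns)
        assert rdm.matrix[0, 1] == pytest.approx(1.0)

    def test_entries_within_zero_two(self):
        rng = np.random.default_rng(2)
        rdm = neural_rdm(rng.standard_normal((10, 25)))
        off = rdm.matrix[~np.eye(10, dtype=bool)]
        assert np.all((off >= 0) & (off <= 2))
        assert np.allclose(rdm.matrix, rdm.matrix.T)

    def test_degenerate_pattern_flagged_missing(self):
        patterns = np.ones((3, 5))
        patterns[0] = [1, 2, 3, 4, 5]
        patterns[1] = [2, 4, 6, 8, 10]
        # condition 2 equals the mean pattern after centering -> zero variance
        rdm = neural_rdm(np.vstack([patterns[0], patterns[0], patterns[0]]))
        assert rdm.has_missing


class TestRDMRegression:
    def test_matches_normal_equations_oracle(self, predictors):
        """Betas equal the closed-form solve on the 45-pair design."""
        X = predictors.stacked(PREDICTOR_NAMES)
        y = zscore(X[:, 0])  # neural vector equal to z-scored sample predictor
        res = RDMRegression(y, predictors).fit()
        ref = normal_equations_betas(X, y)
        assert res.rsquared == pytest.approx(1.0, abs=1e-10)
        for j, name in enumerate(PREDICTOR_NAMES):
            assert res.betas[name] == pytest.approx(ref[j + 1], abs=1e-10)

    @pytest.mark.parametrize("target", PREDICTOR_NAMES)
    def test_oracle_equivalence_all_targets(self, predictors, target):
        X = predictors.stacked(PREDICTOR_NAMES)
        rng = np.random.default_rng(5)
        y = 0.6 * zscore(X[:, PREDICTOR_NAMES.index(target)]) + 0.1 * rng.standard_normal(45)
        res = RDMRegression(y, predictors).fit()
        ref = normal_equations_betas(X, y)
        for j, name in enumerate(PREDICTOR_NAMES):
            assert res.betas[name] == pytest.approx(ref[j + 1], abs=1e-10)

    def test_null_neural_vectors_give_zero_mean_betas(self, predictors):
        rng = np.random.default_rng(0)
        betas = np.array([RDMRegression(rng.standard_normal(45), predictors)
                          .fit().beta_array() for _ in range(1000)])
        assert np.all(np.abs(betas.mean(axis=0)) < 0.02)

    def test_scale_equivariance(self, predictors):
        X = predictors.stacked(PREDICTOR_NAMES)
        y = 0.3 * zscore(X[:, 0]) + 0.5 * zscore(X[:, 3]) + 0.05
        r1 = RDMRegression(y, predictors).fit()
        r2 = RDMRegression(7.3 * y, predictors).fit()
        ratio1 = r1.betas["sample"] / r1.betas["result"]
        ratio2 = r2.betas["sample"] / r2.betas["result"]
        assert ratio1 == pytest.approx(ratio2)

    def test_singular_predictors_rejected(self, conditions, predictors):
        from calcmvpa.design import PredictorSet

        mats = {k: v.copy() for k, v in predictors.matrices.items()}
        mats["operand"] = mats["operation"]
        broken = PredictorSet(conditions, mats)
        with pytest.raises(ValueError, match="collinear|singular"):
            RDMRegression(np.arange(45.0), broken)

    def test_missing_entries_rejected(self, predictors):
        rdm = neural_rdm(np.vstack([np.ones(5)] * 10))
        with pytest.raises(ValueError, match="missing"):
            RDMRegression(rdm, predictors)


class TestSearchlight:
    def test_interior_sphere_has_123_voxels(self):
        """Radius-3 sphere size by independent lattice enumeration."""
        count = sum(1 for x in range(-3, 4) for y in range(-3, 4) for z in range(-3, 4)
                    if x * x + y * y + z * z <= 9)
        assert count == 123
        assert sphere_offsets(3).shape[0] == count

    def test_corner_neighborhood_is_truncated(self, predictors):
        betas = _random_betas(8)
        res = searchlight_rsa(betas, np.ones((8, 8, 8), bool), predictors,
                              radius_voxels=3, bins=[1])
        # count in-mask neighbours at the corner
        off = sphere_offsets(3)
        nb = off + np.array([0, 0, 0])
        inside = ((nb >= 0) & (nb < 8)).all(axis=1)
        assert inside.sum() < 123
        assert np.isfinite(res.beta_maps[0, 0, 0, 0, 0])

    def test_matches_brute_force_loop(self, predictors):
        """Searchlight map equals an independent per-center loop on 8x8x8."""
        betas = _random_betas(8)
        mask = np.ones((8, 8, 8), bool)
        res = searchlight_rsa(betas, mask, predictors, radius_voxels=3, bins=[2])
        lin = np.arange(512).reshape(8, 8, 8)
        rng_centers = [(1, 1, 1), (4, 4, 4), (7, 0, 3), (2, 6, 5)]
        for cx, cy, cz in rng_centers:
            vox = []
            for x in range(8):
                for y in range(8):
                    for z in range(8):
                        if (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= 9:
                            vox.append(lin[x, y, z])
            ref = RDMRegression(neural_rdm(betas.patterns(2)[:, vox]), predictors).fit()
            for pi, name in enumerate(PREDICTOR_NAMES):
                assert res.beta_maps[pi, 0, cx, cy, cz] == pytest.approx(
                    ref.betas[name], abs=1e-10)

    def test_localizes_embedded_code(self, spec, predictors):
        """Group-mean sample-code betas peak at the embedded coding region."""
        grid = (12, 12, 12)
        active = np.zeros(grid, bool)
        active[3:10, 3:10, 3:10] = True  # coding cube centred at (6, 6, 6)
        maps = []
        for seed in range(6):
            model = make_voxel_population(12 ** 3, 0.0, seed=seed,
                                          active=active.ravel(),
                                          amplitudes={"sample": 0.5, "result": 0.0,
                                                      "operation": 0.0, "operand": 0.0})
            runs = simulate_subject_runs(spec, model, NoiseModel(sigma=1.0),
                                         seed=seed + 10, n_runs=4)
            fir = FIRModel(runs, spec).fit()
            res = searchlight_rsa(fir, np.ones(grid, bool), predictors, bins=[3, 4])
            maps.append(np.nanmean(res.beta_maps[0], axis=0))
        gmap = np.mean(maps, axis=0)
        peak = np.unravel_index(np.nanargmax(gmap), grid)
        assert np.max(np.abs(np.array(peak) - 6)) <= 1  # within 1 voxel per axis

    def test_empty_mask_rejected(self, predictors):
        with pytest.raises(ValueError, match="empty"):
            searchlight_rsa(_random_betas(4), np.zeros((4, 4, 4), bool), predictors)


def _random_betas(side):
    from calcmvpa.glm import FIRResults

    rng = np.random.default_rng(42)
    est = rng.standard_normal((10, 10, side ** 3))
    return FIRResults(est, [f"c{i}" for i in range(10)], "concatenated")


class TestWindows:
    def test_constant_betas(self):
        eff = RSAEffects(np.full((6, 4), 3.25), bins=list(range(1, 7)))
        wm = window_average(eff)
        for w in ("early", "middle", "late"):
            assert all(v == pytest.approx(3.25) for v in wm[w].values())

    def test_bin_index_betas(self):
        eff = RSAEffects(np.tile(np.arange(1.0, 7.0)[:, None], (1, 4)),
                         bins=list(range(1, 7)))
        wm = window_average(eff)
        assert wm["early"]["sample"] == pytest.approx(1.5)
        assert wm["middle"]["sample"] == pytest.approx(3.5)
        assert wm["late"]["sample"] == pytest.approx(5.5)

    def test_missing_bin_rejected(self):
        eff = RSAEffects(np.zeros((3, 4)), bins=[1, 2, 3])
        with pytest.raises(ValueError, match="missing"):
            window_average(eff)

    def test_sample_code_strongest_in_middle_window(self, spec, predictors):
        """Group mean sample beta: middle > early for a mid-envelope code."""
        mids, earlies = [], []
        for seed in range(5):
            model = rsa_recovery_model(60, seed=seed)
            runs = simulate_subject_runs(spec, model, NoiseModel(), seed=seed + 100)
            fir = FIRModel(runs, spec).fit()
            wm = window_average(roi_rsa(fir, predictors, bins=list(range(1, 7))))
            mids.append(wm["middle"]["sample"])
            earlies.append(wm["early"]["sample"])
        assert np.mean(mids) > np.mean(earlies)
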