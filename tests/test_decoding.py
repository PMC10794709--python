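"""SVR numerosity decoding, temporal generalization, window rule."""

import numpy as np
import pytest

from calcmvpa.decoding import (DecoderSpec, GeneralizationMatrix,
                               cross_decoding_score, fisher_z,
                               fit_predict_numerosity, generalization_matrix,
                               numerosity_labels, valid_cross_cells)
from calcmvpa.glm import FIRResults
from calcmvpa.scenarios import decoding_model
from calcmvpa.simulate import NoiseModel, simulate_subject_runs
from calcmvpa.glm import FIRModel


def synthetic_run_betas(conditions, weights, scale_by_attr, noise_sd, rng,
                        n_runs=4, n_bins=10):
    """Per-run FIR betas with a linear code injected at every bin."""
    n_vox = weights["sample"].size
    out = []
    for _ in range(n_runs):
        est = rng.standard_normal((10, n_bins, n_vox)) * noise_sd
        for attr, scale in scale_by_attr.items():
            labels = numerosity_labels(conditions, attr)
            est += scale * labels[:, None, None] * weights[attr][None, None, :]
        out.append(FIRResults(est, [c.label for c in conditions], "per_run"))
    return out


@pytest.fixture(scope="module")
def ortho_weights():
    rng = np.random.default_rng(0)
    w = rng.standard_normal((2, 40))
    w[1] -= (w[1] @ w[0]) / (w[0] @ w[0]) * w[0]
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    return {"sample": w[0], "result": w[1]}


class TestFitPredict:
    def test_fisher_transform_closed_form(self):
        assert fisher_z(0.5) == pytest.approx(np.arctanh(0.5))
        assert np.isfinite(fisher_z(1.0))

    def test_noiseless_code_decodes_perfectly(self, conditions, ortho_weights):
        rng = np.random.default_rng(1)
        betas = synthetic_run_betas(conditions, ortho_weights,
                                    {"sample": 1.0}, 1e-4, rng)
        score = fit_predict_numerosity(betas, conditions, 3, 3, "sample", "sample")
        assert np.tanh(score) >= 0.99  # fold r before Fisher transform

    def test_pure_noise_scores_near_zero(self, conditions, ortho_weights):
        rng = np.random.default_rng(2)
        scores = []
        for _ in range(50):
            betas = synthetic_run_betas(conditions, ortho_weights, {}, 1.0, rng)
            scores.append(fit_predict_numerosity(betas, conditions, 2, 2,
                                                 "sample", "sample"))
        scores = np.array(scores)
        sem = scores.std(ddof=1) / np.sqrt(len(scores))
        assert abs(scores.mean()) < 2 * sem + 0.02

    def test_constant_patterns_score_zero(self, conditions):
        betas = [FIRResults(np.zeros((10, 10, 20)),
                            [c.label for c in conditions], "per_run")
                 for _ in range(3)]
        score = fit_predict_numerosity(betas, conditions, 2, 5, "sample", "result")
        assert score == 0.0

    def test_needs_two_runs(self, conditions, ortho_weights):
        rng = np.random.default_rng(3)
        betas = synthetic_run_betas(conditions, ortho_weights, {"sample": 1}, 0.1,
                                    rng, n_runs=1)
        with pytest.raises(ValueError, match="2 runs"):
            fit_predict_numerosity(betas, conditions, 1, 1)

    def test_test_set_scaling_independent_of_offsets(self, conditions, ortho_weights):
        """Per-set feature scaling makes the score invariant to test-run offsets."""
        rng = np.random.default_rng(4)
        betas = synthetic_run_betas(conditions, ortho_weights, {"sample": 1.0},
                                    0.05, rng)
        base = fit_predict_numerosity(betas, conditions, 2, 2, "sample", "sample")
        shifted = [FIRResults(b.estimates + 100.0, b.condition_labels, b.mode)
                   for b in betas]
        assert fit_predict_numerosity(shifted, conditions, 2, 2, "sample",
                                      "sample") == pytest.approx(base, abs=1e-6)


class TestWindowRule:
    def test_exactly_six_cells(self):
        cells = valid_cross_cells()
        assert len(cells) == 6
        assert set(cells) == {(2, 4), (2, 5), (2, 6), (3, 5), (3, 6), (4, 6)}

    def test_cells_satisfy_constraints(self):
        for s, r in valid_cross_cells():
            assert s in (2, 3, 4) and r in (4, 5, 6)
            assert abs(s - r) >= 2

    def test_constant_cells_average_to_constant(self):
        m = GeneralizationMatrix(np.full((10, 10), 0.37), "sample", "result")
        assert cross_decoding_score(m) == pytest.approx(0.37)
        m2 = GeneralizationMatrix(np.full((10, 10), 0.11), "result", "sample")
        assert cross_decoding_score(m, m2) == pytest.approx((0.37 + 0.11) / 2)

    def test_zero_matrices_score_zero(self):
        m = GeneralizationMatrix(np.zeros((10, 10)), "sample", "result")
        assert cross_decoding_score(m, m) == 0.0

    def test_empty_window_rejected(self):
        m = GeneralizationMatrix(np.zeros((10, 10)), "sample", "result")
        with pytest.raises(ValueError, match="no valid cells"):
            cross_decoding_score(m, sample_bins=(2,), result_bins=(3,))

    def test_uncomputed_cells_rejected(self):
        m = GeneralizationMatrix(np.full((10, 10), np.nan), "sample", "result")
        with pytest.raises(ValueError, match="not all computed"):
            cross_decoding_score(m)


class TestGeneralization:
    def test_shared_subspace_enables_cross_decoding(self, spec, conditions):
        """Cross-attribute cells positive at subspace_share 1, near zero at 0."""
        cells = valid_cross_cells()
        tb = sorted({c[0] for c in cells})
        rb = sorted({c[1] for c in cells})
        noise = NoiseModel()
        scores = {0.0: [], 1.0: []}
        for share in scores:
            for seed in range(3):
                ss = np.random.SeedSequence(seed + 60)
                model = decoding_model(60, share, seed=ss.spawn(1)[0])
                runs = simulate_subject_runs(spec, model, noise, seed=ss)
                per_run = FIRModel(runs, spec).fit(mode="per_run")
                m_sr = generalization_matrix(per_run, conditions, "sample", "result",
                                             train_bins=tb, test_bins=rb)
                m_rs = generalization_matrix(per_run, conditions, "result", "sample",
                                             train_bins=rb, test_bins=tb)
                scores[share].append(cross_decoding_score(m_sr, m_rs))
        assert np.mean(scores[1.0]) > np.mean(scores[0.0]) + 0.1
        assert abs(np.mean(scores[0.0])) < 0.1

    def test_within_attribute_diagonal_positive_at_zero_share(self, spec, conditions):
        """Same-attribute decoding works even when subspaces are separate."""
        scores = []
        for seed in (77, 78, 79):
            ss = np.random.SeedSequence(seed)
            model = decoding_model(60, 0.0, seed=ss.spawn(1)[0])
            runs = simulate_subject_runs(spec, model, NoiseModel(), seed=ss)
            per_run = FIRModel(runs, spec).fit(mode="per_run")
            m_ss = generalization_matrix(per_run, conditions, "sample", "sample",
                                         train_bins=[3, 4], test_bins=[3, 4])
            scores += [m_ss.score(3, 3), m_ss.score(4, 4)]
        assert np.mean(scores) > 0.1

    def test_restricted_matrix_leaves_other_cells_nan(self, conditions, ortho_weights):
        rng = np.random.default_rng(5)
        betas = synthetic_run_betas(conditions, ortho_weights, {"sample": 0.5}, 0.3, rng)
        m = generalization_matrix(betas, conditions, "sample", "sample",
                                  train_bins=[2], test_bins=[2, 3])
        assert np.isfinite(m.score(2, 2))
        assert np.isnan(m.score(5, 5))

    def test_decoder_spec_validation(self):
        with pytest.raises(ValueError):
            DecoderSpec(C=0.0)
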