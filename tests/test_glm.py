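"""FIR design construction and OLS estimation."""

import numpy as np
import pytest

from calcmvpa.design import DesignSpec, build_conditions
from calcmvpa.glm import FIRModel, build_fir_design, dct_drift_basis, fit_fir
from calcmvpa.simulate import (DEFAULT_ENVELOPES, NoiseModel, double_gamma_hrf,
                               condition_attribute_values, make_event_table,
                               make_voxel_population, simulate_bold_run,
                               trapezoid_envelope)


def expected_bin_amplitudes(spec, model):
    """Independent computation of the injected condition x bin x voxel betas."""
    dt = 0.1
    conds = build_conditions(spec)
    vals = condition_attribute_values(conds)
    hrf = double_gamma_hrf(np.arange(0, 32, dt))
    n_win = int(spec.trial_length / dt)
    out = np.zeros((len(conds), spec.n_fir_bins, model.n_voxels))
    for attr, amp in model.amplitudes.items():
        if amp == 0:
            continue
        env = trapezoid_envelope(np.arange(0, spec.trial_length, dt), model.envelopes[attr])
        bold = np.convolve(env, hrf)[:n_win] * dt
        samples = bold[(np.arange(spec.n_fir_bins) * spec.tr / dt).astype(int)]
        out += amp * (np.outer(vals[attr], samples)[:, :, None]
                      * model.weights[attr][None, None, :])
    return out


class TestFIRDesign:
    def test_column_count_default_run(self, spec):
        ev = make_event_table(spec, seed=0)
        design = build_fir_design(ev, spec)
        n_drift = dct_drift_basis(spec.n_volumes_per_run, spec.tr).shape[1]
        # 11 conditions (10 + catch) x 10 bins + run constant + drift
        assert design.n_regressors == 110 + 1 + n_drift

    def test_empty_event_table_gives_nuisance_only(self, spec):
        import pandas as pd

        from calcmvpa.simulate import EVENT_COLUMNS

        empty = pd.DataFrame(columns=EVENT_COLUMNS)
        design = build_fir_design(empty, spec)
        assert all(":bin" not in lab for lab in design.column_labels)
        assert design.n_regressors >= 1

    def test_full_rank_with_finite_condition_number(self, spec):
        ev = make_event_table(spec, seed=1)
        design = build_fir_design(ev, spec)
        assert np.linalg.matrix_rank(design.matrix) == design.n_regressors
        assert np.isfinite(np.linalg.cond(design.matrix))

    def test_rank_deficiency_reported_with_columns(self, spec):
        ev = make_event_table(spec, seed=0)
        conf = np.ones((spec.n_volumes_per_run, 1))  # duplicates the run constant
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            build_fir_design(ev, spec, confounds=[conf])

    def test_events_beyond_run_duration_rejected(self, spec):
        ev = make_event_table(spec, seed=0)
        ev.loc[ev.index[-1], "onset"] = 1e4
        with pytest.raises(ValueError, match="beyond run duration"):
            build_fir_design(ev, spec)


class TestFIRFit:
    def test_noiseless_identity(self, noiseless):
        """OLS recovers the injected bin amplitudes exactly without noise."""
        spec = DesignSpec(n_catch_per_run=0)
        amps = {"sample": 1.0, "result": 0.7, "operation": 0.0, "operand": 0.0}
        model = make_voxel_population(12, 0.0, amplitudes=amps, seed=3)
        run = simulate_bold_run(spec, model, noiseless, seed=4)
        fir = FIRModel([run], spec).fit()
        assert np.abs(fir.estimates - expected_bin_amplitudes(spec, model)).max() < 1e-8

    def test_ols_matches_statsmodels(self, spec):
        """Estimates agree with an independent statsmodels OLS solve."""
        import statsmodels.api as sm

        ev = make_event_table(spec, seed=2)
        design = build_fir_design(ev, spec)
        rng = np.random.default_rng(0)
        y = rng.standard_normal((design.matrix.shape[0], 3))
        fir = fit_fir(y, design)
        for v in range(3):
            ref = sm.OLS(y[:, v], design.matrix).fit().params
            for ci, lab in enumerate(design.condition_labels):
                for b in range(1, 11):
                    col = design.column_labels.index(f"{lab}:bin{b}")
                    assert fir.estimates[ci, b - 1, v] == pytest.approx(ref[col], abs=1e-10)

    def test_highpass_attenuates_slow_sinusoid(self, spec):
        """A sinusoid slower than the 244 s cutoff is >= 90% removed."""
        ev = make_event_table(spec, seed=3)
        design = build_fir_design(ev, spec)
        n = design.matrix.shape[0]
        t = np.arange(n) * spec.tr
        y = np.sin(2 * np.pi * t / 490.0)[:, None]
        beta, *_ = np.linalg.lstsq(design.matrix, y, rcond=None)
        resid = y - design.matrix @ beta
        assert (resid ** 2).sum() <= 0.1 * (y ** 2).sum()

    def test_noise_only_betas_shrink_with_more_runs(self, spec):
        """Mean |beta| scales roughly as 1/sqrt(number of volumes)."""
        model = make_voxel_population(4, 0.0, amplitudes={a: 0.0 for a in DEFAULT_ENVELOPES},
                                      seed=0)
        noise = NoiseModel(ar1_rho=0.0, sigma=1.0, drift_order=0, drift_sigma=0)
        m1, m6 = [], []
        for seed in range(20):
            runs = [simulate_bold_run(spec, model, noise, seed=1000 * seed + r)
                    for r in range(6)]
            fir1 = FIRModel(runs[:1], spec).fit()
            fir6 = FIRModel(runs, spec).fit()
            m1.append(np.abs(fir1.estimates).mean())
            m6.append(np.abs(fir6.estimates).mean())
        ratio = np.mean(m6) / np.mean(m1)
        assert ratio == pytest.approx(1 / np.sqrt(6), rel=0.15)

    def test_per_run_mode_matches_concatenated_when_noiseless(self, noiseless):
        spec = DesignSpec(n_catch_per_run=0, n_runs=3)
        amps = {"sample": 0.8, "result": 0.4, "operation": 0.0, "operand": 0.0}
        model = make_voxel_population(10, 0.0, amplitudes=amps, seed=5)
        runs = [simulate_bold_run(spec, model, noiseless, seed=r) for r in range(3)]
        glm = FIRModel(runs, spec)
        concat = glm.fit(mode="concatenated")
        per_run = glm.fit(mode="per_run")
        assert len(per_run) == 3
        assert [r.run for r in per_run] == [0, 1, 2]
        avg = np.mean([r.estimates for r in per_run], axis=0)
        assert np.abs(avg - concat.estimates).max() < 1e-8

    def test_per_run_average_approximates_concatenated_with_noise(self, spec):
        model = make_voxel_population(15, 0.0, seed=6)
        runs = [simulate_bold_run(spec, model, NoiseModel(), seed=r + 50)
                for r in range(6)]
        glm = FIRModel(runs, spec)
        concat = glm.fit(mode="concatenated").estimates
        avg = np.mean([r.estimates for r in glm.fit(mode="per_run")], axis=0)
        r = np.corrcoef(avg.ravel(), concat.ravel())[0, 1]
        assert r > 0.95

    def test_nan_in_data_identifies_run_and_voxel(self, spec):
        model = make_voxel_population(5, 0.0, seed=0)
        run = simulate_bold_run(spec, model, NoiseModel(), seed=0)
        run.data[3, 2] = np.nan
        with pytest.raises(ValueError, match="run 0.*voxel.*2"):
            FIRModel([run], spec).fit()

    def test_prewhitening_preserves_noiseless_identity(self, noiseless):
        spec = DesignSpec(n_catch_per_run=0)
        amps = {"sample": 1.0, "result": 0.0, "operation": 0.0, "operand": 0.0}
        model = make_voxel_population(6, 0.0, amplitudes=amps, seed=7)
        run = simulate_bold_run(spec, model, noiseless, seed=8)
        plain = FIRModel([run], spec).fit()
        white = FIRModel([run], spec).fit(prewhiten=True)
        assert np.abs(plain.estimates - white.estimates).max() < 1e-6
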