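"""Canonical simulation scenarios for validation studies.

Each scenario fixes the generator parameters for one question, so the
test suite, the acceptance studies and the documentation all refer to
the same study conditions:

``rsa_recovery``
    Sample code (middle-window BOLD peak) and result code
    (late-window peak) embedded in separate subspaces
    (subspace_share 0) at the generator's default amplitudes; used
    for group-level parameter recovery of the RSA regression.

``rsa_null``
    No codes embedded; used to calibrate false-positive rates.

``decoding``
    Equal sample and result amplitudes (matched SNR, as the
    cross-decoding comparison requires) with a sharpened sample
    envelope so little stimulus-evoked activity persists into the
    result test bins; ``subspace_share`` is the scenario's free knob.

``brain_behavior``
    Shared-code cohort (subspace_share 1) in which a per-subject
    factor scales the result-code amplitude and inversely scales the
    behavioral Weber fraction, emulating subjects whose more faithful
    internal result representation yields both better cross-decoding
    and more precise comparison behavior.
"""

from __future__ import annotations

import numpy as np

from .design import DesignSpec
from .simulate import (DEFAULT_AMPLITUDES, DEFAULT_ENVELOPES, CodingModel,
                       NoiseModel, make_voxel_population)

__all__ = ["rsa_recovery_model", "rsa_null_model", "decoding_model",
           "brain_behavior_cohort_params", "DECODING_ENVELOPES",
           "DECODING_AMPLITUDES"]

DECODING_ENVELOPES = {
    "sample": (0.0, 0.3, 0.8, 1.2),
    "operation": (2.0, 3.0, 5.0, 7.0),
    "operand": (2.0, 3.0, 5.0, 7.0),
    "result": (3.5, 5.0, 7.5, 9.0),
}
DECODING_AMPLITUDES = {"sample": 0.5, "operation": 0.0, "operand": 0.0, "result": 0.5}

#: brain-behavior cohort: stronger base code and a larger ROI so the
#: between-subject SNR range dominates the decoder's score noise.
BRAIN_BEHAVIOR_AMPLITUDES = {"sample": 1.0, "operation": 0.0, "operand": 0.0, "result": 1.0}
BRAIN_BEHAVIOR_N_VOXELS = 150
BRAIN_BEHAVIOR_N_TRIALS = 500


def rsa_recovery_model(n_voxels: int, seed, **kwargs) -> CodingModel:
    """Sample + result codes in orthogonal subspaces at default amplitudes."""
    return make_voxel_population(n_voxels, subspace_share=0.0,
                                 amplitudes=dict(DEFAULT_AMPLITUDES),
                                 envelopes=dict(DEFAULT_ENVELOPES),
                                 seed=seed, **kwargs)


def rsa_null_model(n_voxels: int, seed, **kwargs) -> CodingModel:
    """No embedded codes: pure noise cohort for calibration."""
    amplitudes = {k: 0.0 for k in DEFAULT_AMPLITUDES}
    return make_voxel_population(n_voxels, subspace_share=0.0,
                                 amplitudes=amplitudes,
                                 envelopes=dict(DEFAULT_ENVELOPES),
                                 seed=seed, **kwargs)


def decoding_model(n_voxels: int, subspace_share: float, seed, **kwargs) -> CodingModel:
    """Matched-SNR sample/result codes for cross-decoding studies."""
    return make_voxel_population(n_voxels, subspace_share=subspace_share,
                                 amplitudes=dict(DECODING_AMPLITUDES),
                                 envelopes=dict(DECODING_ENVELOPES),
                                 seed=seed, **kwargs)


def brain_behavior_cohort_params(
    n_subjects: int,
    seed,
    weber_base: float = 0.29,
    factor_range: tuple[float, float] = (0.25, 2.2),
    coupling_exponent: float = 0.8,
    weber_jitter_sd: float = 0.02,
) -> list[dict]:
    """Per-subject (result amplitude factor, Weber fraction) pairs.

    The result-code SNR factor f is uniform over ``factor_range``; the
    Weber fraction is ``weber_base * f**(-coupling_exponent)`` with
    lognormal jitter, so high-SNR subjects are behaviorally precise.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_subjects):
        f = rng.uniform(*factor_range)
        weber = weber_base * f ** (-coupling_exponent) * np.exp(rng.normal(0, weber_jitter_sd))
        out.append({"snr_factor": float(f), "weber": float(weber)})
    return out
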