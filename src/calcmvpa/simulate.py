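"""Synthetic BOLD, event and behavioral data with known embedded codes.

The generator emulates the approximate-calculation paradigm at desk
scale: each run contains 2 standard trials of each of the 10 conditions
plus 4 catch trials (20%), trials last 20 s, the dot sample appears at
0 s, the operation cue at 2 s and the probe at 12 s (catch trials:
uniform 5.4-9.6 s).  Voxels carry linear codes for sample numerosity,
result numerosity, operation and operand: each attribute has a weight
vector over voxels, a temporal envelope over post-sample seconds and an
amplitude.  Numeric attributes enter as z-scored log numerosity, so the
coded magnitude is monotone in log numerosity, matching how the
decoding stage labels patterns.  The sample/result weight vectors share
a controllable fraction of their direction (``subspace_share``), which
operationalizes the shared-representational-space hypothesis probed by
cross-decoding.

Noise is AR(1) plus slow cosine drift; the neural envelopes are
convolved with a canonical double-gamma HRF.  Probe-evoked responses
are not simulated (analysis windows all precede the standard-trial
probe).

A Weber-fraction observer produces the behavioral comparison data:
P(respond "larger") = Phi((log ratio - pse) / sigma) with
sigma = weber / Phi^-1(0.75), so the log-scale JND equals the Weber
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.stats import norm

from .design import Condition, DesignSpec, build_conditions

__all__ = [
    "ATTRIBUTES",
    "CodingModel",
    "NoiseModel",
    "BoldRun",
    "double_gamma_hrf",
    "trapezoid_envelope",
    "make_voxel_population",
    "make_event_table",
    "condition_attribute_values",
    "simulate_bold_run",
    "simulate_subject_runs",
    "simulate_observer",
    "subject_seeds",
]

ATTRIBUTES = ("sample", "operation", "operand", "result")

#: default neural envelopes (start, plateau-start, plateau-end, end) in
#: seconds post-sample, chosen so the HRF-convolved BOLD code peaks in
#: the middle (4-8 s) window for the sample and the late (8-12 s)
#: window for the result; cue-dependent codes start no earlier than the
#: 2 s cue.
DEFAULT_ENVELOPES = {
    "sample": (0.0, 0.4, 1.2, 2.0),
    "operation": (2.0, 3.0, 5.0, 7.0),
    "operand": (2.0, 3.0, 5.0, 7.0),
    "result": (3.5, 5.0, 7.5, 9.0),
}

#: sample code stronger than result code, mirroring the relative
#: prominence of stimulus-evoked vs internally generated effects;
#: operation and operand are not coded by default.
DEFAULT_AMPLITUDES = {"sample": 0.40, "operation": 0.0, "operand": 0.0, "result": 0.16}


def double_gamma_hrf(t: np.ndarray, peak: float = 5.0, undershoot: float = 15.0,
                     ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at times ``t``.

    Peak near ``peak`` seconds, undershoot near ``undershoot`` seconds,
    peak-to-undershoot amplitude ratio ``ratio``; normalized to unit
    maximum.
    """
    from scipy.stats import gamma as gamma_dist

    t = np.asarray(t, dtype=float)
    pos = gamma_dist.pdf(t, peak, scale=1.0)
    neg = gamma_dist.pdf(t, undershoot, scale=1.0)
    h = pos - neg / ratio
    h[t < 0] = 0.0
    m = h.max()
    return h / m if m > 0 else h


def trapezoid_envelope(t: np.ndarray, breaks: tuple[float, float, float, float]) -> np.ndarray:
    """Piecewise-linear bump: 0 before t0, rises to 1 on [t0,t1], flat on
    [t1,t2], falls to 0 on [t2,t3]."""
    t0, t1, t2, t3 = breaks
    if not (t0 <= t1 <= t2 <= t3):
        raise ValueError(f"envelope breakpoints must be nondecreasing, got {breaks}")
    t = np.asarray(t, dtype=float)
    up = np.clip((t - t0) / max(t1 - t0, 1e-12), 0.0, 1.0)
    down = np.clip((t3 - t) / max(t3 - t2, 1e-12), 0.0, 1.0)
    return np.minimum(up, down)


@dataclass
class NoiseModel:
    """AR(1) + drift noise and the HRF shaping the ground-truth signal."""

    ar1_rho: float = 0.3
    sigma: float = 1.0
    drift_order: int = 3
    drift_sigma: float = 0.5
    hrf_peak: float = 5.0
    hrf_undershoot: float = 15.0
    hrf_ratio: float = 6.0

    def __post_init__(self) -> None:
        if not 0 <= abs(self.ar1_rho) < 1:
            raise ValueError("stationary AR(1) requires |rho| < 1")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


@dataclass
class CodingModel:
    """Voxel weight vectors, temporal envelopes and amplitudes per attribute."""

    n_voxels: int
    weights: dict[str, np.ndarray]
    envelopes: dict[str, tuple[float, float, float, float]]
    subspace_share: float
    amplitudes: dict[str, float]
    grid_shape: tuple[int, int, int] | None = None

    def weight_cosine(self, a: str, b: str) -> float:
        wa, wb = self.weights[a], self.weights[b]
        na, nb = np.linalg.norm(wa), np.linalg.norm(wb)
        if na == 0 or nb == 0:
            return 0.0
        return float(wa @ wb / (na * nb))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def make_voxel_population(
    n_voxels: int,
    subspace_share: float,
    amplitudes: dict[str, float] | None = None,
    seed: int | np.random.SeedSequence = 0,
    envelopes: dict[str, tuple] | None = None,
    active: np.ndarray | None = None,
    grid_shape: tuple[int, int, int] | None = None,
) -> CodingModel:
    """Draw unit-norm attribute weight vectors over ``n_voxels`` voxels.

    The result-code direction is constructed as
    ``s * w_sample + sqrt(1 - s^2) * w_perp`` with ``s = subspace_share``,
    so the cosine between sample and result weights equals
    ``subspace_share`` exactly.  ``active`` optionally restricts all
    codes to a boolean voxel mask (weights are zero elsewhere), which
    localizes the information for searchlight tests.
    """
    if not 0.0 <= subspace_share <= 1.0:
        raise ValueError("subspace_share must lie in [0, 1]")
    if n_voxels < 2:
        raise ValueError("need at least 2 voxels per coded attribute")
    rng = np.random.default_rng(seed)
    amplitudes = dict(DEFAULT_AMPLITUDES if amplitudes is None else amplitudes)
    envelopes = dict(DEFAULT_ENVELOPES if envelopes is None else envelopes)

    if active is None:
        active_idx = np.arange(n_voxels)
    else:
        active = np.asarray(active, dtype=bool)
        if active.size != n_voxels:
            raise ValueError("active mask size must equal n_voxels")
        active_idx = np.flatnonzero(active)
        if active_idx.size < 2:
            raise ValueError("active mask must contain at least 2 voxels")
    k = active_idx.size

    w_sample = _unit(rng.standard_normal(k))
    g = rng.standard_normal(k)
    w_perp = _unit(g - (g @ w_sample) * w_sample)
    s = subspace_share
    w_result = s * w_sample + np.sqrt(max(0.0, 1.0 - s * s)) * w_perp

    weights = {}
    for name, w_active in (
        ("sample", w_sample),
        ("result", w_result),
        ("operation", _unit(rng.standard_normal(k))),
        ("operand", _unit(rng.standard_normal(k))),
    ):
        w = np.zeros(n_voxels)
        w[active_idx] = w_active
        weights[name] = w
    return CodingModel(n_voxels, weights, envelopes, subspace_share, amplitudes,
                       grid_shape=grid_shape)


@dataclass
class BoldRun:
    """One simulated run: volumes x voxels signal plus its event table."""

    data: np.ndarray
    tr: float
    grid_shape: tuple[int, int, int]
    events: pd.DataFrame

    def __post_init__(self) -> None:
        if int(np.prod(self.grid_shape)) != self.data.shape[1]:
            raise ValueError("grid_shape product must equal voxel count")
        last_offset = float(self.events["onset"].max()) if len(self.events) else 0.0
        if self.data.shape[0] * self.tr < last_offset:
            raise ValueError("run shorter than last event onset")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


EVENT_COLUMNS = ["onset", "condition", "condition_index", "is_catch",
                 "probe_onset", "probe_ratio", "correct_side"]


def make_event_table(spec: DesignSpec, seed: int | np.random.SeedSequence = 0) -> pd.DataFrame:
    """Randomized trial sequence for one run.

    2 standard trials per condition plus 4 catch trials in uniformly
    random order; trials abut at ``trial_length`` spacing.  Standard
    trials have the probe at onset + 12 s, catch trials at a uniform
    [5.4, 9.6] s SOA.  Probe ratios are drawn from the 8-ratio design
    set; ``correct_side`` is "larger" when the ratio exceeds 1.
    """
    rng = np.random.default_rng(seed)
    conditions = build_conditions(spec)
    idx = np.repeat(np.arange(len(conditions)), spec.trials_per_condition_per_run)
    catch_conditions = rng.integers(0, len(conditions), size=spec.n_catch_per_run)
    cond_index = np.concatenate([idx, catch_conditions])
    is_catch = np.concatenate([
        np.zeros(idx.size, dtype=bool), np.ones(spec.n_catch_per_run, dtype=bool)
    ])
    order = rng.permutation(cond_index.size)
    cond_index, is_catch = cond_index[order], is_catch[order]

    onsets = np.arange(cond_index.size) * spec.trial_length
    lo, hi = spec.catch_soa_range
    soa = np.where(is_catch, rng.uniform(lo, hi, size=cond_index.size),
                   spec.probe_soa_standard)
    ratios = rng.choice(spec.probe_ratios, size=cond_index.size)
    return pd.DataFrame({
        "onset": onsets,
        "condition": [conditions[i].label for i in cond_index],
        "condition_index": cond_index,
        "is_catch": is_catch,
        "probe_onset": onsets + soa,
        "probe_ratio": ratios,
        "correct_side": np.where(ratios > 1, "larger", "smaller"),
    })


def condition_attribute_values(conditions: list[Condition]) -> dict[str, np.ndarray]:
    """Numeric code value per condition and attribute.

    Sample/result: log numerosity z-scored across the condition list
    (population sd).  Operation and operand: +/-0.5 contrast codes.
    """
    samples = np.log(np.array([c.sample for c in conditions], dtype=float))
    results = np.log(np.array([c.result for c in conditions], dtype=float))

    def z(v: np.ndarray) -> np.ndarray:
        return (v - v.mean()) / v.std()

    return {
        "sample": z(samples),
        "result": z(results),
        "operation": np.array([0.5 if c.operation == "multiply" else -0.5 for c in conditions]),
        "operand": np.array([0.5 if c.operand == 4 else -0.5 for c in conditions]),
    }


def _ar1_noise(rng: np.random.Generator, n_vol: int, n_vox: int, rho: float,
               sigma: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sigma``."""
    if sigma == 0:
        return np.zeros((n_vol, n_vox))
    w = rng.standard_normal((n_vol, n_vox)) * sigma * np.sqrt(1.0 - rho * rho)
    w[0] = rng.standard_normal(n_vox) * sigma
    return sps.lfilter([1.0], [1.0, -rho], w, axis=0)


def _drift(rng: np.random.Generator, n_vol: int, n_vox: int, order: int,
           sigma: float) -> np.ndarray:
    """Random slow drift from the first ``order`` non-constant cosines."""
    if order == 0 or sigma == 0:
        return np.zeros((n_vol, n_vox))
    t = np.arange(n_vol)
    basis = np.stack([np.cos(np.pi * k * (t + 0.5) / n_vol) for k in range(1, order + 1)])
    coef = rng.standard_normal((order, n_vox)) * sigma
    return basis.T @ coef


def simulate_bold_run(
    spec: DesignSpec,
    model: CodingModel,
    noise: NoiseModel,
    events: pd.DataFrame | None = None,
    seed: int | np.random.SeedSequence = 0,
    grid_shape: tuple[int, int, int] | None = None,
    dt: float = 0.1,
) -> BoldRun:
    """Simulate one run of voxel time courses.

    signal(t, v) = sum over attributes a and trials of
    ``amplitude[a] * weight[a][v] * value_a(condition) *
    (envelope_a shifted to trial onset, convolved with the HRF)``
    sampled at the TR, plus drift plus AR(1) noise.  Catch trials carry
    the same condition codes as standard trials (the GLM models them as
    a separate condition and they are excluded from analysis).
    """
    rng = np.random.default_rng(seed)
    if events is None:
        events = make_event_table(spec, rng)
    conditions = build_conditions(spec)
    labels = {c.label for c in conditions}
    unknown = set(events["condition"]) - labels
    if unknown:
        raise ValueError(f"unknown condition ids in event table: {sorted(unknown)}")
    values = condition_attribute_values(conditions)

    n_vol = spec.n_volumes_per_run
    duration = n_vol * spec.tr
    n_hr = int(round(duration / dt))
    t_hr = np.arange(n_hr) * dt
    hrf = double_gamma_hrf(np.arange(0, 32, dt), peak=noise.hrf_peak,
                           undershoot=noise.hrf_undershoot, ratio=noise.hrf_ratio)

    if grid_shape is None:
        grid_shape = model.grid_shape or (model.n_voxels, 1, 1)
    data = np.zeros((n_vol, model.n_voxels))
    vol_idx = np.clip((np.arange(n_vol) * spec.tr / dt).astype(int), 0, n_hr - 1)

    env_t = np.arange(0, spec.trial_length, dt)
    n_win = env_t.size
    for attr in ATTRIBUTES:
        amp = model.amplitudes.get(attr, 0.0)
        if amp == 0.0:
            continue
        env = trapezoid_envelope(env_t, model.envelopes[attr])
        # per-trial BOLD profile, confined to the trial's own window so the
        # ground truth lies exactly in the span of the FIR sticks (the FIR
        # window equals the trial length)
        bold_win = np.convolve(env, hrf)[:n_win] * dt
        signal_hr = np.zeros(n_hr)
        for onset, cidx in zip(events["onset"], events["condition_index"]):
            i0 = int(round(onset / dt))
            seg = min(n_win, n_hr - i0)
            if seg > 0:
                signal_hr[i0:i0 + seg] += values[attr][cidx] * bold_win[:seg]
        data += amp * np.outer(signal_hr[vol_idx], model.weights[attr])

    data += _drift(rng, n_vol, model.n_voxels, noise.drift_order, noise.drift_sigma)
    data += _ar1_noise(rng, n_vol, model.n_voxels, noise.ar1_rho, noise.sigma)
    return BoldRun(data, spec.tr, grid_shape, events)


def subject_seeds(global_seed: int, n_subjects: int) -> list[np.random.SeedSequence]:
    """Deterministic per-subject seed fan-out from one global seed."""
    return np.random.SeedSequence(global_seed).spawn(n_subjects)


def simulate_subject_runs(
    spec: DesignSpec,
    model: CodingModel,
    noise: NoiseModel,
    seed: int | np.random.SeedSequence,
    n_runs: int | None = None,
    grid_shape: tuple[int, int, int] | None = None,
    events_per_run: list[pd.DataFrame] | None = None,
) -> list[BoldRun]:
    """Simulate all runs of one subject with per-run sub-seeds."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    n_runs = n_runs or spec.n_runs
    run_seeds = ss.spawn(n_runs)
    runs = []
    for r in range(n_runs):
        ev = events_per_run[r] if events_per_run is not None else None
        runs.append(simulate_bold_run(spec, model, noise, events=ev,
                                      seed=run_seeds[r], grid_shape=grid_shape))
    return runs


def simulate_observer(
    weber: float,
    pse_shift_by_operation: tuple[float, float] = (0.0, 0.0),
    ratios: tuple[float, ...] = DesignSpec().probe_ratios,
    n_trials: int = 160,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Simulate probe-comparison responses of a Weber-fraction observer.

    ``pse_shift_by_operation`` gives the PSE (in log-ratio units) for
    (division, multiplication) trials; a negative division PSE with a
    positive multiplication PSE emulates operational momentum.  The
    response noise sigma is ``weber / Phi^-1(0.75)`` so that the
    log-scale JND of the generating process equals ``weber``.
    """
    if weber <= 0:
        raise ValueError("weber fraction must be positive")
    if np.any(np.asarray(ratios) <= 0):
        raise ValueError("ratios must be positive")
    rng = np.random.default_rng(seed)
    sigma = weber / norm.ppf(0.75)
    pse_div, pse_mul = pse_shift_by_operation
    operation = rng.choice(["divide", "multiply"], size=n_trials)
    operand = rng.choice([2, 4], size=n_trials)
    ratio = rng.choice(ratios, size=n_trials)
    pse = np.where(operation == "multiply", pse_mul, pse_div)
    p_larger = norm.cdf((np.log(ratio) - pse) / sigma)
    larger = rng.random(n_trials) < p_larger
    response = np.where(larger, "larger", "smaller")
    correct = (ratio > 1) == larger
    return pd.DataFrame({
        "operation": operation,
        "operand": operand,
        "probe_ratio": ratio,
        "response": response,
        "correct": correct,
    })
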