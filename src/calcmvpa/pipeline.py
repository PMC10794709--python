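"""End-to-end orchestration: simulate -> GLM -> RSA -> decoding -> stats.

The pipeline simulates a cohort of subjects with codes for the sample
and result numerosities embedded in a cubic "coding" region of a
voxel grid (plus a code-free "control" region), runs the FIR GLM per
subject, the ROI and searchlight RSA regressions, the windowed
cross-decoding, the psychometric fits, and the group statistics, and
writes a machine-readable summary.  One global seed fans out
deterministically to per-subject and per-run sub-seeds through
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import fit_psychometric, operational_momentum
from .decoding import DecoderSpec, cross_decoding_score, generalization_matrix, valid_cross_cells
from .design import (DesignSpec, PREDICTOR_NAMES, build_conditions,
                     build_predictor_rdms, predictor_correlations)
from .glm import FIRModel
from .rsa import WINDOWS, roi_rsa, searchlight_rsa, window_average
from .simulate import (DEFAULT_AMPLITUDES, DEFAULT_ENVELOPES, CodingModel,
                       NoiseModel, make_voxel_population, simulate_observer,
                       simulate_subject_runs)
from .stats import (bh_fdr, brain_behavior_correlation, cluster_permutation,
                    group_onesample_t)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "cube_mask"]

ANALYSIS_WINDOWS = ("middle", "late")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All knobs of one pipeline execution; round-trips through JSON."""

    # cohort and grid
    n_subjects: int = 17
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    roi_center: tuple[int, int, int] = (6, 6, 6)
    roi_halfwidth: int = 3
    control_center: tuple[int, int, int] | None = None  # mirrored by default
    # embedded codes
    subspace_share: float = 0.5
    amplitudes: dict = field(default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    envelopes: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_ENVELOPES.items()})
    # noise
    ar1_rho: float = 0.3
    noise_sigma: float = 1.0
    drift_order: int = 3
    drift_sigma: float = 0.5
    # behavior
    weber_mean: float = 0.29
    weber_sd_log: float = 0.2
    pse_shift_division: float = 0.0
    pse_shift_multiplication: float = 0.0
    n_behavior_trials: int = 160
    couple_result_snr_to_weber: bool = True
    snr_factor_range: tuple[float, float] = (0.4, 1.6)
    # analysis
    searchlight: bool = True
    searchlight_radius: int = 3
    n_permutations: int = 200
    cluster_forming_p: float = 0.01
    alpha: float = 0.05
    fdr_q: float = 0.05
    decoder_C: float = 1.0
    decoder_epsilon: float = 0.1
    # design overrides (DesignSpec fields)
    design: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.envelopes = {k: tuple(v) for k, v in self.envelopes.items()}
        self.grid_shape = tuple(self.grid_shape)
        self.roi_center = tuple(self.roi_center)
        if self.control_center is not None:
            self.control_center = tuple(self.control_center)
        self.snr_factor_range = tuple(self.snr_factor_range)

    def design_spec(self) -> DesignSpec:
        return DesignSpec.from_dict(self.design) if self.design else DesignSpec()

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("grid_shape", "roi_center", "control_center", "snr_factor_range"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        if "envelopes" in d:
            d["envelopes"] = {k: tuple(v) for k, v in d["envelopes"].items()}
        return cls(**d)


def cube_mask(grid_shape: tuple[int, int, int], center: tuple[int, int, int],
              halfwidth: int) -> np.ndarray:
    """Boolean mask of an axis-aligned cube clipped to the grid."""
    mask = np.zeros(grid_shape, dtype=bool)
    sl = tuple(slice(max(c - halfwidth, 0), min(c + halfwidth + 1, n))
               for c, n in zip(center, grid_shape))
    mask[sl] = True
    return mask


def _roi_indices(mask: np.ndarray) -> np.ndarray:
    return np.flatnonzero(mask.ravel())


def _subject_snr_and_weber(config: PipelineConfig, rng: np.random.Generator):
    """Per-subject result-code SNR factor and behavioral Weber fraction.

    With coupling on, a common subject factor scales the result-code
    amplitude and (inversely) the behavioral precision, emulating
    subjects whose internal result representation is both more
    decodable and behaviorally more precise.
    """
    if config.couple_result_snr_to_weber:
        lo, hi = config.snr_factor_range
        f = rng.uniform(lo, hi)
        weber = config.weber_mean * (1.0 / f) ** 0.7 * np.exp(rng.normal(0, 0.05))
    else:
        f = 1.0
        weber = config.weber_mean * np.exp(rng.normal(0, config.weber_sd_log))
    return f, float(weber)


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full pipeline and return (and optionally write) the summary."""
    t0 = time.time()
    stage = "setup"
    try:
        if outdir is not None:
            Path(outdir).mkdir(parents=True, exist_ok=True)
        spec = config.design_spec()
        conditions = build_conditions(spec)
        predictors = build_predictor_rdms(conditions)
        corr = predictor_correlations(predictors)
        grid = tuple(config.grid_shape)
        n_vox = int(np.prod(grid))
        coding_mask = cube_mask(grid, config.roi_center, config.roi_halfwidth)
        control_center = config.control_center or tuple(n - 1 - c for n, c in
                                                        zip(grid, config.roi_center))
        control_mask = cube_mask(grid, control_center, config.roi_halfwidth)
        if (coding_mask & control_mask).any():
            raise ValueError("coding and control ROIs overlap")
        rois = {"coding": _roi_indices(coding_mask), "control": _roi_indices(control_mask)}
        noise = NoiseModel(ar1_rho=config.ar1_rho, sigma=config.noise_sigma,
                           drift_order=config.drift_order, drift_sigma=config.drift_sigma)
        envelopes = {k: tuple(v) for k, v in config.envelopes.items()}
        decoder = DecoderSpec(C=config.decoder_C, epsilon=config.decoder_epsilon)

        root = np.random.SeedSequence(config.seed)
        subj_seeds = root.spawn(config.n_subjects)
        perm_seed, cohort_seed = root.spawn(2)
        cohort_rng = np.random.default_rng(cohort_seed)

        roi_betas = {roi: {w: {p: [] for p in PREDICTOR_NAMES} for w in ANALYSIS_WINDOWS}
                     for roi in rois}
        window_maps = {p: {w: [] for w in ANALYSIS_WINDOWS} for p in PREDICTOR_NAMES} \
            if config.searchlight else None
        scores = {roi: [] for roi in rois}
        webers_true, webers_fit = [], []
        pse_div, pse_mul = [], []

        for s, sseed in enumerate(subj_seeds):
            stage = f"simulate subject {s}"
            f, weber_true = _subject_snr_and_weber(config, cohort_rng)
            amplitudes = dict(config.amplitudes)
            amplitudes["result"] = amplitudes.get("result", 1.0) * f
            model = make_voxel_population(
                n_vox, config.subspace_share, amplitudes=amplitudes,
                seed=sseed.spawn(1)[0], envelopes=envelopes,
                active=coding_mask.ravel(), grid_shape=grid)
            runs = simulate_subject_runs(spec, model, noise, seed=sseed,
                                         grid_shape=grid)

            stage = f"glm subject {s}"
            glm = FIRModel(runs, spec)
            fir = glm.fit(mode="concatenated")
            fir_runs = glm.fit(mode="per_run")
            del runs

            stage = f"rsa subject {s}"
            for roi, vox in rois.items():
                eff = roi_rsa(fir, predictors, voxel_indices=vox, bins=list(range(1, 7)),
                              voxel_set=roi)
                wm = window_average(eff)
                for w in ANALYSIS_WINDOWS:
                    for p in PREDICTOR_NAMES:
                        roi_betas[roi][w][p].append(wm[w][p])
            if config.searchlight:
                stage = f"searchlight subject {s}"
                sl = searchlight_rsa(fir, np.ones(grid, bool), predictors,
                                     radius_voxels=config.searchlight_radius,
                                     bins=list(range(1, 7)))
                for p in PREDICTOR_NAMES:
                    for w in ANALYSIS_WINDOWS:
                        window_maps[p][w].append(np.nan_to_num(sl.window_map(p, w)))
                del sl

            stage = f"decoding subject {s}"
            cells = valid_cross_cells()
            tb = sorted({c[0] for c in cells})
            rb = sorted({c[1] for c in cells})
            for roi, vox in rois.items():
                sliced = [_slice_fir(fr, vox) for fr in fir_runs]
                m_sr = generalization_matrix(sliced, conditions, "sample", "result",
                                             decoder, train_bins=tb, test_bins=rb)
                m_rs = generalization_matrix(sliced, conditions, "result", "sample",
                                             decoder, train_bins=rb, test_bins=tb)
                scores[roi].append(cross_decoding_score(m_sr, m_rs))

            stage = f"behavior subject {s}"
            behav = simulate_observer(
                weber_true,
                (config.pse_shift_division, config.pse_shift_multiplication),
                ratios=spec.probe_ratios, n_trials=config.n_behavior_trials,
                seed=sseed.spawn(2)[1])
            fit_pooled = fit_psychometric(behav, "pooled")
            webers_true.append(weber_true)
            webers_fit.append(fit_pooled.jnd)
            pse_div.append(fit_psychometric(behav, "divide").pse)
            pse_mul.append(fit_psychometric(behav, "multiply").pse)

        stage = "group statistics"
        roi_rows = []
        for p in PREDICTOR_NAMES:
            fam_p, fam_keys = [], []
            for roi in rois:
                for w in ANALYSIS_WINDOWS:
                    vals = np.asarray(roi_betas[roi][w][p])
                    t, pv = group_onesample_t(vals)
                    fam_p.append(float(pv))
                    fam_keys.append((roi, w))
                    roi_rows.append({"predictor": p, "roi": roi, "window": w,
                                     "mean_beta": float(vals.mean()),
                                     "t": float(t), "df": int(vals.size - 1),
                                     "p": float(pv)})
            reject, p_adj = bh_fdr(fam_p, q=config.fdr_q)
            for (roi, w), rj, pa in zip(fam_keys, reject, p_adj):
                for row in roi_rows:
                    if row["predictor"] == p and row["roi"] == roi and row["window"] == w:
                        row["p_fdr"] = float(pa)
                        row["significant"] = bool(rj)
        roi_table = pd.DataFrame(roi_rows)

        cluster_tables = {}
        if config.searchlight:
            stage = "cluster permutation"
            perm_seeds = np.random.SeedSequence(perm_seed.entropy).spawn(
                len(PREDICTOR_NAMES) * len(ANALYSIS_WINDOWS))
            i = 0
            for p in PREDICTOR_NAMES:
                for w in ANALYSIS_WINDOWS:
                    maps = np.stack(window_maps[p][w])
                    gsm = cluster_permutation(
                        maps, n_perm=config.n_permutations,
                        cluster_forming_p=config.cluster_forming_p,
                        alpha=config.alpha, seed=perm_seeds[i])
                    i += 1
                    cluster_tables[f"{p}:{w}"] = gsm.cluster_table
                    if outdir is not None:
                        from .io import write_beta_map
                        write_beta_map(Path(outdir) / f"group_t_{p}_{w}.nii.gz", gsm.t)

        stage = "decoding statistics"
        score_rows = []
        for roi in rois:
            vals = np.asarray(scores[roi])
            t, pv = group_onesample_t(vals)
            score_rows.append({"roi": roi, "mean_score": float(vals.mean()),
                               "t": float(t), "df": int(vals.size - 1), "p": float(pv)})
        bb = brain_behavior_correlation({r: np.asarray(v) for r, v in scores.items()},
                                        np.asarray(webers_fit), q=config.fdr_q)

        stage = "behavior statistics"
        momentum = operational_momentum(np.asarray(pse_div), np.asarray(pse_mul))

        summary = {
            "meta": {
                "package_version": __version__,
                "numpy": np.__version__,
                "seed": config.seed,
                "n_subjects": config.n_subjects,
                "df_group": config.n_subjects - 1,
                "elapsed_s": round(time.time() - t0, 2),
            },
            "design": {
                "n_conditions": len(conditions),
                "conditions": [c.label for c in conditions],
                "predictor_correlations": corr.round(6).to_dict(),
            },
            "rsa_roi": roi_table.to_dict(orient="records"),
            "clusters": {k: v.to_dict(orient="records") for k, v in cluster_tables.items()},
            "decoding": {
                "group": score_rows,
                "per_subject_scores": {r: [round(x, 6) for x in v] for r, v in scores.items()},
                "brain_behavior": bb.to_dict(orient="records"),
            },
            "behavior": {
                "weber_true": [round(w, 6) for w in webers_true],
                "weber_fit": [round(w, 6) for w in webers_fit],
                "pse_division": [round(x, 6) for x in pse_div],
                "pse_multiplication": [round(x, 6) for x in pse_mul],
                "operational_momentum": {
                    "t": momentum.t, "df": momentum.df, "p": momentum.p,
                    "cohens_d": momentum.cohens_d,
                },
            },
        }
        if outdir is not None:
            stage = "write artifacts"
            out = Path(outdir)
            out.mkdir(parents=True, exist_ok=True)
            config.to_json(out / "config.json")
            roi_table.to_csv(out / "rsa_roi.tsv", sep="\t", index=False)
            bb.to_csv(out / "brain_behavior.tsv", sep="\t", index=False)
            for key, tab in cluster_tables.items():
                tab.to_csv(out / f"clusters_{key.replace(':', '_')}.tsv",
                           sep="\t", index=False)
            (out / "summary.json").write_text(
                json.dumps(summary, indent=1, sort_keys=True) + "\n")
        return summary
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc


def _slice_fir(fir, voxel_indices):
    from .glm import FIRResults

    return FIRResults(fir.estimates[:, :, voxel_indices],
                      fir.condition_labels, fir.mode, run=fir.run)
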