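# Artifact formats

All coordinates are 0-based voxel indices; all times are seconds from
run start.

## Event tables (`*_events.tsv`, tab-separated)

| column          | type  | meaning                                        |
|-----------------|-------|------------------------------------------------|
| onset           | float | trial onset (sample presentation)              |
| condition       | str   | condition label, e.g. `12x2`, `48/4`           |
| condition_index | int   | index into the canonical condition ordering    |
| is_catch        | bool  | catch trial (shortened delay; never analyzed)  |
| probe_onset     | float | probe presentation time                        |
| probe_ratio     | float | probe : correct-result ratio (one of 8)        |
| correct_side    | str   | `smaller` / `larger`                           |

## Behavioral tables (`behavior.tsv`)

`operation` (multiply/divide), `operand` (2/4), `probe_ratio`,
`response` (smaller/larger), `correct` (bool).

## BOLD runs

`<prefix>.nii.gz` — 4-D NIfTI, grid (x, y, z) × volumes, float32;
`<prefix>.json` — sidecar with `tr`, `grid_shape`, `seed`;
`<prefix>_events.tsv` — the run's event table.

## FIR betas

`<prefix>.npz` — array `estimates` of shape (conditions, bins, voxels),
analyzed conditions in canonical order; `<prefix>.json` — sidecar with
`condition_labels`, `mode` (`concatenated`/`per_run`), `run`, `n_bins`.
Bins are 1-based; bin k covers (k−1)·2 s to k·2 s post-sample.

## Predictor sets

`<prefix>_{sample,operation,operand,result}.tsv` — labeled 10×10
matrices; `<prefix>.json` — labels, log base and condition list.

## Group outputs

`rsa_roi_effects.tsv` — long format: subject, roi, window, predictor,
beta. `group_rsa_roi.tsv` adds mean_beta, t, df, p, p_fdr,
significant. `decoding_scores.tsv` — subject, roi, score (Fisher-z).
`psychometric_fits.tsv` — subject, operation, pse, sigma, jnd,
n_trials, log_likelihood. `clusters_*.tsv` — label, sign, extent,
peak_t, cluster_p_fwe. `brain_behavior.tsv` — roi, r, p, df, p_fdr,
significant. `summary.json` — the machine-readable bundle
(meta/versions/seeds, design, rsa_roi, clusters, decoding, behavior).
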