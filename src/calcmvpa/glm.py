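"""Finite-impulse-response GLM for per-condition, per-latency patterns.

Responses to the 10 analyzed conditions (plus one catch condition) are
modeled with an FIR basis of 10 stick regressors of 2 s (= 1 TR) width
per condition, so no hemodynamic shape is assumed.  Slow drifts are
removed with a discrete-cosine basis (244 s cutoff) per run; in
concatenated mode each run additionally gets its own constant.
Estimation is ordinary least squares per voxel; an optional pooled
AR(1) prewhitening pass exists for fidelity experiments but is off by
default (OLS is unbiased and the downstream representational analyses
do not depend on whitening).

Two estimation modes mirror the two downstream uses: ``concatenated``
(one set of FIR estimates per condition and subject, input to the RSA)
and ``per_run`` (run-wise estimates, input to the leave-one-run-out
decoder).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignSpec, build_conditions
from .simulate import BoldRun

__all__ = ["FIRDesign", "FIRResults", "FIRBetas", "FIRModel",
           "build_fir_design", "dct_drift_basis", "fit_fir"]

CATCH_LABEL = "catch"
DRIFT_CUTOFF_S = 244.0


def dct_drift_basis(n_volumes: int, tr: float, cutoff: float = DRIFT_CUTOFF_S) -> np.ndarray:
    """Non-constant discrete-cosine drift regressors with period >= cutoff.

    Returns an (n_volumes, k) array with k = floor(2 * duration / cutoff);
    columns are unit-norm DCT-II basis vectors.
    """
    duration = n_volumes * tr
    k = int(2.0 * duration / cutoff)
    t = np.arange(n_volumes)
    cols = [np.cos(np.pi * j * (t + 0.5) / n_volumes) for j in range(1, k + 1)]
    if not cols:
        return np.zeros((n_volumes, 0))
    basis = np.stack(cols, axis=1)
    return basis / np.linalg.norm(basis, axis=0, keepdims=True)


@dataclass
class FIRDesign:
    """Design matrix with labeled columns for one or several runs."""

    matrix: np.ndarray
    column_labels: list[str]
    row_run: np.ndarray  # run index per row
    bin_width: float
    n_bins: int
    condition_labels: list[str]  # analyzed conditions, canonical order

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]

    def column_index(self, condition: str, bin_index: int) -> int:
        """Column of one condition x bin stick; ``bin_index`` is 1-based."""
        return self.column_labels.index(f"{condition}:bin{bin_index}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.column_labels)


def _check_rank(matrix: np.ndarray, labels: list[str]) -> None:
    rank = np.linalg.matrix_rank(matrix)
    if rank < matrix.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(matrix, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(matrix.shape) * np.finfo(float).eps
        bad = sorted(labels[p] for p in piv[diag.size - (matrix.shape[1] - rank):])
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {matrix.shape[1]}); "
            f"collinear columns involve: {bad}"
        )


def build_fir_design(
    events: pd.DataFrame | list[pd.DataFrame],
    spec: DesignSpec,
    confounds: np.ndarray | list[np.ndarray] | None = None,
    n_volumes_per_run: int | None = None,
    check_rank: bool = True,
) -> FIRDesign:
    """Build the FIR design for one run or a concatenation of runs.

    One 0/1 stick regressor per condition x bin, aligned to
    (trial onset + (bin-1) * bin_width) and sampled at the TR; catch
    trials are modeled as an 11th condition.  Each run contributes its
    own constant and its own discrete-cosine drift set.  ``confounds``
    (e.g. motion parameters) are appended per run as covariates of no
    interest.
    """
    event_tables = events if isinstance(events, list) else [events]
    if confounds is not None and not isinstance(confounds, list):
        confounds = [confounds]
    conditions = build_conditions(spec)
    cond_labels = [c.label for c in conditions]
    all_labels = cond_labels + [CATCH_LABEL]
    n_vol = n_volumes_per_run or spec.n_volumes_per_run
    n_bins = spec.n_fir_bins
    bin_width = spec.tr

    n_runs = len(event_tables)
    fir_cols = [f"{lab}:bin{b}" for lab in all_labels for b in range(1, n_bins + 1)]
    fir = np.zeros((n_runs * n_vol, len(fir_cols)))
    nuisance_blocks: list[np.ndarray] = []
    nuisance_labels: list[str] = []

    for r, ev in enumerate(event_tables):
        if len(ev) and ev["onset"].max() + spec.trial_length > n_vol * spec.tr + 1e-9:
            raise ValueError(f"run {r}: events extend beyond run duration")
        row0 = r * n_vol
        for onset, label, is_catch in zip(ev["onset"], ev["condition"], ev["is_catch"]):
            lab = CATCH_LABEL if is_catch else label
            if lab != CATCH_LABEL and lab not in cond_labels:
                raise ValueError(f"run {r}: unknown condition {lab!r}")
            base = all_labels.index(lab) * n_bins
            for b in range(n_bins):
                vol = int(round((onset + b * bin_width) / spec.tr))
                if 0 <= vol < n_vol:
                    fir[row0 + vol, base + b] = 1.0

        block = np.zeros((n_runs * n_vol, 1))
        block[row0:row0 + n_vol, 0] = 1.0
        nuisance_blocks.append(block)
        nuisance_labels.append(f"run{r}:constant")
        drift = dct_drift_basis(n_vol, spec.tr)
        dmat = np.zeros((n_runs * n_vol, drift.shape[1]))
        dmat[row0:row0 + n_vol] = drift
        nuisance_blocks.append(dmat)
        nuisance_labels.extend(f"run{r}:drift{k + 1}" for k in range(drift.shape[1]))
        if confounds is not None:
            conf = np.atleast_2d(np.asarray(confounds[r], dtype=float))
            if conf.shape[0] != n_vol:
                conf = conf.T
            cmat = np.zeros((n_runs * n_vol, conf.shape[1]))
            cmat[row0:row0 + n_vol] = conf
            nuisance_blocks.append(cmat)
            nuisance_labels.extend(f"run{r}:confound{k}" for k in range(conf.shape[1]))

    # drop FIR columns for conditions that never occur (e.g. catch-free runs)
    keep = fir.any(axis=0)
    fir_labels = [lab for lab, k in zip(fir_cols, keep) if k]
    matrix = np.column_stack([fir[:, keep]] + nuisance_blocks)
    labels = fir_labels + nuisance_labels
    if check_rank:
        _check_rank(matrix, labels)
    return FIRDesign(matrix, labels, np.repeat(np.arange(n_runs), n_vol),
                     bin_width, n_bins, cond_labels)


@dataclass
class FIRResults:
    """FIR beta estimates: conditions x bins x voxels.

    ``estimates`` covers the analyzed conditions in canonical order;
    the catch condition is estimated but held separately and never
    analyzed.  ``bin b`` (1-based) covers (b-1)*2 s to b*2 s after the
    sample.
    """

    estimates: np.ndarray
    condition_labels: list[str]
    mode: str  # "concatenated" or "per_run"
    run: int | None = None
    residual_variance: np.ndarray | None = None
    design: FIRDesign | None = None

    @property
    def n_bins(self) -> int:
        return self.estimates.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.estimates.shape[2]

    def patterns(self, bin_index: int) -> np.ndarray:
        """(n_conditions, n_voxels) pattern matrix at a 1-based bin."""
        return self.estimates[:, bin_index - 1, :]

    def summary(self) -> str:
        lines = [
            "FIR GLM results",
            f"  mode: {self.mode}" + (f" (run {self.run})" if self.run is not None else ""),
            f"  conditions: {len(self.condition_labels)} analyzed + catch",
            f"  bins: {self.n_bins}  voxels: {self.n_voxels}",
            "",
            "  mean |beta| per bin (across conditions and voxels):",
        ]
        mb = np.abs(self.estimates).mean(axis=(0, 2))
        lines += [f"    bin {b + 1}: {mb[b]:.4f}" for b in range(self.n_bins)]
        return "\n".join(lines)


FIRBetas = FIRResults  # domain-type alias


class FIRModel:
    """FIR GLM over one subject's runs.

    Parameters
    ----------
    runs : list of BoldRun
    spec : DesignSpec
    confounds : optional list of per-run confound arrays (volumes x k)
    """

    def __init__(self, runs: list[BoldRun], spec: DesignSpec,
                 confounds: list[np.ndarray] | None = None):
        if not runs:
            raise ValueError("need at least one run")
        self.runs = runs
        self.spec = spec
        self.confounds = confounds

    def fit(self, mode: str = "concatenated", prewhiten: bool = False):
        """Estimate FIR betas.

        mode="concatenated" stacks all runs into a single GLM with
        per-run constants and returns one :class:`FIRResults`;
        mode="per_run" fits each run separately and returns a list of
        :class:`FIRResults`, one per run.
        """
        if mode == "concatenated":
            data = np.vstack([r.data for r in self.runs])
            self._check_nan()
            design = build_fir_design([r.events for r in self.runs], self.spec,
                                      confounds=self.confounds,
                                      n_volumes_per_run=self.runs[0].n_volumes)
            return fit_fir(data, design, mode="concatenated", prewhiten=prewhiten)
        if mode == "per_run":
            self._check_nan()
            out = []
            for i, run in enumerate(self.runs):
                conf = [self.confounds[i]] if self.confounds is not None else None
                design = build_fir_design([run.events], self.spec, confounds=conf,
                                          n_volumes_per_run=run.n_volumes)
                res = fit_fir(run.data, design, mode="per_run", prewhiten=prewhiten)
                res.run = i
                out.append(res)
            return out
        raise ValueError(f"unknown mode {mode!r}")

    def _check_nan(self) -> None:
        for i, run in enumerate(self.runs):
            if not np.isfinite(run.data).all():
                bad = np.unique(np.argwhere(~np.isfinite(run.data))[:, 1])
                raise ValueError(f"non-finite data in run {i}, voxel(s) {bad[:10].tolist()}")


def _ols(design: np.ndarray, data: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, data, rcond=None)
    return beta


def fit_fir(data: np.ndarray, design: FIRDesign, mode: str = "concatenated",
            prewhiten: bool = False) -> FIRResults:
    """OLS fit of an FIR design to a (volumes x voxels) data array."""
    if data.shape[0] != design.matrix.shape[0]:
        raise ValueError("design rows must equal total volumes")
    if not np.isfinite(data).all():
        bad = np.unique(np.argwhere(~np.isfinite(data))[:, 1])
        raise ValueError(f"non-finite data in voxel(s) {bad[:10].tolist()}")
    X = design.matrix
    beta = _ols(X, data)
    if prewhiten:
        resid = data - X @ beta
        num = (resid[1:] * resid[:-1]).sum()
        den = (resid ** 2).sum()
        rho = float(num / den) if den > 0 else 0.0
        rho = np.clip(rho, -0.99, 0.99)
        # Cochrane-Orcutt-style transform within each run
        Xw, yw = X.copy(), data.copy()
        for r in np.unique(design.row_run):
            rows = np.flatnonzero(design.row_run == r)
            Xw[rows[1:]] -= rho * X[rows[:-1]]
            yw[rows[1:]] -= rho * data[rows[:-1]]
        beta = _ols(Xw, yw)

    resid = data - X @ beta
    dof = max(X.shape[0] - X.shape[1], 1)
    resid_var = (resid ** 2).sum(axis=0) / dof

    n_bins = design.n_bins
    n_vox = data.shape[1]
    est = np.zeros((len(design.condition_labels), n_bins, n_vox))
    for ci, lab in enumerate(design.condition_labels):
        for b in range(1, n_bins + 1):
            name = f"{lab}:bin{b}"
            if name in design.column_labels:
                est[ci, b - 1] = beta[design.column_labels.index(name)]
    return FIRResults(est, list(design.condition_labels), mode,
                      residual_variance=resid_var, design=design)
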