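"""Time-resolved representational similarity regression.

For each FIR time bin, the pairwise correlation distances between the
10 condition patterns (after subtracting each voxel's mean across
conditions) form a neural RDM.  Its vectorized strict upper triangle
(45 values) is regressed on the four z-scored predictor RDMs (sample,
operation, operand, result) in a multiple regression, so each beta
reflects variance that predictor explains on top of the other three.
The analysis runs either in a searchlight (sphere of radius 3 voxels
around every in-mask voxel) or on a region of interest, and bin-wise
betas are averaged into early (bins 1-2), middle (bins 3-4) and late
(bins 5-6) delay windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .design import PREDICTOR_NAMES, PredictorSet
from .glm import FIRResults

__all__ = [
    "WINDOWS", "NeuralRDM", "RDMRegression", "RDMRegressionResults",
    "RSAEffects", "neural_rdm", "rdm_regression", "sphere_offsets",
    "searchlight_rsa", "SearchlightResult", "roi_rsa", "window_average",
]

logger = logging.getLogger(__name__)

#: 1-based FIR bins per delay window; bin k covers (k-1)*2 s to k*2 s
#: after the sample.
WINDOWS = {"early": (1, 2), "middle": (3, 4), "late": (5, 6)}


@dataclass
class NeuralRDM:
    """Correlation-distance matrix between condition patterns at one bin."""

    matrix: np.ndarray
    bin: int
    voxel_set: str = ""

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.matrix).any())

    def vectorized(self) -> np.ndarray:
        iu = np.triu_indices(self.matrix.shape[0], k=1)
        return self.matrix[iu]


def neural_rdm(betas: FIRResults | np.ndarray, bin_index: int = 1,
               voxel_indices: np.ndarray | None = None,
               voxel_set: str = "") -> NeuralRDM:
    """Correlation-distance RDM of condition patterns at one FIR bin.

    Voxel-wise scaling subtracts each voxel's mean across the 10
    conditions, then distance(a, b) = 1 - Pearson(pattern_a, pattern_b)
    across voxels.  Conditions whose centered pattern has zero variance
    yield NaN entries (flagged, propagated as missing).
    """
    patterns = betas.patterns(bin_index) if isinstance(betas, FIRResults) else np.asarray(betas, float)
    if voxel_indices is not None:
        patterns = patterns[:, voxel_indices]
    n_cond, n_vox = patterns.shape
    if n_vox < 2:
        raise ValueError("need at least 2 voxels for a correlation distance")
    centered = patterns - patterns.mean(axis=0, keepdims=True)
    demeaned = centered - centered.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(demeaned, axis=1)
    matrix = np.full((n_cond, n_cond), np.nan)
    ok = norms > 0
    if ok.any():
        u = np.zeros_like(demeaned)
        u[ok] = demeaned[ok] / norms[ok, None]
        corr = u @ u.T
        matrix[np.ix_(ok, ok)] = 1.0 - corr[np.ix_(ok, ok)]
    np.fill_diagonal(matrix, np.where(ok, 0.0, np.nan))
    return NeuralRDM(matrix, bin_index, voxel_set)


def _zscore(v: np.ndarray, name: str = "vector") -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError(f"{name} has zero variance; z-transform undefined")
    return (v - v.mean()) / sd


class RDMRegression:
    """Multiple regression of one neural RDM on the four predictor RDMs.

    Both the neural dissimilarity vector and each predictor vector
    (strict upper triangles) are z-transformed; an intercept is
    included, making the fit invariant to the neural vector's mean.
    """

    def __init__(self, neural: NeuralRDM | np.ndarray, predictors: PredictorSet):
        if isinstance(neural, NeuralRDM):
            if neural.has_missing:
                raise ValueError("neural RDM contains missing entries")
            vec = neural.vectorized()
        else:
            neural = np.asarray(neural, float)
            vec = neural[np.triu_indices(neural.shape[0], k=1)] if neural.ndim == 2 else neural
        self.neural_vector = vec
        self.predictors = predictors
        X = predictors.stacked(PREDICTOR_NAMES)
        if X.shape[0] != vec.size:
            raise ValueError("predictor and neural RDM shapes do not match")
        Xz = np.column_stack([_zscore(X[:, j], PREDICTOR_NAMES[j]) for j in range(X.shape[1])])
        self.design = np.column_stack([np.ones(vec.size), Xz])
        if np.linalg.matrix_rank(self.design) < self.design.shape[1]:
            raise ValueError("singular predictor set: predictors are collinear")

    def fit(self) -> "RDMRegressionResults":
        y = _zscore(self.neural_vector, "neural dissimilarity vector")
        coef, *_ = np.linalg.lstsq(self.design, y, rcond=None)
        fitted = self.design @ coef
        ss_res = float(((y - fitted) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        betas = dict(zip(PREDICTOR_NAMES, coef[1:]))
        return RDMRegressionResults(betas, float(coef[0]), r2, self)


@dataclass
class RDMRegressionResults:
    """Per-predictor effect sizes (beta) from one RDM regression."""

    betas: dict[str, float]
    intercept: float
    rsquared: float
    model: RDMRegression | None = None

    def beta_array(self) -> np.ndarray:
        return np.array([self.betas[n] for n in PREDICTOR_NAMES])

    def summary(self) -> str:
        lines = ["RDM regression (45 pairs, z-transformed)", f"  R^2 = {self.rsquared:.4f}"]
        lines += [f"  beta[{n}] = {self.betas[n]:+.4f}" for n in PREDICTOR_NAMES]
        return "\n".join(lines)


def rdm_regression(neural: NeuralRDM | np.ndarray, predictors: PredictorSet) -> dict[str, float]:
    """Convenience wrapper returning the four betas."""
    return RDMRegression(neural, predictors).fit().betas


def _predictor_pinv(predictors: PredictorSet) -> np.ndarray:
    """Precompute pinv of the [1 | z-scored predictors] design (6x45 -> 5x45)."""
    X = predictors.stacked(PREDICTOR_NAMES)
    Xz = np.column_stack([_zscore(X[:, j]) for j in range(X.shape[1])])
    design = np.column_stack([np.ones(X.shape[0]), Xz])
    return np.linalg.pinv(design)


def sphere_offsets(radius: int) -> np.ndarray:
    """Integer lattice offsets with squared distance <= radius^2 (center included)."""
    r = int(radius)
    rng = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(rng, rng, rng, indexing="ij")
    keep = dx ** 2 + dy ** 2 + dz ** 2 <= radius ** 2
    return np.column_stack([dx[keep], dy[keep], dz[keep]])


@dataclass
class SearchlightResult:
    """Per-predictor beta maps per bin; NaN outside the mask or at skipped centers."""

    beta_maps: np.ndarray  # (n_predictors, n_bins, *grid_shape)
    predictor_names: tuple[str, ...]
    bins: list[int]
    skipped: list[tuple[int, int, int]] = field(default_factory=list)

    def map_for(self, predictor: str, bin_index: int) -> np.ndarray:
        return self.beta_maps[self.predictor_names.index(predictor),
                              self.bins.index(bin_index)]

    def window_map(self, predictor: str, window: str) -> np.ndarray:
        lo, hi = WINDOWS[window]
        maps = [self.map_for(predictor, b) for b in range(lo, hi + 1)]
        return np.mean(maps, axis=0)


def searchlight_rsa(
    betas: FIRResults,
    mask: np.ndarray,
    predictors: PredictorSet,
    radius_voxels: int = 3,
    bins: list[int] | None = None,
) -> SearchlightResult:
    """Map RDM-regression betas with a spherical searchlight.

    For every in-mask center voxel, the in-mask voxels within a
    Euclidean radius of ``radius_voxels`` (boundary and center
    included) form the pattern; the resulting neural RDM is regressed
    on the predictors and the betas written at the center.  Centers
    with fewer than 2 voxels or a degenerate RDM are skipped and
    logged.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be a 3-D voxel grid")
    if not mask.any():
        raise ValueError("mask is empty")
    grid = mask.shape
    if int(np.prod(grid)) != betas.n_voxels:
        raise ValueError("mask grid size must equal voxel count of the betas")
    bins = bins or list(range(1, betas.n_bins + 1))
    offsets = sphere_offsets(radius_voxels)
    pinv = _predictor_pinv(predictors)
    lin = np.arange(int(np.prod(grid))).reshape(grid)
    centers = np.argwhere(mask)
    out = np.full((len(PREDICTOR_NAMES), len(bins)) + grid, np.nan)
    skipped: list[tuple[int, int, int]] = []

    patterns_by_bin = [betas.patterns(b) for b in bins]
    iu = np.triu_indices(patterns_by_bin[0].shape[0], k=1)

    for cx, cy, cz in centers:
        nb = offsets + np.array([cx, cy, cz])
        valid = ((nb >= 0) & (nb < np.array(grid))).all(axis=1)
        nb = nb[valid]
        nb = nb[mask[nb[:, 0], nb[:, 1], nb[:, 2]]]
        if nb.shape[0] < 2:
            skipped.append((int(cx), int(cy), int(cz)))
            logger.info("searchlight center (%d,%d,%d) skipped: %d voxel(s)",
                        cx, cy, cz, nb.shape[0])
            continue
        vox = lin[nb[:, 0], nb[:, 1], nb[:, 2]]
        degenerate = False
        for bi, patt in enumerate(patterns_by_bin):
            rdm = neural_rdm(patt[:, vox])
            vec = rdm.matrix[iu]
            if np.isnan(vec).any() or vec.std() == 0:
                degenerate = True
                continue
            z = (vec - vec.mean()) / vec.std()
            coef = pinv @ z
            out[:, bi, cx, cy, cz] = coef[1:]
        if degenerate:
            skipped.append((int(cx), int(cy), int(cz)))
            logger.info("searchlight center (%d,%d,%d): degenerate RDM", cx, cy, cz)
    return SearchlightResult(out, PREDICTOR_NAMES, list(bins), skipped)


@dataclass
class RSAEffects:
    """Bin-wise and window-averaged betas for one voxel set (ROI)."""

    betas: np.ndarray  # (n_bins, n_predictors)
    bins: list[int]
    predictor_names: tuple[str, ...] = PREDICTOR_NAMES
    voxel_set: str = ""

    def beta(self, predictor: str, bin_index: int) -> float:
        return float(self.betas[self.bins.index(bin_index),
                                self.predictor_names.index(predictor)])

    def window_means(self) -> dict[str, dict[str, float]]:
        return window_average(self)


def roi_rsa(betas: FIRResults, predictors: PredictorSet,
            voxel_indices: np.ndarray | None = None,
            bins: list[int] | None = None, voxel_set: str = "") -> RSAEffects:
    """RDM regression on an ROI's pattern at each FIR bin."""
    bins = bins or list(range(1, betas.n_bins + 1))
    out = np.zeros((len(bins), len(PREDICTOR_NAMES)))
    for i, b in enumerate(bins):
        rdm = neural_rdm(betas, b, voxel_indices=voxel_indices, voxel_set=voxel_set)
        res = RDMRegression(rdm, predictors).fit()
        out[i] = res.beta_array()
    return RSAEffects(out, list(bins), voxel_set=voxel_set)


def window_average(effects: RSAEffects) -> dict[str, dict[str, float]]:
    """Average bin-wise betas into the early/middle/late delay windows.

    early = mean(bins 1, 2); middle = mean(bins 3, 4); late =
    mean(bins 5, 6).  Raises if a required bin is absent.
    """
    out: dict[str, dict[str, float]] = {}
    for window, (lo, hi) in WINDOWS.items():
        rows = []
        for b in range(lo, hi + 1):
            if b not in effects.bins:
                raise ValueError(f"bin {b} required for window {window!r} is missing")
            rows.append(effects.betas[effects.bins.index(b)])
        mean = np.mean(rows, axis=0)
        out[window] = dict(zip(effects.predictor_names, mean))
    return out
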