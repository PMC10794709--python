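"""Cross-temporal and cross-attribute numerosity decoding.

A linear support-vector regression (C = 1) is trained on run-wise FIR
patterns to predict the z-scored logarithm of numerosity (of either
the sample or the result), with leave-one-run-out cross-validation and
voxel-wise z-scoring across conditions within each set.  Performance
is the Fisher-z transformed Pearson correlation between true and
predicted labels, averaged over folds.  Training and testing can use
any combination of the 10 FIR bins, giving a 10 x 10 generalization
matrix; the sample<->result cross-decoding score averages the cells
where sample-evoked activity (bins 2-4, i.e. 2-8 s post-sample) is
paired with later result-related activity (bins 4-6, 6-12 s), with the
bins non-overlapping and separated by at least one intermediate bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVR

from .design import Condition
from .glm import FIRResults
from .simulate import condition_attribute_values

__all__ = [
    "DecoderSpec", "GeneralizationMatrix", "numerosity_labels",
    "fit_predict_numerosity", "generalization_matrix",
    "valid_cross_cells", "cross_decoding_score", "fisher_z",
]

logger = logging.getLogger(__name__)

SAMPLE_TRAIN_BINS = (2, 3, 4)
RESULT_TEST_BINS = (4, 5, 6)
MIN_BIN_SEPARATION = 2  # non-overlapping with >= 1 bin in between


@dataclass
class DecoderSpec:
    """Linear SVR decoder configuration with leave-one-run-out CV."""

    C: float = 1.0
    epsilon: float = 0.1
    #: if True, apply the training-set voxel-wise z-scoring statistics to
    #: the test set instead of recomputing them per set.
    scale_test_with_train: bool = False

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")

    def make_estimator(self) -> SVR:
        return SVR(kernel="linear", C=self.C, epsilon=self.epsilon)


def fisher_z(r: float | np.ndarray, clip: float = 1.0 - 1e-7) -> np.ndarray:
    """atanh of a correlation, clipped away from +/-1 to stay finite."""
    return np.arctanh(np.clip(r, -clip, clip))


def numerosity_labels(conditions: list[Condition], attr: str) -> np.ndarray:
    """z-scored log numerosity per condition, for attr 'sample' or 'result'."""
    if attr not in ("sample", "result"):
        raise ValueError("decoded attribute must be 'sample' or 'result'")
    return condition_attribute_values(conditions)[attr]


def _zscale_voxelwise(patterns: np.ndarray) -> np.ndarray:
    """z-score each voxel across the condition rows of one set."""
    mu = patterns.mean(axis=0, keepdims=True)
    sd = patterns.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (patterns - mu) / sd


def fit_predict_numerosity(
    run_betas: list[FIRResults],
    conditions: list[Condition],
    train_bin: int,
    test_bin: int,
    train_attr: str = "sample",
    test_attr: str = "result",
    spec: DecoderSpec | None = None,
) -> float:
    """Leave-one-run-out decoding score for one (train bin, test bin) cell.

    Each fold trains the SVR on the patterns of all but one run at
    ``train_bin`` labeled by ``train_attr`` and predicts the held-out
    run's patterns at ``test_bin`` labeled by ``test_attr``.  The fold
    score is the Fisher-z of the Pearson correlation between true and
    predicted labels; folds with constant predictions (or constant true
    labels) score 0 and are logged.  Returns the fold average.
    """
    spec = spec or DecoderSpec()
    if len(run_betas) < 2:
        raise ValueError("leave-one-run-out CV needs at least 2 runs")
    y_train_cond = numerosity_labels(conditions, train_attr)
    y_test_cond = numerosity_labels(conditions, test_attr)
    if np.ptp(y_train_cond) == 0:
        raise ValueError("training labels do not vary")

    scores = []
    n_runs = len(run_betas)
    for held_out in range(n_runs):
        train_parts, mus, sds = [], [], []
        for r in range(n_runs):
            if r == held_out:
                continue
            p = run_betas[r].patterns(train_bin)
            train_parts.append(p)
        X_train = np.vstack(train_parts)
        mu = X_train.mean(axis=0, keepdims=True)
        sd = X_train.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        X_train = (X_train - mu) / sd
        y_train = np.tile(y_train_cond, n_runs - 1)

        X_test = run_betas[held_out].patterns(test_bin)
        if spec.scale_test_with_train:
            X_test = (X_test - mu) / sd
        else:
            X_test = _zscale_voxelwise(X_test)

        est = spec.make_estimator()
        est.fit(X_train, y_train)
        pred = est.predict(X_test)
        if np.ptp(pred) == 0 or np.ptp(y_test_cond) == 0:
            logger.info("fold %d: constant predictions; score set to 0", held_out)
            scores.append(0.0)
            continue
        r = np.corrcoef(y_test_cond, pred)[0, 1]
        scores.append(float(fisher_z(r)))
    return float(np.mean(scores))


@dataclass
class GeneralizationMatrix:
    """Train-bin x test-bin Fisher-z decoding scores (NaN = not computed)."""

    scores: np.ndarray
    train_attr: str
    test_attr: str
    bins: list[int] = field(default_factory=lambda: list(range(1, 11)))

    def score(self, train_bin: int, test_bin: int) -> float:
        return float(self.scores[self.bins.index(train_bin), self.bins.index(test_bin)])


def generalization_matrix(
    run_betas: list[FIRResults],
    conditions: list[Condition],
    train_attr: str,
    test_attr: str,
    spec: DecoderSpec | None = None,
    train_bins: list[int] | None = None,
    test_bins: list[int] | None = None,
) -> GeneralizationMatrix:
    """Decoding scores for all (train bin, test bin) combinations.

    By default all 10 x 10 combinations are computed; restricting
    ``train_bins``/``test_bins`` leaves the other cells NaN (used when
    only the cross-decoding window cells are needed).
    """
    n_bins = run_betas[0].n_bins
    all_bins = list(range(1, n_bins + 1))
    train_bins = train_bins or all_bins
    test_bins = test_bins or all_bins
    scores = np.full((n_bins, n_bins), np.nan)
    for i in train_bins:
        for j in test_bins:
            scores[i - 1, j - 1] = fit_predict_numerosity(
                run_betas, conditions, i, j, train_attr, test_attr, spec)
    return GeneralizationMatrix(scores, train_attr, test_attr, all_bins)


def valid_cross_cells(
    sample_bins: tuple[int, ...] = SAMPLE_TRAIN_BINS,
    result_bins: tuple[int, ...] = RESULT_TEST_BINS,
    min_separation: int = MIN_BIN_SEPARATION,
) -> list[tuple[int, int]]:
    """(sample bin, result bin) pairs entering the cross-decoding average.

    Pairs must be non-overlapping and separated by at least one
    intermediate bin (|sample - result| >= 2 at defaults).
    """
    cells = [(s, r) for s in sample_bins for r in result_bins
             if s != r and abs(s - r) >= min_separation]
    return cells


def cross_decoding_score(
    m_sample_to_result: GeneralizationMatrix,
    m_result_to_sample: GeneralizationMatrix | None = None,
    sample_bins: tuple[int, ...] = SAMPLE_TRAIN_BINS,
    result_bins: tuple[int, ...] = RESULT_TEST_BINS,
) -> float:
    """Average cross-decoding score over the windowed cells.

    For the sample->result direction the sample bin is the train bin
    and the result bin the test bin; for result->sample the roles swap.
    Both directions are averaged when given.
    """
    cells = valid_cross_cells(sample_bins, result_bins)
    if not cells:
        raise ValueError("no valid cells under the given window constraints")
    values = [m_sample_to_result.score(s, r) for s, r in cells]
    if m_result_to_sample is not None:
        values += [m_result_to_sample.score(r, s) for s, r in cells]
    arr = np.asarray(values, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("cross-decoding window cells were not all computed")
    return float(arr.mean())
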