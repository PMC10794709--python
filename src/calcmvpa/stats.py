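"""Group-level inference for the pattern analyses.

Subject-wise effect estimates (RSA betas, decoding scores) are tested
against 0 with two-tailed one-sample t-tests (df = n - 1).  ROI
families are corrected with Benjamini-Hochberg FDR (e.g. 32 subregions
x 2 delay windows).  Searchlight beta maps are corrected at the
cluster level by sign-flip permutation: clusters are 6-connected
components of |t| above the two-tailed cluster-forming threshold, and
their extent is compared against the permutation null of the maximum
cluster extent over both signs.  The brain-behavior analysis
correlates per-subject cross-decoding scores with behavioral Weber
fractions per ROI (Pearson, FDR-corrected across ROIs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = ["group_onesample_t", "bh_fdr", "GroupStatMap",
           "cluster_permutation", "brain_behavior_correlation"]


def group_onesample_t(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-tailed one-sample t-test against 0 over the first axis.

    ``values`` is (n_subjects,) or (n_subjects, ...); returns (t, p)
    with the subject axis removed.  Zero-variance input raises.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if not np.isfinite(values).all():
        raise ValueError("non-finite values in group test")
    sd = values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero variance across subjects: t undefined")
    res = sstats.ttest_1samp(values, 0.0, axis=0)
    return np.asarray(res.statistic), np.asarray(res.pvalue)


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR over one family of p-values.

    The family is all inputs; returns (reject mask, adjusted p).
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject, p_adj


@dataclass
class GroupStatMap:
    """Group t-map with permutation-corrected clusters."""

    t: np.ndarray
    p: np.ndarray
    cluster_labels: np.ndarray
    cluster_table: pd.DataFrame  # label, sign, extent, peak_t, cluster_p_fwe
    n_subjects: int
    n_permutations: int
    threshold_t: float

    @property
    def df(self) -> int:
        return self.n_subjects - 1

    def significant_mask(self, alpha: float = 0.05) -> np.ndarray:
        sig = np.zeros(self.t.shape, dtype=bool)
        for _, row in self.cluster_table.iterrows():
            if row["cluster_p_fwe"] <= alpha:
                sig |= self.cluster_labels == row["label"]
        return sig

    def summary(self) -> str:
        lines = [
            f"Sign-flip cluster permutation (n = {self.n_subjects}, df = {self.df}, "
            f"{self.n_permutations} permutations, |t| > {self.threshold_t:.3f})",
            f"  clusters found: {len(self.cluster_table)}",
        ]
        for _, row in self.cluster_table.iterrows():
            lines.append(
                f"  cluster {int(row['label'])} ({row['sign']}): extent "
                f"{int(row['extent'])}, peak t = {row['peak_t']:.2f}, "
                f"p_FWE = {row['cluster_p_fwe']:.4f}"
            )
        return "\n".join(lines)


_STRUCTURE_6 = ndimage.generate_binary_structure(3, 1)  # face connectivity


def _max_cluster_extent(t_map: np.ndarray, thr: float) -> int:
    best = 0
    for sign in (1.0, -1.0):
        lab, n = ndimage.label(sign * t_map > thr, structure=_STRUCTURE_6)
        if n:
            best = max(best, int(np.bincount(lab.ravel())[1:].max()))
    return best


def cluster_permutation(
    subject_maps: np.ndarray,
    n_perm: int = 5000,
    cluster_forming_p: float = 0.01,
    alpha: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
) -> GroupStatMap:
    """Cluster-extent correction of a group t-map by sign flipping.

    ``subject_maps`` is (n_subjects, nx, ny, nz).  Observed clusters
    are 6-connected components of the two-tailed suprathreshold |t|
    map (positive and negative searched separately); the null is the
    maximum cluster extent over both signs from random whole-map sign
    flips, so ``cluster_p_fwe = (1 + #{null >= extent}) / (n_perm + 1)``
    and can never be 0.
    """
    maps = np.asarray(subject_maps, dtype=float)
    if maps.ndim != 4:
        raise ValueError("subject_maps must be (n_subjects, nx, ny, nz)")
    if maps.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if not np.isfinite(maps).all():
        raise ValueError("non-finite entries in subject maps")
    if n_perm < 100:
        warnings.warn(f"only {n_perm} permutations: p-values are coarse",
                      stacklevel=2)
    n_subj = maps.shape[0]
    thr = float(sstats.t.isf(cluster_forming_p / 2, n_subj - 1))

    t_obs, p_obs = group_onesample_t(maps)

    labels = np.zeros(t_obs.shape, dtype=int)
    rows = []
    next_label = 1
    for sign, name in ((1.0, "positive"), (-1.0, "negative")):
        lab, n = ndimage.label(sign * t_obs > thr, structure=_STRUCTURE_6)
        for k in range(1, n + 1):
            comp = lab == k
            labels[comp] = next_label
            peak = t_obs[comp][np.argmax(np.abs(t_obs[comp]))]
            rows.append({"label": next_label, "sign": name,
                         "extent": int(comp.sum()), "peak_t": float(peak)})
            next_label += 1

    rng = np.random.default_rng(seed)
    flat = maps.reshape(n_subj, -1)
    null_max = np.zeros(n_perm, dtype=int)
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_subj)
        flipped = flat * signs[:, None]
        mean = flipped.mean(axis=0)
        sd = flipped.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = np.where(sd > 0, mean / (sd / np.sqrt(n_subj)), 0.0)
        null_max[i] = _max_cluster_extent(t_perm.reshape(t_obs.shape), thr)

    for row in rows:
        row["cluster_p_fwe"] = float(
            (1 + np.sum(null_max >= row["extent"])) / (n_perm + 1))
    table = pd.DataFrame(rows, columns=["label", "sign", "extent", "peak_t",
                                        "cluster_p_fwe"])
    return GroupStatMap(t_obs, p_obs, labels, table, n_subj, n_perm, thr)


def brain_behavior_correlation(
    scores: pd.DataFrame | dict[str, np.ndarray],
    webers: np.ndarray,
    q: float = 0.05,
) -> pd.DataFrame:
    """Across-subject Pearson correlation of decoding scores with Weber fractions.

    ``scores`` maps ROI name -> per-subject cross-decoding scores
    (columns of a DataFrame or dict values); ``webers`` is the matched
    per-subject Weber fractions.  Returns a table with r, two-tailed p
    (t transform of r), BH-FDR adjusted p and rejection mask across
    all ROIs.
    """
    if isinstance(scores, dict):
        scores = pd.DataFrame(scores)
    webers = np.asarray(webers, dtype=float)
    n = webers.size
    if n < 3:
        raise ValueError("need at least 3 subjects for a correlation test")
    if len(scores) != n:
        raise ValueError("scores and webers must have matching subjects")
    rows = []
    for roi in scores.columns:
        x = scores[roi].to_numpy(dtype=float)
        if not (np.isfinite(x).all() and np.isfinite(webers).all()):
            raise ValueError(f"non-finite values for ROI {roi!r}")
        if np.ptp(x) == 0 or np.ptp(webers) == 0:
            raise ValueError(f"constant input for ROI {roi!r}: r undefined")
        r, p = sstats.pearsonr(x, webers)
        rows.append({"roi": roi, "r": float(r), "p": float(p), "df": n - 2})
    table = pd.DataFrame(rows)
    reject, p_adj = bh_fdr(table["p"].to_numpy(), q=q)
    table["p_fdr"] = p_adj
    table["significant"] = reject
    return table
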