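"""Psychometrics of the probe-comparison task.

The probe differs from the correct result by one of 8 ratios; the
proportion of "larger" responses as a function of log ratio is fitted
with a cumulative-Gaussian psychometric function

    P(larger) = lapse + (1 - 2*lapse) * Phi((log ratio - pse) / sigma)

by maximum likelihood under a binomial model.  The point of subjective
equality (pse) indexes operation-dependent bias (operational
momentum); the just-noticeable difference jnd = sigma * Phi^-1(0.75)
on the log scale is the Weber fraction of the comparison.  The lapse
rate is fixed at 0 by default and can be freed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm, t as t_dist

__all__ = ["PsychometricModel", "PsychometricResults", "fit_psychometric",
           "jnd_weber", "operational_momentum", "MomentumResult"]

JND_QUANTILE = norm.ppf(0.75)
SIGMA_FLOOR = 1e-3
SIGMA_CEIL = 20.0


@dataclass
class PsychometricResults:
    """ML estimates of one psychometric function."""

    pse: float
    sigma: float
    lapse: float
    n_trials: int
    log_likelihood: float
    operation: str = "pooled"
    boundary: bool = False

    @property
    def jnd(self) -> float:
        """Log-scale JND: the Weber fraction of the comparison."""
        return self.sigma * JND_QUANTILE

    def predict(self, ratios: np.ndarray) -> np.ndarray:
        x = np.log(np.asarray(ratios, dtype=float))
        return self.lapse + (1 - 2 * self.lapse) * norm.cdf((x - self.pse) / self.sigma)

    def summary(self) -> str:
        lines = [
            f"Psychometric fit ({self.operation} trials, n = {self.n_trials})",
            f"  PSE   = {self.pse:+.4f} (log-ratio units)",
            f"  sigma = {self.sigma:.4f}",
            f"  JND / Weber fraction = {self.jnd:.4f}",
            f"  lapse = {self.lapse:.4f}",
            f"  log-likelihood = {self.log_likelihood:.2f}",
        ]
        if self.boundary:
            lines.append("  WARNING: estimate at parameter boundary")
        return "\n".join(lines)


class PsychometricModel:
    """Cumulative-Gaussian psychometric model of comparison responses.

    Parameters
    ----------
    data : BehavioralData frame with columns ``probe_ratio``,
        ``response`` ("smaller"/"larger") and ``operation``.
    operation : "pooled" (default), "multiply" or "divide" trial filter.
    free_lapse : fit the lapse rate instead of fixing it at 0.
    """

    def __init__(self, data: pd.DataFrame, operation: str = "pooled",
                 free_lapse: bool = False):
        if operation not in ("pooled", "multiply", "divide"):
            raise ValueError(f"unknown operation filter {operation!r}")
        if operation != "pooled":
            data = data[data["operation"] == operation]
        grouped = (data.assign(larger=(data["response"] == "larger"))
                       .groupby("probe_ratio")["larger"].agg(["sum", "count"]))
        if len(grouped) < 2:
            raise ValueError("need responses at >= 2 distinct ratios")
        if grouped["sum"].sum() == 0 or (grouped["count"] - grouped["sum"]).sum() == 0:
            raise ValueError("need responses on both sides")
        self.log_ratios = np.log(grouped.index.to_numpy(dtype=float))
        self.n_larger = grouped["sum"].to_numpy(dtype=float)
        self.n_total = grouped["count"].to_numpy(dtype=float)
        self.operation = operation
        self.free_lapse = free_lapse

    def _nll(self, params: np.ndarray) -> float:
        pse, log_sigma = params[0], params[1]
        lapse = params[2] if self.free_lapse else 0.0
        sigma = np.exp(log_sigma)
        p = lapse + (1 - 2 * lapse) * norm.cdf((self.log_ratios - pse) / sigma)
        p = np.clip(p, 1e-10, 1 - 1e-10)
        ll = self.n_larger * np.log(p) + (self.n_total - self.n_larger) * np.log1p(-p)
        return -float(ll.sum())

    def fit(self) -> PsychometricResults:
        """Deterministic multi-start ML fit."""
        starts = [(0.0, np.log(s0)) for s0 in (0.08, 0.3, 0.9)]
        bounds = [(-2.0, 2.0), (np.log(SIGMA_FLOOR), np.log(SIGMA_CEIL))]
        if self.free_lapse:
            starts = [s + (0.02,) for s in starts]
            bounds.append((0.0, 0.4999))
        best = None
        for x0 in starts:
            res = optimize.minimize(self._nll, np.array(x0), method="L-BFGS-B",
                                    bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
        pse, log_sigma = best.x[0], best.x[1]
        lapse = float(best.x[2]) if self.free_lapse else 0.0
        sigma = float(np.exp(log_sigma))
        boundary = sigma <= SIGMA_FLOOR * 1.01 or sigma >= SIGMA_CEIL * 0.99
        if boundary:
            warnings.warn("psychometric sigma at boundary; estimate unreliable",
                          stacklevel=2)
        return PsychometricResults(
            pse=float(pse), sigma=sigma, lapse=lapse,
            n_trials=int(self.n_total.sum()), log_likelihood=-float(best.fun),
            operation=self.operation, boundary=boundary,
        )


def fit_psychometric(data: pd.DataFrame, operation: str = "pooled",
                     free_lapse: bool = False) -> PsychometricResults:
    """Fit a psychometric function to (optionally operation-filtered) data."""
    return PsychometricModel(data, operation=operation, free_lapse=free_lapse).fit()


def jnd_weber(fit: PsychometricResults) -> float:
    """The log-scale JND of a fit, i.e. the behavioral Weber fraction."""
    if fit.boundary:
        warnings.warn("Weber fraction from a boundary-flagged fit", stacklevel=2)
    return fit.jnd


@dataclass
class MomentumResult:
    """Paired test of division vs multiplication PSE (operational momentum)."""

    t: float
    df: int
    p: float
    cohens_d: float
    mean_difference: float

    def summary(self) -> str:
        return (f"Operational momentum: PSE(division) - PSE(multiplication) "
                f"= {self.mean_difference:+.4f}; "
                f"t({self.df}) = {self.t:.3f}, p = {self.p:.4f}, "
                f"d = {self.cohens_d:.3f}")


def operational_momentum(pse_division: np.ndarray,
                         pse_multiplication: np.ndarray) -> MomentumResult:
    """Paired two-tailed t-test of per-subject division vs multiplication PSEs."""
    a = np.asarray(pse_division, dtype=float)
    b = np.asarray(pse_multiplication, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need paired PSE vectors of >= 2 subjects")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return MomentumResult(0.0, a.size - 1, 1.0, 0.0, 0.0)
        raise ValueError("zero-variance nonzero differences: degenerate test")
    n = a.size
    t_stat = diff.mean() / (sd / np.sqrt(n))
    p = 2 * t_dist.sf(abs(t_stat), n - 1)
    return MomentumResult(float(t_stat), n - 1, float(p),
                          float(diff.mean() / sd), float(diff.mean()))
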