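"""Experimental design: conditions, trial timing, and predictor RDMs.

The task crosses four sample numerosities (6, 12, 24, 48 dots) with two
operations (multiply, divide) and two operands (2, 4), keeping only the
combinations whose exact result is itself one of the four numerosities.
This closure rule yields 10 conditions and guarantees that (i) every
result can also occur as a sample and (ii) the sample and result
predictors are equally correlated with the operation predictor, so their
effects can be separated in a multiple regression on neural
dissimilarities.

Four 10x10 predictor dissimilarity matrices describe the pairwise
condition differences: sample and result as absolute log-numerosity
distances (numerosity is coded on a logarithmic scale), operation and
operand as 0/1 category mismatch.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "DesignSpec",
    "PredictorSet",
    "PREDICTOR_NAMES",
    "build_conditions",
    "build_predictor_rdms",
    "predictor_correlations",
]

PREDICTOR_NAMES = ("sample", "operation", "operand", "result")

MULTIPLY = "multiply"
DIVIDE = "divide"


@dataclass(frozen=True)
class Condition:
    """One sample x operation x operand cell with its exact result."""

    sample: int
    operation: str  # "multiply" or "divide"
    operand: int
    result: int

    def __post_init__(self) -> None:
        if self.operation not in (MULTIPLY, DIVIDE):
            raise ValueError(f"unknown operation {self.operation!r}")
        expected = self.sample * self.operand if self.operation == MULTIPLY else self.sample / self.operand
        if self.result != expected:
            raise ValueError(
                f"result {self.result} inconsistent with "
                f"{self.sample} {self.operation} {self.operand}"
            )

    @property
    def label(self) -> str:
        sym = "x" if self.operation == MULTIPLY else "/"
        return f"{self.sample}{sym}{self.operand}"


@dataclass(frozen=True)
class DesignSpec:
    """Trial timing and run structure of the calculation paradigm.

    Defaults describe the experiment: 20 s trials with the dot sample at
    0 s, the operation cue at 2 s and the probe at 12 s on standard
    trials; 20% catch trials with a probe SOA drawn uniformly from
    [5.4, 9.6] s; TR = 2 s; 2 standard trials per condition per run plus
    4 catch trials; 6 runs per subject by default (the cohort completed
    6-8); FIR window of 10 bins x 2 s spanning the full trial.
    """

    numerosities: tuple[int, ...] = (6, 12, 24, 48)
    operands: tuple[int, ...] = (2, 4)
    trial_length: float = 20.0
    cue_onset: float = 2.0
    probe_soa_standard: float = 12.0
    catch_fraction: float = 0.2
    catch_soa_range: tuple[float, float] = (5.4, 9.6)
    trials_per_condition_per_run: int = 2
    n_catch_per_run: int = 4
    n_runs: int = 6
    rest_duration: float = 10.0
    tr: float = 2.0
    n_fir_bins: int = 10
    probe_ratios: tuple[float, ...] = (0.5, 0.667, 0.8, 0.909, 1.1, 1.25, 1.5, 2.0)

    def __post_init__(self) -> None:
        if not self.numerosities:
            raise ValueError("numerosities must be nonempty")
        if any(n <= 0 for n in self.numerosities):
            raise ValueError("numerosities must be positive")
        if any(int(k) != k or k <= 0 for k in self.operands):
            raise ValueError("operands must be positive integers")
        if self.probe_soa_standard > self.trial_length:
            raise ValueError("probe SOA exceeds trial length")
        lo, hi = self.catch_soa_range
        if not (0 < lo <= hi < self.probe_soa_standard):
            raise ValueError("catch SOA range must lie within (0, probe_soa_standard)")

    @property
    def n_standard_trials_per_run(self) -> int:
        return self.trials_per_condition_per_run * len(build_conditions(self))

    @property
    def n_trials_per_run(self) -> int:
        return self.n_standard_trials_per_run + self.n_catch_per_run

    @property
    def run_duration(self) -> float:
        """Trials plus an end-of-run rest period.

        The rest volumes keep the FIR design full rank: with
        back-to-back 20 s trials and a 20 s FIR window the condition
        sticks would otherwise tile every volume and sum to the run
        constant.
        """
        return self.n_trials_per_run * self.trial_length + self.rest_duration

    @property
    def n_volumes_per_run(self) -> int:
        return int(round(self.run_duration / self.tr))

    def replace(self, **kwargs) -> "DesignSpec":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "numerosities": list(self.numerosities),
            "operands": list(self.operands),
            "trial_length": self.trial_length,
            "cue_onset": self.cue_onset,
            "probe_soa_standard": self.probe_soa_standard,
            "catch_fraction": self.catch_fraction,
            "catch_soa_range": list(self.catch_soa_range),
            "trials_per_condition_per_run": self.trials_per_condition_per_run,
            "n_catch_per_run": self.n_catch_per_run,
            "n_runs": self.n_runs,
            "rest_duration": self.rest_duration,
            "tr": self.tr,
            "n_fir_bins": self.n_fir_bins,
            "probe_ratios": list(self.probe_ratios),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown DesignSpec keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("numerosities", "operands", "catch_soa_range", "probe_ratios"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def build_conditions(spec: DesignSpec | None = None) -> list[Condition]:
    """Enumerate the conditions closed under the design numerosity set.

    Every sample x operation x operand combination is kept iff its exact
    result is itself a member of ``spec.numerosities`` (non-integer
    division results are thereby excluded).  Ordering is canonical: by
    sample, then operation (divide < multiply alphabetically), then
    operand, so condition indices are comparable across subjects and
    runs.
    """
    spec = spec or DesignSpec()
    numerosities = set(spec.numerosities)
    out: list[Condition] = []
    for sample in sorted(spec.numerosities):
        for operation in sorted((DIVIDE, MULTIPLY)):
            for operand in sorted(spec.operands):
                if operation == MULTIPLY:
                    result = sample * operand
                else:
                    if sample % operand != 0:
                        continue
                    result = sample // operand
                if result in numerosities:
                    out.append(Condition(sample, operation, operand, result))
    return out


@dataclass
class PredictorSet:
    """The four condition-dissimilarity matrices used as RSA predictors.

    ``matrices[name]`` is a symmetric zero-diagonal array of pairwise
    condition dissimilarities.  Numeric predictors (sample, result) are
    absolute differences of log numerosity; changing ``log_base`` only
    rescales them globally, which the z-transform used downstream
    removes.
    """

    conditions: list[Condition]
    matrices: dict[str, np.ndarray]
    log_base: float = 2.0

    def __post_init__(self) -> None:
        n = len(self.conditions)
        for name, m in self.matrices.items():
            m = np.asarray(m, dtype=float)
            if m.shape != (n, n):
                raise ValueError(f"{name} matrix shape {m.shape} != ({n}, {n})")
            self.matrices[name] = m

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def vectorized(self, name: str) -> np.ndarray:
        """Strict upper triangle of one predictor, row-major."""
        m = self.matrices[name]
        iu = np.triu_indices(m.shape[0], k=1)
        return m[iu]

    def stacked(self, names: tuple[str, ...] = PREDICTOR_NAMES) -> np.ndarray:
        """Column-stacked vectorized predictors, one column per name."""
        return np.column_stack([self.vectorized(n) for n in names])

    def to_frames(self) -> dict[str, pd.DataFrame]:
        labels = [c.label for c in self.conditions]
        return {
            name: pd.DataFrame(m, index=labels, columns=labels)
            for name, m in self.matrices.items()
        }

    def save(self, path_prefix: str) -> None:
        """Write matrices as TSV files plus a JSON sidecar."""
        for name, frame in self.to_frames().items():
            frame.to_csv(f"{path_prefix}_{name}.tsv", sep="\t")
        sidecar = {
            "labels": list(PREDICTOR_NAMES),
            "log_base": self.log_base,
            "conditions": [
                {"sample": c.sample, "operation": c.operation,
                 "operand": c.operand, "result": c.result}
                for c in self.conditions
            ],
        }
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, path_prefix: str) -> "PredictorSet":
        with open(f"{path_prefix}.json") as fh:
            sidecar = json.load(fh)
        conditions = [Condition(**c) for c in sidecar["conditions"]]
        matrices = {
            name: pd.read_csv(f"{path_prefix}_{name}.tsv", sep="\t", index_col=0).to_numpy()
            for name in sidecar["labels"]
        }
        return cls(conditions, matrices, log_base=sidecar["log_base"])


def _log_distance_matrix(values: np.ndarray, log_base: float) -> np.ndarray:
    if np.any(values <= 0):
        raise ValueError("numerosities must be positive for log-scale distances")
    logs = np.log(values.astype(float)) / math.log(log_base)
    return np.abs(logs[:, None] - logs[None, :])


def _category_distance_matrix(values: list) -> np.ndarray:
    arr = np.asarray(values)
    return (arr[:, None] != arr[None, :]).astype(float)


def build_predictor_rdms(conditions: list[Condition], log_base: float = 2.0) -> PredictorSet:
    """Build the four predictor RDMs for a condition list.

    Sample and result matrices hold |log(a) - log(b)| between the
    conditions' numerosities; operation and operand matrices hold 0 for
    matching and 1 for differing categories (any positive constant is
    equivalent after the downstream z-transform).
    """
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions to build predictor RDMs")
    if log_base <= 0 or log_base == 1:
        raise ValueError("log_base must be positive and != 1")
    matrices = {
        "sample": _log_distance_matrix(np.array([c.sample for c in conditions]), log_base),
        "operation": _category_distance_matrix([c.operation for c in conditions]),
        "operand": _category_distance_matrix([c.operand for c in conditions]),
        "result": _log_distance_matrix(np.array([c.result for c in conditions]), log_base),
    }
    return PredictorSet(list(conditions), matrices, log_base=log_base)


def predictor_correlations(predictors: PredictorSet) -> pd.DataFrame:
    """Pearson correlations between vectorized predictor upper triangles.

    Returns a symmetric 4x4 table with unit diagonal.  Raises if any
    vectorized predictor has zero variance (correlation undefined).
    """
    vectors = {name: predictors.vectorized(name) for name in PREDICTOR_NAMES}
    for name, v in vectors.items():
        if np.ptp(v) == 0:
            raise ValueError(f"predictor {name!r} has zero variance; correlation undefined")
    corr = np.corrcoef(np.vstack([vectors[n] for n in PREDICTOR_NAMES]))
    return pd.DataFrame(corr, index=list(PREDICTOR_NAMES), columns=list(PREDICTOR_NAMES))
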