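"""Readers and writers for the pipeline's artifact formats.

Volumes are NIfTI (via nibabel) with a JSON sidecar carrying TR, grid
shape and seed; event tables and behavioral data are tab-separated
files; FIR betas are NumPy array archives with a JSON sidecar.  Column
layouts are documented in docs/formats.md.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .glm import FIRResults
from .simulate import BoldRun, EVENT_COLUMNS

__all__ = [
    "write_events", "read_events", "write_table", "read_table",
    "write_bold_run", "read_bold_run", "save_fir", "load_fir",
    "write_beta_map", "read_beta_map", "write_json", "read_json",
]


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_events(path: str | Path, events: pd.DataFrame) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    try:
        ev = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"malformed event table {path}: {exc}") from exc
    missing = set(EVENT_COLUMNS) - set(ev.columns)
    if missing:
        raise ValueError(f"event table {path} lacks columns {sorted(missing)}")
    ev["is_catch"] = ev["is_catch"].astype(bool)
    ev["condition_index"] = ev["condition_index"].astype(int)
    return ev


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"malformed table {path}: {exc}") from exc


def write_bold_run(path_prefix: str | Path, run: BoldRun, seed: int | None = None) -> None:
    """Write one run as <prefix>.nii.gz + <prefix>_events.tsv + <prefix>.json."""
    prefix = Path(path_prefix)
    vol = run.data.T.reshape(run.grid_shape + (run.n_volumes,)).astype(np.float32)
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(prefix) + ".nii.gz")
    write_events(str(prefix) + "_events.tsv", run.events)
    write_json(str(prefix) + ".json",
               {"tr": run.tr, "grid_shape": list(run.grid_shape), "seed": seed})


def read_bold_run(path_prefix: str | Path) -> BoldRun:
    prefix = str(path_prefix)
    sidecar = read_json(prefix + ".json")
    img = nib.load(prefix + ".nii.gz")
    vol = np.asarray(img.dataobj, dtype=np.float64)
    grid = tuple(sidecar["grid_shape"])
    data = vol.reshape(int(np.prod(grid)), vol.shape[-1]).T
    return BoldRun(data, float(sidecar["tr"]), grid, read_events(prefix + "_events.tsv"))


def save_fir(path_prefix: str | Path, results: FIRResults) -> None:
    """Write FIR betas as <prefix>.npz + <prefix>.json."""
    prefix = str(path_prefix)
    np.savez(prefix + ".npz", estimates=results.estimates)
    write_json(prefix + ".json", {
        "condition_labels": results.condition_labels,
        "mode": results.mode,
        "run": results.run,
        "n_bins": results.n_bins,
    })


def load_fir(path_prefix: str | Path) -> FIRResults:
    prefix = str(path_prefix)
    sidecar = read_json(prefix + ".json")
    with np.load(prefix + ".npz") as npz:
        estimates = npz["estimates"]
    return FIRResults(estimates, list(sidecar["condition_labels"]),
                      sidecar["mode"], run=sidecar["run"])


def write_beta_map(path: str | Path, volume: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), np.eye(4)), str(path))


def read_beta_map(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
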