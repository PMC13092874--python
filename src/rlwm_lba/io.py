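"""Readers and writers for the pipeline's on-disk artifacts.

Tables are TSV (tab-separated; missing delay written as an empty field),
epoched EEG is HDF5 (datasets ``/data``, ``/times``, ``/channels``,
``/trial_index``; attributes ``sampling_rate``, ``lock``), and scalar
results (fit summaries, model comparisons) are JSON.  Writing then
reading any artifact reproduces the in-memory structure.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import h5py
import numpy as np
import pandas as pd
import yaml

from .fitting import FitResult, ModelComparison
from .synth import EpochSet
from .task import Criterion, DesignSpec

__all__ = [
    "TRIAL_COLUMNS",
    "write_trials",
    "read_trials",
    "write_epochs",
    "read_epochs",
    "write_fit_result",
    "write_comparison",
    "load_design",
    "dump_design",
    "load_config",
]

#: Canonical trial-table column order; latent columns follow if present.
TRIAL_COLUMNS = (
    "subject", "block", "set_size", "stimulus", "presentation_index",
    "action", "correct_action", "reward", "rt", "delay", "included_in_eeg",
)


def write_trials(path: Union[str, Path], trials: pd.DataFrame) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns {missing}")
    extra = [c for c in trials.columns if c not in TRIAL_COLUMNS]
    out = trials[list(TRIAL_COLUMNS) + extra]
    out.to_csv(path, sep="\t", index=False, na_rep="")


def read_trials(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["delay"] = df["delay"].astype("Float64")
    df["included_in_eeg"] = df["included_in_eeg"].astype(bool)
    return df


def write_epochs(path: Union[str, Path], epochs: EpochSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32))
        f.create_dataset("times", data=np.asarray(epochs.times, dtype=float))
        f.create_dataset(
            "channels",
            data=np.array([str(c) for c in epochs.channels], dtype=h5py.string_dtype("utf-8")),
        )
        f.create_dataset("trial_index", data=np.asarray(epochs.trial_index, dtype=np.int64))
        f.attrs["sampling_rate"] = float(epochs.sampling_rate)
        f.attrs["lock"] = epochs.lock


def read_epochs(path: Union[str, Path]) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            times=f["times"][()],
            channels=[c.decode() if isinstance(c, bytes) else str(c) for c in f["channels"][()]],
            sampling_rate=float(f.attrs["sampling_rate"]),
            lock=str(f.attrs["lock"]),
            trial_index=f["trial_index"][()],
        )


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_fit_result(outdir: Union[str, Path], result: FitResult) -> None:
    """Serialize a fit: JSON summary + CSVs of subject params and logliks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = {
        "model_tag": result.model_tag,
        "seed": result.seed,
        "param_names": list(result.param_names),
        "group_mean": result.group_mean,
        "group_sd": result.group_sd,
        "beta_slope": result.beta_slope,
        "total_loglik": result.total_loglik(),
        "n_trials": result.n_trials,
        "diagnostics": result.diagnostics,
    }
    (outdir / "fit.json").write_text(json.dumps(_jsonable(summary), indent=2))
    result.params.to_csv(outdir / "subject_params.csv")
    pd.DataFrame(
        {"trial": result.trial_index, "loglik": result.pointwise_map}
    ).to_csv(outdir / "pointwise_loglik.csv", index=False)
    with h5py.File(outdir / "pointwise_draws.h5", "w") as f:
        f.create_dataset("loglik", data=result.pointwise_draws.astype(np.float32))
        f.create_dataset("trial_index", data=np.asarray(result.trial_index, dtype=np.int64))


def write_comparison(path: Union[str, Path], comp: ModelComparison) -> None:
    d = dataclasses.asdict(comp)
    d["pointwise_diff"] = None  # kept in memory only; summary suffices on disk
    d["n_trials"] = int(comp.pointwise_diff.shape[0])
    Path(path).write_text(json.dumps(_jsonable(d), indent=2))


def dump_design(path: Union[str, Path], design: DesignSpec, seed: int = 0) -> None:
    doc = {
        "n_blocks": design.n_blocks,
        "set_size_sequence": list(design.set_size_sequence),
        "min_presentations": design.min_presentations,
        "max_presentations": design.max_presentations,
        "criterion": {"hits": design.criterion.hits, "window": design.criterion.window},
        "seed": seed,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_design(path: Union[str, Path]) -> tuple[DesignSpec, int]:
    doc = yaml.safe_load(Path(path).read_text())
    crit = doc.get("criterion", {})
    design = DesignSpec(
        n_blocks=doc.get("n_blocks", 11),
        set_size_sequence=tuple(doc["set_size_sequence"]),
        min_presentations=doc.get("min_presentations", 9),
        max_presentations=doc.get("max_presentations", 15),
        criterion=Criterion(hits=crit.get("hits", 4), window=crit.get("window", 5)),
    )
    return design, int(doc.get("seed", 0))


def load_config(path: Union[str, Path]) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return doc
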