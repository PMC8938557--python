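"""Lightweight persistence helpers (HDF5 for EEG, YAML for configs).

Trial tables and summary tables travel as tidy CSV via pandas; continuous
EEG and epoch arrays round-trip through HDF5 with ms/µV metadata attached
as attributes; task and cohort configurations round-trip through YAML
files mirroring the dataclass field names (nested group x condition
mappings use ``"GROUP:condition"`` keys).
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import yaml

from .cohort import CohortConfig, EEGNoiseModel, ErpTemplates
from .erp import ContinuousEEG, EpochSet
from .hbayes import GroupHyperParams
from .task import TaskConfig


def save_eeg(eeg: ContinuousEEG, path) -> None:
    with h5py.File(Path(path), "w") as f:
        dset = f.create_dataset("data", data=eeg.data, compression="gzip")
        dset.attrs["units"] = "uV"
        f.create_dataset("events", data=eeg.events)
        f.attrs["sfreq"] = eeg.sfreq
        f.attrs["channels"] = list(eeg.channels)


def load_eeg(path) -> ContinuousEEG:
    with h5py.File(Path(path), "r") as f:
        return ContinuousEEG(
            data=f["data"][()],
            channels=tuple(str(c) for c in f.attrs["channels"]),
            sfreq=float(f.attrs["sfreq"]),
            events=f["events"][()],
        )


def save_epochs(epochs: EpochSet, path) -> None:
    with h5py.File(Path(path), "w") as f:
        dset = f.create_dataset("data", data=epochs.data, compression="gzip")
        dset.attrs["units"] = "uV"
        f.create_dataset("event_codes", data=epochs.event_codes)
        f.create_dataset("mask", data=epochs.mask)
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["window_ms"] = list(epochs.window_ms)
        f.attrs["channels"] = list(epochs.channels)
        f.attrs["n_skipped"] = epochs.n_skipped


def load_epochs(path) -> EpochSet:
    with h5py.File(Path(path), "r") as f:
        return EpochSet(
            data=f["data"][()],
            channels=tuple(str(c) for c in f.attrs["channels"]),
            sfreq=float(f.attrs["sfreq"]),
            window_ms=tuple(float(x) for x in f.attrs["window_ms"]),
            event_codes=f["event_codes"][()],
            mask=f["mask"][()].astype(bool),
            n_skipped=int(f.attrs["n_skipped"]),
        )


# --------------------------------------------------------------------------
# YAML configuration round-trips


def _pairkey(key: tuple[str, str]) -> str:
    return f"{key[0]}:{key[1]}"


def _unpairkey(key: str) -> tuple[str, str]:
    group, condition = key.split(":")
    return group, condition


def save_task_config(config: TaskConfig, path) -> None:
    payload = asdict(config)
    payload["block_length_range"] = list(config.block_length_range)
    payload["ratio_set"] = [list(r) for r in config.ratio_set]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_task_config(path) -> TaskConfig:
    payload = yaml.safe_load(Path(path).read_text())
    payload["block_length_range"] = tuple(payload["block_length_range"])
    payload["ratio_set"] = tuple(tuple(r) for r in payload["ratio_set"])
    return TaskConfig(**payload)


def save_cohort_config(config: CohortConfig, path) -> None:
    payload = asdict(config)
    payload["task"] = None
    payload["conditions"] = list(config.conditions)
    payload["group_params"] = {
        _pairkey(k): asdict(v) for k, v in config.group_params.items()
    }
    payload["erp_templates"] = {
        _pairkey(k): asdict(v) for k, v in config.erp_templates.items()
    }
    payload["panas_shifts"] = {
        _pairkey(k): list(v) for k, v in config.panas_shifts.items()
    }
    payload["factor_stats"] = {k: list(v) for k, v in config.factor_stats.items()}
    payload["planted_correlations"] = {
        f"{m}:{f}": r for (m, f), r in config.planted_correlations.items()
    }
    payload["noise"] = asdict(config.noise)
    document = {"task": asdict(config.task), "cohort": payload}
    document["task"]["block_length_range"] = list(config.task.block_length_range)
    document["task"]["ratio_set"] = [list(r) for r in config.task.ratio_set]
    Path(path).write_text(yaml.safe_dump(document, sort_keys=False))


def load_cohort_config(path) -> CohortConfig:
    document = yaml.safe_load(Path(path).read_text())
    task_payload = document["task"]
    task_payload["block_length_range"] = tuple(task_payload["block_length_range"])
    task_payload["ratio_set"] = tuple(tuple(r) for r in task_payload["ratio_set"])
    payload = document["cohort"]
    payload["task"] = TaskConfig(**task_payload)
    payload["conditions"] = tuple(payload["conditions"])
    payload["group_params"] = {
        _unpairkey(k): GroupHyperParams(**v) for k, v in payload["group_params"].items()
    }
    payload["erp_templates"] = {
        _unpairkey(k): ErpTemplates(**v) for k, v in payload["erp_templates"].items()
    }
    payload["panas_shifts"] = {
        _unpairkey(k): tuple(v) for k, v in payload["panas_shifts"].items()
    }
    payload["factor_stats"] = {k: tuple(v) for k, v in payload["factor_stats"].items()}
    payload["planted_correlations"] = {
        tuple(k.split(":")): r for k, r in payload["planted_correlations"].items()
    }
    payload["noise"] = EEGNoiseModel(**payload["noise"])
    return CohortConfig(**payload)
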