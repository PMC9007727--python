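"""HDF5 serialization for trial sets and inversion results.

Stages of the pipeline are resumable from these artifacts: evaluation
needs only the stored posterior operator and the trial set, not a refit.
"""
from __future__ import annotations

import json
from dataclasses import asdict

import h5py
import numpy as np

from .inversion import InversionResults
from .simulate import SimConfig, TrialSet


def save_trialset(path, trials: TrialSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("sensor_data", data=trials.sensor_data)
        f.create_dataset("source_truth", data=trials.source_truth)
        f.create_dataset("times", data=trials.times)
        f.create_dataset("realized_deltas", data=trials.realized_deltas)
        f.attrs["vertex_indices"] = list(trials.vertex_indices)
        cfg = asdict(trials.config)
        cfg["snr_db"] = "inf" if np.isinf(cfg["snr_db"]) else cfg["snr_db"]
        f.attrs["config_json"] = json.dumps(cfg)


def load_trialset(path) -> TrialSet:
    with h5py.File(path, "r") as f:
        cfg = json.loads(f.attrs["config_json"])
        if cfg["snr_db"] == "inf":
            cfg["snr_db"] = np.inf
        cfg["dipole_positions"] = tuple(tuple(p) for p in cfg["dipole_positions"])
        cfg["t_window"] = tuple(cfg["t_window"])
        cfg["delta_range"] = tuple(cfg["delta_range"])
        return TrialSet(sensor_data=f["sensor_data"][()],
                        source_truth=f["source_truth"][()],
                        times=f["times"][()], config=SimConfig(**cfg),
                        realized_deltas=f["realized_deltas"][()],
                        vertex_indices=tuple(int(v) for v in f.attrs["vertex_indices"]))


def save_result(path, result: InversionResults, config_hash: str = "",
                variant: str = "") -> None:
    """Persist a fitted inversion (hyperparameters, F, posterior operator)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("log_lambda", data=result.hyperparameters.log_lambda)
        f.create_dataset("free_energy_trajectory", data=result.free_energy_trajectory)
        f.create_dataset("posterior_operator", data=result.posterior_operator)
        f.attrs["free_energy"] = result.free_energy
        f.attrs["n_iterations"] = result.n_iterations
        f.attrs["converged"] = bool(result.converged)
        f.attrs["data_scale"] = result.data_scale
        f.attrs["labels_json"] = json.dumps(result.labels)
        f.attrs["config_hash"] = config_hash
        f.attrs["variant"] = variant


class StoredResult:
    """A deserialized inversion result (no model attached)."""

    def __init__(self, log_lambda, free_energy, free_energy_trajectory,
                 posterior_operator, n_iterations, converged, data_scale, labels,
                 config_hash, variant):
        self.log_lambda = log_lambda
        self.free_energy = free_energy
        self.free_energy_trajectory = free_energy_trajectory
        self.posterior_operator = posterior_operator
        self.n_iterations = n_iterations
        self.converged = converged
        self.data_scale = data_scale
        self.labels = labels
        self.config_hash = config_hash
        self.variant = variant


def load_result(path) -> StoredResult:
    with h5py.File(path, "r") as f:
        return StoredResult(
            log_lambda=f["log_lambda"][()],
            free_energy=float(f.attrs["free_energy"]),
            free_energy_trajectory=f["free_energy_trajectory"][()],
            posterior_operator=f["posterior_operator"][()],
            n_iterations=int(f.attrs["n_iterations"]),
            converged=bool(f.attrs["converged"]),
            data_scale=float(f.attrs["data_scale"]),
            labels=json.loads(f.attrs["labels_json"]),
            config_hash=str(f.attrs["config_hash"]),
            variant=str(f.attrs["variant"]))
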