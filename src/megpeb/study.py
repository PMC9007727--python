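"""The end-to-end simulation study.

For each noise level (noiseless, 10 dB, −10 dB) the two-dipole trial set
is inverted under four prior variants — the cortical-patch library alone
("none"), with all fMRI components ("all"), with the valid components
only ("valid") and with the invalid component only ("invalid") — and
scored: detection AUC against a 10 mm ground-truth neighbourhood, peak
and centre-of-mass localisation error per source, free energy, and VOI
eigenvariate time-course RMSE in time and frequency domain (trial-mean
and trial-average).  ``run_battery`` repeats the study over a seed
battery for the stochastic summaries.

Per-stage seeds derive from the study seed by a fixed counter scheme
(seed·1000 + offset, modulo 2³¹) so stages can rerun independently.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluate import (SourceMap, build_report, extract_voi_timecourse, localization_errors,
                       rmse, roc_auc, spectral_rmse, truth_labels, virtual_sensor_timecourse)
from .exceptions import ConfigError
from .geometry import DEFAULT_DIPOLES_MM, build_leadfield, generate_fixture_geometry
from .inversion import ComponentSet, SourceInversion, build_msp_library
from .priors import SmoothingSpec, build_prior_set, component_centroid_mm
from .simulate import SimConfig, SyntheticPriorSpec, make_synthetic_statmap, simulate_trials

NOISE_LABELS = {np.inf: "no_noise", 10.0: "10dB", -10.0: "-10dB"}

_STAGE_OFFSETS = {"geometry": 1, "msp": 2, "trials": 3}


def stage_seed(global_seed: int, stage: str, index: int = 0) -> int:
    """Documented counter scheme: seed·1000 + stage offset + 10·index."""
    return (int(global_seed) * 1000 + _STAGE_OFFSETS[stage] + 10 * index) % (2**31)


@dataclass
class StudyConfig:
    """Conditions of the simulation study (defaults are the standard ones)."""

    seed: int = 0
    n_vertices: int = 2000
    n_channels: int = 275
    n_trials: int = 100
    noise_levels_db: tuple = (np.inf, 10.0, -10.0)
    variants: tuple = ("none", "all", "valid", "invalid")
    n_patches: int = 256  # bilateral pairs: 128 centers, reference density
    bilateral_patches: bool = True
    sigma: float = 0.6
    truncation_order: int = 8
    height_T: float = 5.0
    extent_k: int = 10
    blob_radius_mm: float = 10.0
    peak_T: float = 10.0
    label_radius_mm: float = 10.0
    voi_radius_mm: float = 10.0
    dipole_positions: tuple = DEFAULT_DIPOLES_MM
    valid_distance_mm: float = 20.0
    max_iter: int = 128
    tolerance: float = 1e-4
    compute_timecourses: bool = True
    include_virtual_sensor: bool = True


@dataclass
class StudyResult:
    """Metrics per (variant, noise label) plus the run's configuration."""

    config: StudyConfig
    metrics: dict
    vertex_indices: tuple

    def tables(self):
        return build_report(self.metrics)

    def metric(self, variant: str, noise_db: float, key: str):
        return self.metrics[(variant, NOISE_LABELS.get(noise_db, str(noise_db)))][key]

    def to_json_dict(self) -> dict:
        out = {}
        for (variant, noise), vals in self.metrics.items():
            out[f"{variant}|{noise}"] = {k: (None if v is None or (np.isscalar(v) and not
                                             np.isfinite(v)) else float(v))
                                         for k, v in vals.items() if np.isscalar(v)}
        return out


def prior_variant_components(statmap, mesh, cfg: StudyConfig):
    """Split fMRI components into valid / invalid by centroid distance."""
    spec = SmoothingSpec(adjacency=mesh.adjacency, sigma=cfg.sigma,
                         truncation_order=cfg.truncation_order)
    comps = build_prior_set(statmap, mesh, cfg.height_T, cfg.extent_k, spec)
    valid, invalid = [], []
    for c in comps:
        centroid = component_centroid_mm(c, mesh)
        d = min(np.linalg.norm(centroid - np.asarray(p, float))
                for p in cfg.dipole_positions)
        (valid if d <= cfg.valid_distance_mm else invalid).append(c)
    return valid, invalid


def _variant_sets(msp, valid, invalid, variants):
    mapping = {"none": msp, "all": msp + valid + invalid,
               "valid": msp + valid, "invalid": msp + invalid}
    try:
        return {v: mapping[v] for v in variants}
    except KeyError as err:
        raise ConfigError(f"unknown prior variant {err.args[0]!r}") from None


def _timecourse_metrics(res, trials, mesh, cfg: StudyConfig) -> dict:
    """VOI eigenvariate RMSE (time + frequency), per trial and averaged."""
    out = {}
    fs = trials.config.sample_rate
    m_op = res.posterior_operator
    for s, pos in enumerate(cfg.dipole_positions):
        key = f"x{s + 1}"
        voi = mesh.vertices_within(pos, cfg.voi_radius_mm)
        m_voi = m_op[voi]
        est_avg = extract_voi_timecourse(m_voi @ trials.sensor_data.mean(axis=0), pos,
                                         _submesh_stub(mesh, voi), radius_mm=np.inf).samples
        truth_avg = trials.source_truth[:, s, :].mean(axis=0)
        out[f"rmse_time_avg_{key}"] = rmse(est_avg, truth_avg, normalize=True)
        out[f"rmse_freq_avg_{key}"] = spectral_rmse(est_avg, truth_avg, fs)
        r_t, r_f = [], []
        for i in range(trials.n_trials):
            est = extract_voi_timecourse(m_voi @ trials.sensor_data[i], pos,
                                         _submesh_stub(mesh, voi), radius_mm=np.inf).samples
            r_t.append(rmse(est, trials.source_truth[i, s], normalize=True))
            r_f.append(spectral_rmse(est, trials.source_truth[i, s], fs))
        out[f"rmse_time_trial_{key}"] = float(np.mean(r_t))
        out[f"rmse_freq_trial_{key}"] = float(np.mean(r_f))
    return out


class _submesh_stub:
    """Restriction of a mesh to given vertices, for VOI extraction only."""

    def __init__(self, mesh, idx):
        self.vertices = mesh.vertices[idx]

    def vertices_within(self, center_mm, radius_mm):
        if not np.isfinite(radius_mm):
            return np.arange(len(self.vertices))
        d = np.linalg.norm(self.vertices - np.asarray(center_mm, float), axis=1)
        return np.flatnonzero(d <= radius_mm)


def _virtual_sensor_metrics(trials, L, mesh, cfg: StudyConfig) -> dict:
    out = {}
    fs = trials.config.sample_rate
    for s, pos in enumerate(cfg.dipole_positions):
        key = f"x{s + 1}"
        tcs = virtual_sensor_timecourse(trials.sensor_data, L, pos, mesh)
        truth_avg = trials.source_truth[:, s, :].mean(axis=0)
        out[f"rmse_time_avg_{key}"] = rmse(tcs.mean(axis=0), truth_avg, normalize=True)
        out[f"rmse_freq_avg_{key}"] = spectral_rmse(tcs.mean(axis=0), truth_avg, fs)
        out[f"rmse_time_trial_{key}"] = float(np.mean(
            [rmse(tcs[i], trials.source_truth[i, s], normalize=True)
             for i in range(trials.n_trials)]))
        out[f"rmse_freq_trial_{key}"] = float(np.mean(
            [spectral_rmse(tcs[i], trials.source_truth[i, s], fs)
             for i in range(trials.n_trials)]))
    return out


def run_study(cfg: StudyConfig) -> StudyResult:
    """One full pass of the simulation study at one seed."""
    mesh, sensors, sphere = generate_fixture_geometry(
        cfg.n_vertices, seed=stage_seed(cfg.seed, "geometry"), n_channels=cfg.n_channels,
        dipole_positions_mm=cfg.dipole_positions)
    L = build_leadfield(mesh, sensors, sphere)
    spec = SmoothingSpec(adjacency=mesh.adjacency, sigma=cfg.sigma,
                         truncation_order=cfg.truncation_order)
    msp = build_msp_library(mesh, cfg.n_patches, spec, seed=stage_seed(cfg.seed, "msp"),
                            bilateral=cfg.bilateral_patches)
    statmap = make_synthetic_statmap(SyntheticPriorSpec(
        valid_centers=cfg.dipole_positions, blob_radius_mm=cfg.blob_radius_mm,
        peak_T=cfg.peak_T))
    valid, invalid = prior_variant_components(statmap, mesh, cfg)
    variant_sets = _variant_sets(msp, valid, invalid, cfg.variants)
    labels = truth_labels(mesh, cfg.dipole_positions, cfg.label_radius_mm)

    metrics = {}
    vertex_indices = None
    for noise_idx, snr in enumerate(cfg.noise_levels_db):
        noise_label = NOISE_LABELS.get(snr, f"{snr:g}dB")
        sim_cfg = SimConfig(dipole_positions=cfg.dipole_positions, n_trials=cfg.n_trials,
                            snr_db=snr, seed=stage_seed(cfg.seed, "trials", noise_idx))
        trials = simulate_trials(sim_cfg, mesh, L)
        vertex_indices = trials.vertex_indices
        for variant, source_comps in variant_sets.items():
            model = SourceInversion.from_trialset(
                trials, L, ComponentSet.with_white_noise(source_comps, L.n_channels),
                mode="evoked")
            res = model.fit(max_iter=cfg.max_iter, tolerance=cfg.tolerance)
            src_map = SourceMap.from_power(res.source_power_map())
            roc = roc_auc(src_map, labels)
            loc = localization_errors(src_map, cfg.dipole_positions, mesh)
            diffs = np.diff(res.free_energy_trajectory)
            cell = {"auc": roc.auc, "free_energy": res.free_energy,
                    "n_iterations": res.n_iterations, "converged": float(res.converged),
                    "monotone": float(np.all(diffs >= -1e-8) if diffs.size else True)}
            for s in range(len(cfg.dipole_positions)):
                cell[f"peak_x{s + 1}"] = loc.peak_error_mm[s]
                cell[f"cmass_x{s + 1}"] = loc.cmass_error_mm[s]
            if cfg.compute_timecourses:
                cell.update(_timecourse_metrics(res, trials, mesh, cfg))
            metrics[(variant, noise_label)] = cell
        if cfg.include_virtual_sensor and cfg.compute_timecourses:
            metrics[("virtual", noise_label)] = _virtual_sensor_metrics(trials, L, mesh, cfg)
    return StudyResult(cfg, metrics, vertex_indices)


def run_battery(base_seed: int, n_seeds: int = 5, **overrides) -> list[StudyResult]:
    """Repeat the study over ``n_seeds`` derived seeds."""
    results = []
    for k in range(n_seeds):
        cfg = StudyConfig(seed=(int(base_seed) * 100 + k) % (2**31), **overrides)
        results.append(run_study(cfg))
    return results


def battery_mean(results: list[StudyResult], variant: str, noise_db: float,
                 key: str) -> float:
    return float(np.mean([r.metric(variant, noise_db, key) for r in results]))
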