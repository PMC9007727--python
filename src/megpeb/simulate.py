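"""Two-dipole evoked/induced MEG simulation and synthetic fMRI priors.

The study conditions: an evoked 10 Hz source at MNI (−38, 43, 5) mm whose
waveform is identical on every trial, and an induced source at
(−54, −13, 5) mm whose sinusoid frequency varies randomly from trial to
trial (so it cancels under waveform averaging but survives in power),
over t ∈ [0.55, 0.85] s, 100 trials, with white sensor noise at a
requested SNR of +inf (noiseless), 10 dB or −10 dB.

Waveforms (unit amplitude, onset phase π/2 so both start at 1):

    f_evoked(t)      = sin(2π·10·(t − t0) + π/2)
    f_induced(t; i)  = sin(2π·24·(t − t0)/ρ_i + π/2)

ρ_i = i·δ_i is the per-trial scale of the induced frequency 24/ρ_i Hz.
Drawn as ρ_i ~ U(0.5, 2.0) by default (frequencies spanning 12–48 Hz on
every trial); the literal per-trial law δ_i ~ U(lo, hi) with ρ_i = i·δ_i
is available as ``delta_law="literal-uniform"`` (it drives late trials
toward DC).  t0 defaults to the window start.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ConfigError, DataError, GeometryError
from .geometry import (DEFAULT_DIPOLES_MM, CorticalMesh, LeadField, nearest_vertex)
from .priors import StatVolume


@dataclass
class SimConfig:
    """Simulation conditions; defaults are the standard study conditions."""

    dipole_positions: tuple = DEFAULT_DIPOLES_MM
    t_window: tuple = (0.55, 0.85)
    sample_rate: float = 600.0
    n_trials: int = 100
    snr_db: float = np.inf
    delta_law: str = "scaled-uniform"
    delta_range: tuple = (0.5, 2.0)
    dipole_moment: float = 1e-8  # A·m, typical cortical patch source
    t0: float | None = None     # defaults to window start
    seed: int = 0

    def __post_init__(self):
        if self.t_window[0] >= self.t_window[1]:
            raise ConfigError("t_window start must precede end")
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")
        if self.sample_rate <= 0:
            raise ConfigError("sample_rate must be positive")
        if self.delta_law not in ("scaled-uniform", "literal-uniform"):
            raise ConfigError(f"unknown delta law {self.delta_law!r}")

    @property
    def onset(self) -> float:
        return self.t_window[0] if self.t0 is None else self.t0

    def time_axis(self) -> np.ndarray:
        n = int(np.floor((self.t_window[1] - self.t_window[0]) * self.sample_rate + 1e-9)) + 1
        return self.t_window[0] + np.arange(n) / self.sample_rate


@dataclass
class TrialSet:
    """Simulated per-trial sensor data plus ground truth."""

    sensor_data: np.ndarray    # (trials, channels, samples)
    source_truth: np.ndarray   # (trials, 2, samples), in A·m
    times: np.ndarray
    config: SimConfig
    realized_deltas: np.ndarray
    vertex_indices: tuple

    @property
    def n_trials(self) -> int:
        return self.sensor_data.shape[0]


def evoked_timecourse(t_axis: np.ndarray, t0: float) -> np.ndarray:
    """Phase-locked 10 Hz unit sinusoid, value 1 at t = t0."""
    t = np.asarray(t_axis, dtype=float)
    return np.sin((t - t0) * 10.0 * 2.0 * np.pi + np.pi / 2.0)


def induced_timecourse(t_axis: np.ndarray, t0: float, trial_index: int,
                       delta: float) -> np.ndarray:
    """Trial-varying sinusoid at 24/(i·δ) Hz, value 1 at t = t0."""
    if delta <= 0:
        raise DataError("delta must be positive")
    if trial_index < 1:
        raise DataError("trial_index is 1-based and must be >= 1")
    t = np.asarray(t_axis, dtype=float)
    return np.sin((t - t0) / (trial_index * delta) * 24.0 * 2.0 * np.pi + np.pi / 2.0)


def draw_deltas(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-trial δ_i under the configured law (both keep δ > 0)."""
    lo, hi = cfg.delta_range
    if cfg.delta_law == "scaled-uniform":
        rho = rng.uniform(lo, hi, size=cfg.n_trials)
        return rho / np.arange(1, cfg.n_trials + 1)
    return rng.uniform(lo, hi, size=cfg.n_trials)


def simulate_trials(cfg: SimConfig, mesh: CorticalMesh, L: LeadField,
                    max_vertex_distance_mm: float = 5.0) -> TrialSet:
    """Forward-project both dipoles per trial and add white sensor noise.

    Noise is scaled per trial so that 10·log10(signal power / noise
    power) equals ``cfg.snr_db`` over channels and samples;
    ``snr_db=inf`` yields exactly B = L·X.  Fully reproducible from
    ``cfg.seed``.
    """
    if L.moment_convention != "fixed-normal":
        raise DataError("simulation expects a fixed-normal lead field")
    verts = []
    for p in cfg.dipole_positions:
        v = nearest_vertex(p, mesh)
        d = np.linalg.norm(mesh.vertices[v] - np.asarray(p, dtype=float))
        if d > max_vertex_distance_mm:
            raise GeometryError(f"no mesh vertex within {max_vertex_distance_mm:g} mm "
                                f"of dipole {tuple(p)} (closest {d:.1f} mm)")
        verts.append(v)
    if L.matrix.shape[1] != mesh.n_vertices:
        raise GeometryError("lead field does not match mesh")

    rng = np.random.default_rng(cfg.seed)
    t = cfg.time_axis()
    deltas = draw_deltas(cfg, rng)
    n_chan = L.matrix.shape[0]
    x1 = cfg.dipole_moment * evoked_timecourse(t, cfg.onset)
    truth = np.empty((cfg.n_trials, 2, len(t)))
    data = np.empty((cfg.n_trials, n_chan, len(t)))
    l1, l2 = L.matrix[:, verts[0]], L.matrix[:, verts[1]]
    for i in range(cfg.n_trials):
        x2 = cfg.dipole_moment * induced_timecourse(t, cfg.onset, i + 1, deltas[i])
        truth[i, 0], truth[i, 1] = x1, x2
        signal = np.outer(l1, x1) + np.outer(l2, x2)
        if np.isfinite(cfg.snr_db):
            p_sig = np.mean(signal**2)
            sigma = np.sqrt(p_sig * 10.0 ** (-cfg.snr_db / 10.0))
            signal = signal + rng.normal(0.0, sigma, size=signal.shape)
        data[i] = signal
    return TrialSet(data, truth, t, cfg, deltas, tuple(verts))


@dataclass
class SyntheticPriorSpec:
    """Placement of synthetic fMRI blobs: valid at the dipoles, invalid away."""

    valid_centers: tuple = DEFAULT_DIPOLES_MM
    invalid_centers: tuple = ((48.0, 22.0, 8.0),)
    blob_radius_mm: float = 10.0
    peak_T: float = 10.0
    min_invalid_distance_mm: float = 30.0

    def __post_init__(self):
        for c in self.invalid_centers:
            for v in self.valid_centers:
                d = np.linalg.norm(np.asarray(c, float) - np.asarray(v, float))
                if d < self.min_invalid_distance_mm:
                    raise ConfigError("invalid prior centers must be at least "
                                      f"{self.min_invalid_distance_mm:g} mm from every "
                                      f"true dipole (got {d:.1f} mm)")

    @property
    def centers(self) -> list:
        return list(self.valid_centers) + list(self.invalid_centers)


def default_affine(grid_shape=(41, 41, 41), voxel_mm: float = 4.0) -> np.ndarray:
    """Isotropic affine centred on the origin (covers ±80 mm by default)."""
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = -voxel_mm * (np.asarray(grid_shape) - 1) / 2.0
    return aff


def make_synthetic_statmap(spec: SyntheticPriorSpec, grid_shape=(41, 41, 41),
                           affine: np.ndarray | None = None) -> StatVolume:
    """SPM{T}-like volume of Gaussian blobs (σ = radius/2) at the spec centers.

    Thresholding below ``peak_T`` recovers one cluster per blob; blobs
    whose suprathreshold extents could merge raise an error.
    """
    if affine is None:
        affine = default_affine(grid_shape)
    centers = [np.asarray(c, dtype=float) for c in spec.centers]
    for a in range(len(centers)):
        for b in range(a + 1, len(centers)):
            if np.linalg.norm(centers[a] - centers[b]) < 2.0 * spec.blob_radius_mm:
                raise ConfigError("blobs overlap: centers closer than twice the radius")
    vol = np.zeros(grid_shape)
    if centers:
        ijk = np.stack(np.meshgrid(*[np.arange(s) for s in grid_shape], indexing="ij"), axis=-1)
        mm = ijk.reshape(-1, 3) @ affine[:3, :3].T + affine[:3, 3]
        sig = spec.blob_radius_mm / 2.0
        for c in centers:
            inside = ((mm - c) ** 2).sum(axis=1)
            if not np.any(inside < (2 * sig) ** 2):
                raise ConfigError(f"blob center {tuple(c)} lies outside the grid")
            vol += spec.peak_T * np.exp(-0.5 * inside / sig**2).reshape(grid_shape)
    return StatVolume(vol, affine)


def with_seed(cfg: SimConfig, seed: int, **changes) -> SimConfig:
    """Copy of a config with a new seed (and optional field overrides)."""
    return replace(cfg, seed=seed, **changes)
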