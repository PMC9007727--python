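"""Scoring of inversions against simulated ground truth.

Covers: normalised source maps, peak / centre-of-mass localisation error,
ROC curves and AUC over a decision-threshold sweep, first-eigenvariate
time-course extraction over a 10 mm VOI, time- and frequency-domain RMSE,
a linearly-constrained minimum-variance "virtual sensor" comparison
filter, and the tabular report layout of the simulation study.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError
from .geometry import CorticalMesh, LeadField, nearest_vertex

VARIANTS = ("none", "all", "valid", "invalid")
VARIANT_TITLES = {"none": "No priors", "all": "All", "valid": "Valid Only",
                  "invalid": "Invalid Only", "virtual": "Virtual Sensor"}


@dataclass
class SourceMap:
    """Per-vertex activity scores normalised to [0, 1]."""

    values: np.ndarray
    derivation: str = ""
    is_null: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not self.is_null and (self.values.min() < 0 or abs(self.values.max() - 1.0) > 1e-12):
            raise DataError("non-null source maps must span [0, 1] with max 1")

    @classmethod
    def from_power(cls, power: np.ndarray, derivation: str = "trial power") -> "SourceMap":
        power = np.asarray(power, dtype=float)
        m = power.max()
        if m <= 0:
            return cls(np.zeros_like(power), derivation, is_null=True)
        return cls(power / m, derivation)


@dataclass
class GroundTruthLabels:
    """Binary active/inactive labels per vertex."""

    labels: np.ndarray
    positive_radius_mm: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=bool)


def truth_labels(mesh: CorticalMesh, positions_mm, radius_mm: float = 10.0) -> GroundTruthLabels:
    """Vertices within ``radius_mm`` of any true source are positive."""
    lab = np.zeros(mesh.n_vertices, dtype=bool)
    for p in positions_mm:
        lab[mesh.vertices_within(p, radius_mm)] = True
    if not lab.any():
        raise DataError("no vertex within the positive radius of any source")
    return GroundTruthLabels(lab, radius_mm)


def normalize_source_map(posterior_mean: np.ndarray, window=None) -> SourceMap:
    """Max absolute posterior amplitude per vertex over a sample window,
    divided by the global maximum.  All-zero input yields a flagged null
    map; positive rescaling of the posterior leaves the map unchanged."""
    x = np.atleast_2d(np.asarray(posterior_mean, dtype=float))
    if window is not None:
        x = x[:, window]
    if x.shape[1] == 0:
        raise DataError("empty window")
    amp = np.abs(x).max(axis=1)
    m = amp.max()
    if m == 0:
        return SourceMap(amp, "window max abs", is_null=True)
    return SourceMap(amp / m, "window max abs")


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(1.0 - self.specificity, self.sensitivity, **kwargs)
        ax.plot([0, 1], [0, 1], ls=":", color="gray")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"AUC = {self.auc:.3f}")
        return ax

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"beta": self.thresholds, "sensitivity": self.sensitivity,
                             "specificity": self.specificity})


def roc_auc(src_map: SourceMap, labels: GroundTruthLabels, n_thresholds: int = 101) -> ROCCurve:
    """Threshold sweep ROC: active iff map >= β, β uniform on [0, 1].

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP); AUC by trapezoid
    over (1−specificity, sensitivity) with the (0,0) and (1,1) endpoints
    appended.
    """
    y = labels.labels
    if y.all() or not y.any():
        raise DataError("labels must contain both classes")
    betas = np.linspace(0.0, 1.0, n_thresholds)
    pred = src_map.values[:, None] >= betas[None, :]
    tp = (pred & y[:, None]).sum(axis=0)
    fp = (pred & ~y[:, None]).sum(axis=0)
    fn = y.sum() - tp
    tn = (~y).sum() - fp
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    x = np.concatenate([[0.0], (1.0 - spec)[::-1], [1.0]])
    yy = np.concatenate([[0.0], sens[::-1], [1.0]])
    order = np.argsort(x, kind="stable")
    auc = float(np.trapezoid(yy[order], x[order]))
    return ROCCurve(betas, sens, spec, auc)


@dataclass
class LocalizationReport:
    """Per-source peak and centre-of-mass errors (mm)."""

    peak_error_mm: np.ndarray
    cmass_error_mm: np.ndarray
    peak_vertices: np.ndarray
    cluster_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"source": np.arange(len(self.peak_error_mm)),
                             "peak_error_mm": self.peak_error_mm,
                             "cmass_error_mm": self.cmass_error_mm})


def _connected_component(seed: int, members: np.ndarray, adjacency) -> np.ndarray:
    """BFS over ``adjacency`` restricted to the boolean ``members`` mask."""
    seen = np.zeros(len(members), dtype=bool)
    stack = [seed]
    seen[seed] = True
    while stack:
        v = stack.pop()
        for w in adjacency.indices[adjacency.indptr[v]:adjacency.indptr[v + 1]]:
            if members[w] and not seen[w]:
                seen[w] = True
                stack.append(int(w))
    return np.flatnonzero(seen)


def localization_errors(src_map: SourceMap, truth_positions_mm, mesh: CorticalMesh,
                        cluster_threshold: float = 0.5) -> LocalizationReport:
    """Peak and centre-of-mass error per source.

    The mesh is partitioned by proximity to the true sources so the
    stronger source cannot absorb both scores.  Within each partition the
    peak is the maximal-map vertex; the centre of mass is the
    amplitude-weighted centroid of the connected suprathreshold cluster
    containing that peak, thresholded at ``cluster_threshold`` times the
    regional peak value.
    """
    if src_map.is_null:
        raise DataError("cannot localise a null source map")
    truth = np.atleast_2d(np.asarray(truth_positions_mm, dtype=float))
    d = np.linalg.norm(mesh.vertices[:, None, :] - truth[None, :, :], axis=2)
    partition = np.argmin(d, axis=1)
    peaks, perr, cerr = [], [], []
    for s in range(len(truth)):
        sel = partition == s
        idx = np.flatnonzero(sel)
        local = src_map.values[idx]
        peak = int(idx[np.argmax(local)])
        peaks.append(peak)
        perr.append(float(np.linalg.norm(mesh.vertices[peak] - truth[s])))
        members = sel & (src_map.values >= cluster_threshold * local.max())
        comp = _connected_component(peak, members, mesh.adjacency)
        w = src_map.values[comp]
        centroid = (w @ mesh.vertices[comp]) / w.sum()
        cerr.append(float(np.linalg.norm(centroid - truth[s])))
    return LocalizationReport(np.asarray(perr), np.asarray(cerr), np.asarray(peaks),
                              cluster_threshold)


@dataclass
class TimeCourseEstimate:
    samples: np.ndarray
    voi_center_mm: tuple
    n_vertices: int
    extraction: str = "first eigenvariate, 10 mm VOI"


def extract_voi_timecourse(timecourses: np.ndarray, voi_center_mm, mesh: CorticalMesh,
                           radius_mm: float = 10.0) -> TimeCourseEstimate:
    """First eigenvariate of all vertex time courses within the VOI.

    The dominant singular mode's temporal component scaled by its
    singular value, with the sign chosen to correlate positively with the
    VOI mean time course (more robust to within-region heterogeneity than
    the plain mean).
    """
    idx = mesh.vertices_within(voi_center_mm, radius_mm)
    if len(idx) == 0:
        raise DataError("empty VOI")
    y = np.atleast_2d(np.asarray(timecourses, dtype=float))[idx]
    u, s, vt = np.linalg.svd(y, full_matrices=False)
    e = s[0] * vt[0]
    mean_tc = y.mean(axis=0)
    if np.dot(e, mean_tc) < 0:
        e = -e
    return TimeCourseEstimate(e, tuple(np.asarray(voi_center_mm, float)), len(idx))


def rmse(estimate: np.ndarray, truth: np.ndarray, normalize: bool = False) -> float:
    """Root-mean-square error; with ``normalize`` both signals are first
    scaled to unit maximum absolute amplitude (simulated moments carry an
    arbitrary scale, so normalised RMSE is the comparable quantity)."""
    a = np.asarray(estimate, dtype=float).ravel()
    b = np.asarray(truth, dtype=float).ravel()
    if a.shape != b.shape:
        raise DataError("rmse inputs must have equal length")
    if normalize:
        ma, mb = np.abs(a).max(), np.abs(b).max()
        a = a / ma if ma > 0 else a
        b = b / mb if mb > 0 else b
    return float(np.sqrt(np.mean((a - b) ** 2)))


def amplitude_spectrum(x: np.ndarray, sample_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Single-sided amplitude spectrum: a unit on-grid sinusoid peaks at 1."""
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < 2:
        raise DataError("need at least two samples")
    n = len(x)
    amp = np.abs(np.fft.rfft(x)) / n
    amp[1:] *= 2.0
    if n % 2 == 0:
        amp[-1] /= 2.0
    return np.fft.rfftfreq(n, d=1.0 / sample_rate), amp


def spectral_rmse(estimate: np.ndarray, truth: np.ndarray, sample_rate: float) -> float:
    """RMSE between single-sided spectra of the unit-max normalised signals."""
    a = np.asarray(estimate, dtype=float)
    b = np.asarray(truth, dtype=float)
    ma, mb = np.abs(a).max(), np.abs(b).max()
    _, sa = amplitude_spectrum(a / ma if ma > 0 else a, sample_rate)
    _, sb = amplitude_spectrum(b / mb if mb > 0 else b, sample_rate)
    return rmse(sa, sb)


def virtual_sensor_timecourse(sensor_data: np.ndarray, L: LeadField,
                              target_position_mm, mesh: CorticalMesh,
                              loading: float = 1e-10) -> np.ndarray:
    """LCMV spatial-filter time courses at a target vertex (experimental).

    A linearly constrained minimum-variance filter with unit gain at the
    target lead-field column, applied per trial.  This is a stand-in
    comparison method — the reference "virtual sensor" procedure it
    mirrors is not fully specified — and is excluded from the primary
    metrics.  Near-singular data covariance is regularised by diagonal
    loading (factor reported via a warning).
    """
    data = np.asarray(sensor_data, dtype=float)
    if data.ndim == 2:
        data = data[None]
    v = nearest_vertex(target_position_mm, mesh)
    lvec = L.matrix[:, v]
    n_chan = data.shape[1]
    c = np.einsum("imt,int->mn", data, data) / (data.shape[0] * data.shape[2])
    load = loading * np.trace(c) / n_chan
    if np.linalg.cond(c) > 1e10:
        load = max(load, 1e-6 * np.trace(c) / n_chan)
        warnings.warn(f"virtual sensor: data covariance regularised with loading {load:.3e}",
                      stacklevel=2)
    cinv_l = np.linalg.solve(c + load * np.eye(n_chan), lvec)
    w = cinv_l / (lvec @ cinv_l)
    return np.einsum("m,imt->it", w, data)


# ---------------------------------------------------------------------------
# report layout


def build_report(metrics: dict) -> dict[str, pd.DataFrame]:
    """Assemble the summary tables of the simulation study.

    ``metrics`` maps ``(variant, noise_label)`` to a flat dict with keys
    like ``auc``, ``peak_x1``, ``cmass_x1``, ``rmse_time_avg_x1``,
    ``rmse_time_trial_x1`` (and ``_x2``), plus frequency-domain twins.
    Returns three frames: localisation + AUC, time-domain RMSE and
    frequency-domain RMSE.  Missing cells become NA.
    """
    noises = sorted({k[1] for k in metrics}, key=_noise_sort_key)
    variants = [v for v in VARIANTS if any(k[0] == v for k in metrics)]
    extra = [v for v in sorted({k[0] for k in metrics}) if v not in VARIANTS]
    variants += extra

    def cell(variant, noise, key):
        return metrics.get((variant, noise), {}).get(key, np.nan)

    rows1, index1 = [], []
    for noise in noises:
        for src in ("x1", "x2"):
            for metric, key in (("Peak", f"peak_{src}"), ("Cmass", f"cmass_{src}")):
                index1.append((noise, src.upper(), metric))
                rows1.append([cell(v, noise, key) for v in variants])
        index1.append((noise, "", "AUC"))
        rows1.append([cell(v, noise, "auc") for v in variants])
    table1 = pd.DataFrame(rows1, columns=[VARIANT_TITLES.get(v, v) for v in variants],
                          index=pd.MultiIndex.from_tuples(index1,
                                                          names=["noise", "source", "metric"]))

    def rmse_table(domain):
        rows, index = [], []
        for noise in noises:
            for src in ("x1", "x2"):
                for avg_label, key in (("Average of trials", f"rmse_{domain}_avg_{src}"),
                                       ("Per-trial", f"rmse_{domain}_trial_{src}")):
                    index.append((noise, src.upper(), avg_label))
                    rows.append([cell(v, noise, key) for v in variants])
        return pd.DataFrame(rows, columns=[VARIANT_TITLES.get(v, v) for v in variants],
                            index=pd.MultiIndex.from_tuples(index,
                                                            names=["noise", "source", "metric"]))

    return {"localization": table1, "rmse_time": rmse_table("time"),
            "rmse_freq": rmse_table("freq")}


def _noise_sort_key(label: str) -> float:
    if label in ("no_noise", "noiseless", "inf"):
        return -np.inf
    try:
        return -float(label.replace("dB", "").replace("db", ""))
    except ValueError:
        return np.inf
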