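"""Parametric empirical Bayes source inversion.

Model.  Sensor data B (channels × samples) follow the linear forward
model B = L X + E with Gaussian noise, and the source activity X is
zero-mean Gaussian with covariance Γ = Σ_i exp(λ_i) Q_i built from a
library of fixed covariance components (cortical patches and, optionally,
fMRI cluster priors).  The sensor-level model covariance is

    C = Σ_j exp(λ_j) Q_j^(sensor) + L Γ Lᵀ,

and the hyperparameters λ are estimated by restricted maximum likelihood:
Fisher-scoring ascent on the variational free energy F, a lower bound on
the log model evidence.  With the Laplace approximation and Gaussian
hyperpriors on λ the objective is

    F(λ) = Σ_t log N(b_t; 0, C(λ)) + log N(λ; η, Σ_η)  (+ curvature term),

maximised with a damped Newton step on λ so that the recorded trajectory
is non-decreasing.  The MAP source estimate at the optimum is the
posterior mean  X̂ = Γ Lᵀ C⁻¹ B, linear in the data.

The public surface follows the fitted-model idiom: ``SourceInversion``
holds data + lead field + components; ``fit()`` returns
``InversionResults`` with hyperparameters, free energy, diagnostics and a
``summary()`` table.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .exceptions import DataError
from .geometry import CorticalMesh, LeadField
from .priors import CovComponent, SmoothingSpec, VertexIndicator, green_smooth

logger = logging.getLogger(__name__)

LOG_LAMBDA_CLIP = 500.0  # exp overflow guard only
FIT_SPACE_CLIP = 32.0   # trust region for the optimiser's log scale


@dataclass
class DataMatrix:
    """Sensor data: channels × samples, with a time axis in seconds."""

    values: np.ndarray
    sample_rate: float
    times: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("DataMatrix values must be 2D (channels x samples)")
        if not np.all(np.isfinite(self.values)):
            raise DataError("DataMatrix values must be finite")
        if self.times is None:
            self.times = np.arange(self.values.shape[1]) / self.sample_rate


@dataclass
class ComponentSet:
    """Sensor-level (noise) and source-level covariance components."""

    source_components: list
    sensor_components: list = field(default_factory=list)

    def __post_init__(self):
        if not self.source_components:
            raise DataError("at least one source component is required")
        for c in self.source_components:
            if c.level != "source":
                raise DataError("source_components must have level='source'")
        for c in self.sensor_components:
            if c.level != "sensor":
                raise DataError("sensor_components must have level='sensor'")

    @classmethod
    def with_white_noise(cls, source_components: list, n_channels: int) -> "ComponentSet":
        return cls(source_components=list(source_components),
                   sensor_components=[CovComponent.identity(n_channels)])

    @property
    def n_components(self) -> int:
        return len(self.sensor_components) + len(self.source_components)

    @property
    def labels(self) -> list[str]:
        return ([c.label or f"sensor {i}" for i, c in enumerate(self.sensor_components)]
                + [c.label or f"source {i}" for i, c in enumerate(self.source_components)])


@dataclass
class Hyperparameters:
    """Log-scale hyperparameters; effective weights are exp(log_lambda) >= 0."""

    log_lambda: np.ndarray

    def __post_init__(self):
        self.log_lambda = np.asarray(self.log_lambda, dtype=float).ravel()
        if not np.all(np.isfinite(self.log_lambda)):
            raise DataError("log hyperparameters must be finite")

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.log_lambda)


def build_msp_library(mesh: CorticalMesh, n_patches: int = 512,
                      spec: SmoothingSpec | None = None, seed: int = 0,
                      bilateral: bool = False) -> list[CovComponent]:
    """Multiple-sparse-priors patch library.

    Patch centers are chosen by greedy farthest-point sampling
    (deterministic given ``seed``), an even spatial stratification of the
    mesh; each patch is the Green's-function smoothed unit indicator of
    its center, normalised to unit norm.  With ``bilateral`` each center
    contributes two components — the unilateral patch and the patch plus
    its mirrored (x → −x) homologue — following the usual sparse-prior
    construction for bilateral cortical responses; ``n_patches`` always
    counts components (so ``n_patches // 2`` centers when bilateral).
    """
    n_centers = n_patches // 2 if bilateral else n_patches
    if n_centers < 1 or n_centers > mesh.n_vertices:
        raise DataError("n_patches must give between 1 and n_vertices patch centers")
    if spec is None:
        spec = SmoothingSpec(adjacency=mesh.adjacency)
    rng = np.random.default_rng(seed)
    v = mesh.vertices
    centers = [int(rng.integers(mesh.n_vertices))]
    dist = np.linalg.norm(v - v[centers[0]], axis=1)
    for _ in range(n_centers - 1):
        nxt = int(np.argmax(dist))
        centers.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(v - v[nxt], axis=1))

    def patch(vertex: int) -> np.ndarray:
        e = np.zeros(mesh.n_vertices)
        e[vertex] = 1.0
        return green_smooth(VertexIndicator(e), spec).weights

    comps = []
    for c in centers:
        q = patch(c)
        comps.append(CovComponent(level="source", vector=q / np.linalg.norm(q),
                                  label=f"patch v{c}"))
        if bilateral:
            mirror = nearest_vertex_index(v[c] * np.array([-1.0, 1.0, 1.0]), v)
            qb = q / np.linalg.norm(q) + _unit(patch(mirror))
            comps.append(CovComponent(level="source", vector=qb / np.linalg.norm(qb),
                                      label=f"bilateral v{c}"))
    return comps


def _unit(x: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(x)
    return x / n if n > 0 else x


def nearest_vertex_index(position: np.ndarray, vertices: np.ndarray) -> int:
    return int(np.argmin(np.linalg.norm(vertices - position, axis=1)))


# ---------------------------------------------------------------------------
# sensor-space assembly


def _sensor_ops(L: LeadField | np.ndarray, comps: ComponentSet):
    """Project every component into sensor space.

    Returns (rank1 factor matrix U or None, list of dense matrices,
    index arrays mapping components → columns/list slots) preserving the
    component order sensor-first then source.
    """
    lmat = L.matrix if isinstance(L, LeadField) else np.asarray(L, dtype=float)
    n_chan = lmat.shape[0]
    rank1_cols, dense_mats, kinds = [], [], []
    for c in comps.sensor_components:
        if c.is_rank1:
            rank1_cols.append(c.vector)
            kinds.append(("r", len(rank1_cols) - 1))
        else:
            if c.matrix.shape != (n_chan, n_chan):
                raise DataError("sensor component dimension mismatch")
            dense_mats.append(c.matrix)
            kinds.append(("d", len(dense_mats) - 1))
    for c in comps.source_components:
        if c.is_rank1:
            if len(c.vector) != lmat.shape[1]:
                raise DataError("source component dimension inconsistent with lead field")
            rank1_cols.append(lmat @ c.vector)
            kinds.append(("r", len(rank1_cols) - 1))
        else:
            dense_mats.append(lmat @ c.matrix @ lmat.T)
            kinds.append(("d", len(dense_mats) - 1))
    u = np.column_stack(rank1_cols) if rank1_cols else None
    return u, dense_mats, kinds, n_chan


def _assemble_cov(u, dense_mats, kinds, n_chan, log_lambda):
    w = np.exp(np.clip(log_lambda, -LOG_LAMBDA_CLIP, LOG_LAMBDA_CLIP))
    c = np.zeros((n_chan, n_chan))
    wr = []
    for (kind, slot), wi in zip(kinds, w):
        if kind == "d":
            c += wi * dense_mats[slot]
        else:
            wr.append(wi)
    if u is not None:
        c += (u * np.asarray(wr)) @ u.T
    return c, w


def _gaussian_loglik(c: np.ndarray, s: np.ndarray, n: float) -> float:
    """Σ_t log N(b_t; 0, C) given S = Σ_t b_t b_tᵀ and n samples."""
    m = c.shape[0]
    cho = linalg.cho_factor(c, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    trace = float(np.trace(linalg.cho_solve(cho, s)))
    return -0.5 * (n * m * np.log(2.0 * np.pi) + n * logdet + trace)


def free_energy(B, L, comps: ComponentSet, h: Hyperparameters,
                hyperprior: "HyperPrior | None" = None) -> float:
    """Free energy at fixed hyperparameters.

    Without a hyperprior this is exactly the Gaussian log evidence of the
    data under the assembled sensor covariance — the closed-form marginal
    likelihood of the linear-Gaussian model; with one, the log hyperprior
    density of λ is added.
    """
    b = B.values if isinstance(B, DataMatrix) else np.atleast_2d(np.asarray(B, dtype=float))
    u, dmats, kinds, n_chan = _sensor_ops(L, comps)
    if b.shape[0] != n_chan:
        raise DataError("data/lead-field channel mismatch")
    if len(h.log_lambda) != comps.n_components:
        raise DataError("hyperparameter count does not match component count")
    c, _ = _assemble_cov(u, dmats, kinds, n_chan, h.log_lambda)
    try:
        val = _gaussian_loglik(c, b @ b.T, b.shape[1])
    except linalg.LinAlgError as err:  # pragma: no cover - exp parameterization guards this
        raise DataError("assembled covariance is not positive definite; "
                        "component set is corrupt") from err
    if hyperprior is not None:
        val += hyperprior.logpdf(h.log_lambda)
    return float(val)


@dataclass
class HyperPrior:
    """Independent Gaussian prior on each log hyperparameter."""

    mean: float | np.ndarray = -4.0
    variance: float | np.ndarray = 16.0

    def expand(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        m = np.broadcast_to(np.asarray(self.mean, dtype=float), (k,)).copy()
        v = np.broadcast_to(np.asarray(self.variance, dtype=float), (k,)).copy()
        return m, v

    def logpdf(self, log_lambda: np.ndarray) -> float:
        m, v = self.expand(len(log_lambda))
        return float(-0.5 * np.sum((log_lambda - m) ** 2 / v + np.log(2.0 * np.pi * v)))


@dataclass
class ReMLOptions:
    max_iter: int = 128
    tolerance: float = 1e-4
    hyperprior: HyperPrior = field(default_factory=HyperPrior)
    scale_data: bool = True
    initial_log_lambda: np.ndarray | None = None
    solver: str = "ard"  # "ard" (multiplicative fixed point) or "fisher" (Newton)


def _reml_core(s: np.ndarray, n: float, u, dense_mats, kinds, n_chan,
               opts: ReMLOptions):
    """ReML ascent on log hyperparameters with a monotone line search.

    ``s`` is the (possibly scaled) second-moment matrix Σ b bᵀ; ``n`` the
    number of samples it accumulates.  Two update directions are
    available on the same penalized objective: the multiplicative ARD
    fixed point Δλ_i = log(g2_i/g1_i) with g1 = tr(C⁻¹P_i) and
    g2 = tr(C⁻¹P_iC⁻¹S̄) (default; its rich-get-richer dynamics select
    among correlated components by topography alignment), and a damped
    Fisher-scoring Newton step.  Backtracking guarantees the recorded
    trajectory is non-decreasing either way.  Returns the optimum, the
    trajectory, the Fisher information at the optimum (for the Laplace
    evidence term) and a convergence flag.
    """
    if opts.solver not in ("ard", "fisher"):
        raise DataError(f"unknown solver {opts.solver!r}")
    k = len(kinds)
    h_mean, h_var = opts.hyperprior.expand(k)
    lam = (np.asarray(opts.initial_log_lambda, dtype=float).copy()
           if opts.initial_log_lambda is not None else h_mean.copy())
    sbar = s / n
    const = -0.5 * np.sum(np.log(2.0 * np.pi * h_var))
    r_slots = [i for i, (kind, _) in enumerate(kinds) if kind == "r"]
    d_slots = [i for i, (kind, _) in enumerate(kinds) if kind == "d"]

    def objective_parts(lam):
        c, w = _assemble_cov(u, dense_mats, kinds, n_chan, lam)
        cho = linalg.cho_factor(c, lower=True)
        obj = (-0.5 * n * (n_chan * np.log(2 * np.pi)
                           + 2.0 * np.sum(np.log(np.diag(cho[0])))
                           + float(np.trace(linalg.cho_solve(cho, sbar))))
               - 0.5 * np.sum((lam - h_mean) ** 2 / h_var) + const)
        return obj, c, cho, w

    def curvatures(cinv, t, w):
        """g1_i = tr(C⁻¹Q_i), g2_i = tr(C⁻¹Q_iC⁻¹S̄) per component."""
        g1 = np.empty(k)
        g2 = np.empty(k)
        if u is not None:
            g1[r_slots] = np.einsum("mk,mk->k", u, cinv @ u)
            g2[r_slots] = np.einsum("mk,mk->k", u, t @ u)
        for i in d_slots:
            q = dense_mats[kinds[i][1]]
            g1[i] = float(np.sum(cinv * q))
            g2[i] = float(np.sum(t * q))
        return g1, g2

    def fisher_information(cinv, t, w):
        fisher = np.zeros((k, k))
        if u is not None:
            gram = u.T @ (cinv @ u)
            wr = w[r_slots]
            fisher[np.ix_(r_slots, r_slots)] = 0.5 * n * np.outer(wr, wr) * gram**2
        cd = [cinv @ dense_mats[kinds[i][1]] for i in d_slots]
        for a, i in enumerate(d_slots):
            for b, j in enumerate(d_slots):
                fisher[i, j] = 0.5 * n * w[i] * w[j] * np.sum(cd[a].T * cd[b])
            if u is not None:
                cu = cinv @ u
                cross = 0.5 * n * w[i] * w[r_slots] * np.einsum(
                    "mk,mk->k", cu, dense_mats[kinds[i][1]] @ cu)
                fisher[i, r_slots] = cross
                fisher[r_slots, i] = cross
        fisher[np.diag_indices(k)] += 1.0 / h_var
        return fisher

    obj, c, cho, w = objective_parts(lam)
    trajectory = [obj]
    converged = False
    cinv = linalg.cho_solve(cho, np.eye(n_chan))
    t = cinv @ sbar @ cinv
    for iteration in range(opts.max_iter):
        g1, g2 = curvatures(cinv, t, w)
        if opts.solver == "ard":
            with np.errstate(divide="ignore"):
                step = np.log(np.maximum(g2, 1e-300)) - np.log(np.maximum(g1, 1e-300))
            step = np.clip(step, -4.0, 4.0)
        else:
            grad = -0.5 * n * w * (g1 - g2) - (lam - h_mean) / h_var
            fisher = fisher_information(cinv, t, w)
            try:
                step = linalg.solve(fisher, grad, assume_a="pos")
            except linalg.LinAlgError:
                step = linalg.lstsq(fisher, grad)[0]
            nrm = np.max(np.abs(step))
            if nrm > 8.0:  # trust region on the log scale
                step *= 8.0 / nrm
        improved = False
        for _ in range(12):
            cand = np.clip(lam + step, -FIT_SPACE_CLIP, FIT_SPACE_CLIP)
            try:
                obj_new, c_new, cho_new, w_new = objective_parts(cand)
            except linalg.LinAlgError:
                obj_new = -np.inf
            if np.isfinite(obj_new) and obj_new >= obj - 1e-8:
                improved = True
                break
            step *= 0.5
        if not improved:
            converged = True
            break
        delta = obj_new - obj
        lam, obj, c, cho, w = cand, obj_new, c_new, cho_new, w_new
        trajectory.append(obj)
        cinv = linalg.cho_solve(cho, np.eye(n_chan))
        t = cinv @ sbar @ cinv
        logger.info("reml iter=%d F=%.6f dF=%.3e active=%d", iteration + 1, obj, delta,
                    int(np.sum(np.exp(lam) > 1e-3 * np.exp(lam).max())))
        if not np.isfinite(obj):
            raise DataError(f"free energy diverged at iteration {iteration + 1}: "
                            f"lambda={lam}")
        if abs(delta) < opts.tolerance:
            converged = True
            break
    fisher = fisher_information(cinv, t, w)
    return lam, np.asarray(trajectory), fisher, converged


class SourceInversion:
    """PEB source-inversion model: data + lead field + covariance components.

    Parameters
    ----------
    data : array
        Either channels × samples (a single trial or an average) or
        trials × channels × samples.
    leadfield : LeadField or array
    components : ComponentSet or list of source CovComponent
        A plain list is augmented with a white sensor-noise component.
    mode : {"evoked", "induced"}
        Evoked: hyperparameters fitted on the trial-averaged waveforms
        (induced activity cancels in the average).  Induced: fitted on
        the trial-accumulated second-order statistics Σ_i B_i B_iᵀ, which
        retain non-phase-locked power.
    """

    def __init__(self, data, leadfield, components, mode: str = "evoked",
                 sample_rate: float = 1.0):
        if isinstance(data, DataMatrix):
            values = data.values
            sample_rate = data.sample_rate
        else:
            values = np.asarray(data, dtype=float)
        if values.ndim == 2:
            values = values[None]
        if values.ndim != 3:
            raise DataError("data must be 2D or 3D (trials x channels x samples)")
        if mode not in ("evoked", "induced"):
            raise DataError(f"unknown mode {mode!r}")
        self.data = values
        self.sample_rate = sample_rate
        self.leadfield = leadfield
        lmat = leadfield.matrix if isinstance(leadfield, LeadField) else np.asarray(leadfield)
        if values.shape[1] != lmat.shape[0]:
            raise DataError("data channels do not match lead field")
        if isinstance(components, ComponentSet):
            self.components = components
        else:
            self.components = ComponentSet.with_white_noise(components, lmat.shape[0])
        self.mode = mode

    @classmethod
    def from_trialset(cls, trialset, leadfield, components,
                      mode: str = "induced") -> "SourceInversion":
        return cls(trialset.sensor_data, leadfield, components, mode=mode,
                   sample_rate=trialset.config.sample_rate)

    @property
    def averaged_data(self) -> np.ndarray:
        return self.data.mean(axis=0)

    def _second_moment(self) -> tuple[np.ndarray, float]:
        if self.mode == "evoked":
            b = self.averaged_data
            return b @ b.T, b.shape[1]
        s = np.einsum("imt,int->mn", self.data, self.data)
        return s, self.data.shape[0] * self.data.shape[2]

    def fit(self, max_iter: int = 128, tolerance: float = 1e-4,
            hyperprior: HyperPrior | None = None, scale_data: bool = True,
            initial_log_lambda=None, solver: str = "ard") -> "InversionResults":
        opts = ReMLOptions(max_iter=max_iter, tolerance=tolerance,
                           hyperprior=hyperprior or HyperPrior(),
                           scale_data=scale_data,
                           initial_log_lambda=initial_log_lambda, solver=solver)
        u, dmats, kinds, n_chan = _sensor_ops(self.leadfield, self.components)
        if len(kinds) != self.components.n_components:  # pragma: no cover
            raise DataError("component bookkeeping error")
        s, n = self._second_moment()
        scale = 1.0
        comp_scales = np.ones(len(kinds))
        if opts.scale_data:
            tr = np.trace(s) / (n * n_chan)
            if tr > 0:
                scale = tr
            # normalise every sensor-space component to unit mean diagonal
            # so hyperparameters are comparable and the hyperprior mean is
            # meaningful regardless of lead-field units
            for i, (kind, slot) in enumerate(kinds):
                if kind == "r":
                    cs = np.sum(u[:, slot] ** 2) / n_chan
                else:
                    cs = np.trace(dmats[slot]) / n_chan
                if cs > 0:
                    comp_scales[i] = cs
            if u is not None:
                r_cols = [slot for kind, slot in kinds if kind == "r"]
                r_scales = np.asarray([comp_scales[i] for i, (kind, _) in enumerate(kinds)
                                       if kind == "r"])
                u = u / np.sqrt(r_scales)[None, :]
                assert r_cols == sorted(r_cols)
            dmats = [d / comp_scales[i] for i, (kind, slot) in enumerate(kinds)
                     if kind == "d" for d in [dmats[slot]]]
        if opts.initial_log_lambda is not None:
            # warm starts are given on the original component scale
            opts.initial_log_lambda = (np.asarray(opts.initial_log_lambda, dtype=float)
                                       - np.log(scale) + np.log(comp_scales))
        lam, trajectory, fisher, converged = _reml_core(s / scale, n, u, dmats, kinds,
                                                        n_chan, opts)
        # convert to hyperparameters on the *original* components/data scale
        lam = lam + np.log(scale) - np.log(comp_scales)
        # Laplace correction for the hyperparameter uncertainty
        sign, logdet_h = np.linalg.slogdet(fisher)
        k = len(lam)
        laplace = 0.5 * (k * np.log(2.0 * np.pi) - logdet_h) if sign > 0 else 0.0
        return InversionResults(model=self, hyperparameters=Hyperparameters(lam),
                                free_energy=float(trajectory[-1] + laplace),
                                free_energy_trajectory=trajectory,
                                n_iterations=len(trajectory) - 1, converged=converged,
                                data_scale=scale,
                                hyper_posterior_precision=fisher)


class InversionResults:
    """Fitted PEB inversion: hyperparameters, free energy, posteriors."""

    def __init__(self, model: SourceInversion, hyperparameters: Hyperparameters,
                 free_energy: float, free_energy_trajectory: np.ndarray,
                 n_iterations: int, converged: bool, data_scale: float,
                 hyper_posterior_precision: np.ndarray | None = None):
        self.model = model
        self.hyperparameters = hyperparameters
        self.free_energy = free_energy
        self.free_energy_trajectory = np.asarray(free_energy_trajectory, dtype=float)
        self.n_iterations = n_iterations
        self.converged = converged
        self.data_scale = data_scale
        self.hyper_posterior_precision = hyper_posterior_precision
        self.labels = model.components.labels
        self._posterior_op = None

    # -- posterior ---------------------------------------------------------
    @property
    def posterior_operator(self) -> np.ndarray:
        """M = Γ Lᵀ C⁻¹ mapping sensor data to posterior source means.

        Invariant to the internal data rescaling (Γ and C scale together).
        """
        if self._posterior_op is None:
            comps = self.model.components
            u, dmats, kinds, n_chan = _sensor_ops(self.model.leadfield, comps)
            c, w = _assemble_cov(u, dmats, kinds, n_chan, self.hyperparameters.log_lambda)
            cinv = linalg.cho_solve(linalg.cho_factor(c, lower=True), np.eye(n_chan))
            lmat = (self.model.leadfield.matrix if isinstance(self.model.leadfield, LeadField)
                    else np.asarray(self.model.leadfield))
            n_src = lmat.shape[1]
            w_src = w[len(comps.sensor_components):]
            gamma_lt = np.zeros((n_src, n_chan))
            qvecs = [c_.vector for c_ in comps.source_components if c_.is_rank1]
            if qvecs:
                qmat = np.column_stack(qvecs)
                wr = np.asarray([wi for wi, c_ in zip(w_src, comps.source_components)
                                 if c_.is_rank1])
                gamma_lt += (qmat * wr) @ (lmat @ qmat).T
            for wi, c_ in zip(w_src, comps.source_components):
                if not c_.is_rank1:
                    gamma_lt += wi * (c_.matrix @ lmat.T)
            self._posterior_op = gamma_lt @ cinv
        return self._posterior_op

    def posterior_mean(self, B=None) -> np.ndarray:
        """MAP source estimate; default input is the trial-averaged data."""
        if B is None:
            B = self.model.averaged_data
        b = B.values if isinstance(B, DataMatrix) else np.asarray(B, dtype=float)
        return self.posterior_operator @ b

    def trial_posteriors(self) -> np.ndarray:
        """Per-trial posterior means at the fitted hyperparameters."""
        m = self.posterior_operator
        return np.einsum("sm,imt->ist", m, self.model.data)

    def source_power_map(self) -> np.ndarray:
        """Per-vertex RMS posterior amplitude over all trials and samples.

        Always accumulates the per-trial second moments (so induced,
        non-phase-locked power is retained) even when the hyperparameters
        were fitted on the trial average.
        """
        data = self.model.data
        s = np.einsum("imt,int->mn", data, data)
        n = data.shape[0] * data.shape[2]
        m = self.posterior_operator
        power = np.einsum("sm,mn,sn->s", m, s, m) / n
        return np.sqrt(np.maximum(power, 0.0))

    # -- reporting ---------------------------------------------------------
    def summary(self):
        """Per-component hyperparameter table plus fit diagnostics."""
        import pandas as pd

        w = self.hyperparameters.weights
        levels = (["sensor"] * len(self.model.components.sensor_components)
                  + ["source"] * len(self.model.components.source_components))
        df = pd.DataFrame({"component": self.labels, "level": levels,
                           "log_lambda": self.hyperparameters.log_lambda,
                           "weight": w, "weight_share": w / w.sum()})
        df.attrs["free_energy"] = self.free_energy
        df.attrs["n_iterations"] = self.n_iterations
        df.attrs["converged"] = self.converged
        return df

    def plot_free_energy(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.free_energy_trajectory, marker=".")
        ax.set_xlabel("iteration")
        ax.set_ylabel("objective (free energy, up to Laplace term)")
        return ax


def reml_optimize(B, L, comps: ComponentSet, max_iter: int = 128,
                  tolerance: float = 1e-4, hyperprior: HyperPrior | None = None,
                  scale_data: bool = True) -> InversionResults:
    """Functional wrapper: ReML ascent on a single data matrix."""
    model = SourceInversion(B, L, comps, mode="evoked")
    return model.fit(max_iter=max_iter, tolerance=tolerance, hyperprior=hyperprior,
                     scale_data=scale_data)


def invert(B, L, comps: ComponentSet, mode: str = "evoked", **fit_kwargs) -> InversionResults:
    """Estimate hyperparameters once, then expose per-trial posteriors.

    For 3D (trials × channels × samples) input in ``"evoked"`` mode the
    fit uses the trial average; in ``"induced"`` mode the concatenated
    second-order statistics.  A single trial is identical to the average
    path on that trial.
    """
    model = SourceInversion(B, L, comps, mode=mode)
    return model.fit(**fit_kwargs)


def compare_models(results: list[InversionResults]):
    """Rank fitted inversions of the *same* data by free energy."""
    import pandas as pd

    if not results:
        raise DataError("no results to compare")
    shape0 = results[0].model.data.shape
    for r in results[1:]:
        if r.model.data.shape != shape0:
            raise DataError("compare_models requires identical data shapes")
    rows = sorted(range(len(results)), key=lambda i: -results[i].free_energy)
    best = results[rows[0]].free_energy
    return pd.DataFrame({
        "model": rows,
        "free_energy": [results[i].free_energy for i in rows],
        "delta_F": [results[i].free_energy - best for i in rows],
        "n_components": [results[i].model.components.n_components for i in rows],
    })
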