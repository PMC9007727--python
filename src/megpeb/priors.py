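"""fMRI spatial priors as source-covariance components.

A thresholded statistical volume (SPM{T}-style) is decomposed into
face-connected clusters; each cluster is binarised (Heaviside), projected
onto the cortical mesh by Voronoi assignment of its voxels to their
nearest vertices, smoothed with a truncated mesh Green's function
G = exp(σA) ≈ Σ_{i=0..K} σ^i/i! A^i (A the vertex adjacency matrix), and
turned into a rank-1 covariance component Q = q qᵀ.  The components carry
only spatial information — their overall scale is estimated from the MEG
data by the inversion — so q is normalised to unit Euclidean norm by
default.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.spatial import cKDTree

from .exceptions import DataError
from .geometry import CorticalMesh


@dataclass
class StatVolume:
    """3D statistic grid with a voxel-index → mm affine."""

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise DataError("StatVolume values must be 3D")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise DataError("affine must be an invertible 4x4 matrix")
        if not np.all(np.isfinite(self.values)):
            raise DataError("StatVolume values must be finite")

    def voxel_coords_mm(self, indices: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(indices, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def to_nifti(self, path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.values.astype(np.float32), self.affine), path)

    @classmethod
    def from_nifti(cls, path) -> "StatVolume":
        import nibabel as nib

        img = nib.load(path)
        return cls(np.asarray(img.get_fdata(), dtype=float), img.affine)


@dataclass
class Cluster:
    """One suprathreshold, face-connected voxel cluster."""

    voxel_indices: np.ndarray  # (k, 3) int
    size: int
    peak_value: float


@dataclass
class VertexIndicator:
    """Nonnegative per-vertex weights q_i attached to one cluster."""

    weights: np.ndarray
    source_cluster: int = -1

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise DataError("indicator weights must be nonnegative")

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.weights > 0)


@dataclass
class SmoothingSpec:
    """Green's-function smoothing: parameter σ, series order, adjacency."""

    adjacency: sparse.spmatrix
    sigma: float = 0.6
    truncation_order: int = 8

    def __post_init__(self):
        if self.sigma < 0:
            raise DataError("sigma must be nonnegative")
        if self.truncation_order < 0:
            raise DataError("truncation_order must be >= 0")
        a = sparse.csr_matrix(self.adjacency)
        if (a != a.T).nnz != 0 or a.diagonal().any():
            raise DataError("adjacency must be symmetric with an empty diagonal")
        self.adjacency = a


@dataclass
class CovComponent:
    """Covariance basis matrix Q_i, rank-1 (vector q) or dense.

    fMRI and cortical-patch components are rank 1 at the source level;
    the default sensor-noise component is the identity.
    """

    level: str
    vector: np.ndarray | None = None
    matrix: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        if self.level not in ("source", "sensor"):
            raise DataError(f"unknown component level {self.level!r}")
        if (self.vector is None) == (self.matrix is None):
            raise DataError("exactly one of vector/matrix must be given")
        if self.vector is not None:
            self.vector = np.asarray(self.vector, dtype=float).ravel()
        else:
            self.matrix = np.asarray(self.matrix, dtype=float)

    @property
    def is_rank1(self) -> bool:
        return self.vector is not None

    @property
    def dim(self) -> int:
        return len(self.vector) if self.is_rank1 else self.matrix.shape[0]

    def dense(self) -> np.ndarray:
        """Q as a dense matrix (intended for small problems and tests)."""
        if self.is_rank1:
            return np.outer(self.vector, self.vector)
        return self.matrix

    @classmethod
    def identity(cls, n: int, level: str = "sensor", label: str = "white noise") -> "CovComponent":
        return cls(level=level, matrix=np.eye(n), label=label)


def threshold_statmap(vol: StatVolume, height_T: float, extent_k: int) -> list[Cluster]:
    """Face-connected clusters with value > height_T and size >= extent_k.

    Returned sorted by descending peak value; an empty list is fine.
    """
    if not np.isfinite(height_T):
        raise DataError("height threshold must be finite")
    if extent_k < 1:
        raise DataError("extent threshold must be >= 1")
    mask = vol.values > height_T
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, n = ndimage.label(mask, structure=structure)
    clusters = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        if len(idx) < extent_k:
            continue
        peak = float(vol.values[tuple(idx.T)].max())
        clusters.append(Cluster(idx, len(idx), peak))
    clusters.sort(key=lambda c: -c.peak_value)
    return clusters


def voronoi_project(cluster: Cluster, vol: StatVolume, mesh: CorticalMesh,
                    max_distance_mm: float = 20.0) -> VertexIndicator:
    """Binary Voronoi projection of a cluster onto the mesh.

    Each suprathreshold voxel (already binarised by the thresholding) is
    assigned to its nearest mesh vertex; vertices owning at least one
    voxel get weight 1.  Voxels farther than ``max_distance_mm`` from the
    mesh are dropped; if all are dropped a warning is issued and an
    all-zero indicator returned.
    """
    if cluster.size == 0:
        raise DataError("empty cluster")
    coords = vol.voxel_coords_mm(cluster.voxel_indices)
    dist, idx = cKDTree(mesh.vertices).query(coords)
    keep = dist <= max_distance_mm
    weights = np.zeros(mesh.n_vertices)
    if not keep.any():
        warnings.warn("cluster lies farther than "
                      f"{max_distance_mm:g} mm from the mesh; empty indicator", stacklevel=2)
        return VertexIndicator(weights)
    weights[np.unique(idx[keep])] = 1.0
    return VertexIndicator(weights)


def green_smooth(q: VertexIndicator | np.ndarray, spec: SmoothingSpec) -> VertexIndicator:
    """Apply the truncated Green's function G·q.

    σ = 0 reduces to the identity; output weights stay nonnegative and
    the support grows by at most ``truncation_order`` graph hops.
    """
    w = q.weights if isinstance(q, VertexIndicator) else np.asarray(q, dtype=float)
    cluster_id = q.source_cluster if isinstance(q, VertexIndicator) else -1
    if spec.adjacency.shape[0] != len(w):
        raise DataError("adjacency dimension does not match vertex count")
    out = _green_apply(spec, w)
    return VertexIndicator(np.maximum(out, 0.0), cluster_id)


def _green_apply(spec: SmoothingSpec, x: np.ndarray) -> np.ndarray:
    """Σ_{i=0..K} σ^i/i! A^i applied to a vector or column stack."""
    out = x.astype(float).copy()
    term = out.copy()
    for i in range(1, spec.truncation_order + 1):
        term = (spec.sigma / i) * (spec.adjacency @ term)
        out += term
    return out


def green_kernel(spec: SmoothingSpec) -> np.ndarray:
    """Dense G (small meshes only)."""
    n = spec.adjacency.shape[0]
    return _green_apply(spec, np.eye(n))


def make_covariance_component(q: VertexIndicator, normalize: bool = True,
                              label: str = "") -> CovComponent:
    """Rank-1 source component Q = q qᵀ (q unit-norm when ``normalize``)."""
    w = q.weights.astype(float)
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise DataError("cannot build a covariance component from an all-zero indicator")
    return CovComponent(level="source", vector=w / nrm if normalize else w,
                        label=label or f"fmri cluster {q.source_cluster}")


def build_prior_set(vol: StatVolume, mesh: CorticalMesh, height_T: float,
                    extent_k: int, spec: SmoothingSpec, normalize: bool = True,
                    max_distance_mm: float = 20.0) -> list[CovComponent]:
    """Threshold → project → smooth → outer product, one component per cluster.

    Cluster order (descending peak) is preserved; clusters that project
    to nothing on the mesh are skipped with a warning.
    """
    comps = []
    for k, cluster in enumerate(threshold_statmap(vol, height_T, extent_k)):
        ind = voronoi_project(cluster, vol, mesh, max_distance_mm=max_distance_mm)
        ind.source_cluster = k
        if not ind.weights.any():
            warnings.warn(f"cluster {k} projected to no vertices; skipped", stacklevel=2)
            continue
        comps.append(make_covariance_component(green_smooth(ind, spec), normalize=normalize,
                                               label=f"fmri cluster {k}"))
    return comps


def component_centroid_mm(comp: CovComponent, mesh: CorticalMesh) -> np.ndarray:
    """Weight-averaged position of a rank-1 source component."""
    if not comp.is_rank1:
        raise DataError("centroid defined for rank-1 components only")
    w = comp.vector
    return (w @ mesh.vertices) / w.sum()
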