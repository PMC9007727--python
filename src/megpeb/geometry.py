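"""Source/sensor geometry and the single-sphere MEG forward model.

The forward model is the closed-form magnetic field of a current dipole
inside a homogeneous conducting sphere (Sarvas formula), projected onto
point magnetometers.  For a spherical conductor the field outside the
head depends only on the primary (dipolar) current, the volume-current
contribution is captured exactly by the closed form, and any radial
dipole component is magnetically silent.

Unit conventions: user-facing coordinates are millimetres in MNI-style
axes (x right, y anterior, z superior); everything that touches the
physics (``SensorArray``, ``SphereModel``, ``sarvas_field``) is in
metres and tesla.  Conversion happens explicitly at module boundaries
(``build_leadfield`` takes a mesh in mm and emits T/(A·m)).
"""
from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import ConvexHull

from .exceptions import DataError, GeometryError, SingularGeometryError

MU0_OVER_4PI = 1e-7  # T·m/A

#: Default simulated dipole positions (mm, MNI): an evoked frontal source
#: and an induced temporal source.
MNI_DIPOLE_EVOKED = (-38.0, 43.0, 5.0)
MNI_DIPOLE_INDUCED = (-54.0, -13.0, 5.0)
DEFAULT_DIPOLES_MM = (MNI_DIPOLE_EVOKED, MNI_DIPOLE_INDUCED)


@dataclass(frozen=True)
class SphereModel:
    """Homogeneous conducting sphere; ``center`` and ``radius`` in metres."""

    center: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))
        if not self.radius > 0:
            raise GeometryError(f"sphere radius must be positive, got {self.radius}")

    def contains(self, points_m: np.ndarray, strict: bool = True) -> np.ndarray:
        """Boolean mask of points inside the sphere."""
        d = np.linalg.norm(np.atleast_2d(points_m) - self.center, axis=1)
        return d < self.radius if strict else d <= self.radius


@dataclass(frozen=True)
class SensorArray:
    """Point magnetometers: positions (metres) and unit pickup orientations."""

    positions: np.ndarray
    orientations: np.ndarray
    names: tuple = ()

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        ori = np.asarray(self.orientations, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape != ori.shape:
            raise GeometryError("positions and orientations must both be (n, 3)")
        norms = np.linalg.norm(ori, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise GeometryError("sensor orientations must have unit norm (±1e-9)")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "orientations", ori)
        if not self.names:
            object.__setattr__(self, "names", tuple(f"MEG{i:03d}" for i in range(len(pos))))

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    def to_csv(self, path) -> None:
        """Write ``name,x,y,z,ox,oy,oz`` with coordinates in mm."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["name", "x", "y", "z", "ox", "oy", "oz"])
            for name, p, o in zip(self.names, self.positions * 1e3, self.orientations):
                w.writerow([name, *(f"{v:.6f}" for v in p), *(f"{v:.9f}" for v in o)])

    @classmethod
    def from_csv(cls, path) -> "SensorArray":
        names, pos, ori = [], [], []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                names.append(row["name"])
                pos.append([float(row[k]) for k in ("x", "y", "z")])
                ori.append([float(row[k]) for k in ("ox", "oy", "oz")])
        return cls(np.asarray(pos) / 1e3, np.asarray(ori), tuple(names))


def _vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area-weighted vertex normals from consistently oriented faces."""
    v = vertices
    fn = np.cross(v[faces[:, 1]] - v[faces[:, 0]], v[faces[:, 2]] - v[faces[:, 0]])
    normals = np.zeros_like(v)
    for k in range(3):
        np.add.at(normals, faces[:, k], fn)
    n = np.linalg.norm(normals, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return normals / n


def _face_adjacency(n_vertices: int, faces: np.ndarray) -> sparse.csr_matrix:
    ii = np.concatenate([faces[:, 0], faces[:, 1], faces[:, 2]])
    jj = np.concatenate([faces[:, 1], faces[:, 2], faces[:, 0]])
    a = sparse.coo_matrix((np.ones_like(ii, dtype=float), (ii, jj)), shape=(n_vertices, n_vertices))
    a = ((a + a.T) > 0).astype(float)
    a.setdiag(0)
    a.eliminate_zeros()
    return a.tocsr()


@dataclass
class CorticalMesh:
    """Triangulated cortical surface; vertices in mm (MNI-style axes)."""

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray
    adjacency: sparse.csr_matrix

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self.normals = np.asarray(self.normals, dtype=float)
        nv = self.vertices.shape[0]
        if nv == 0:
            raise DataError("empty mesh")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= nv):
            raise DataError("face indices out of range")
        if not np.allclose(np.linalg.norm(self.normals, axis=1), 1.0, atol=1e-9):
            raise DataError("vertex normals must have unit norm")
        if (self.adjacency != self.adjacency.T).nnz != 0:
            raise DataError("adjacency must be symmetric")
        if self.adjacency.diagonal().any():
            raise DataError("adjacency must have an empty diagonal")

    @classmethod
    def from_vertices_faces(cls, vertices: np.ndarray, faces: np.ndarray) -> "CorticalMesh":
        vertices = np.asarray(vertices, dtype=float)
        faces = np.asarray(faces, dtype=int)
        return cls(vertices, faces, _vertex_normals(vertices, faces),
                   _face_adjacency(len(vertices), faces))

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def vertices_within(self, center_mm, radius_mm: float) -> np.ndarray:
        """Indices of vertices within ``radius_mm`` of ``center_mm``."""
        d = np.linalg.norm(self.vertices - np.asarray(center_mm, dtype=float), axis=1)
        return np.flatnonzero(d <= radius_mm)

    def to_csv(self, vertices_path, faces_path) -> None:
        np.savetxt(vertices_path, self.vertices, delimiter=",", header="x,y,z", comments="")
        np.savetxt(faces_path, self.faces, delimiter=",", fmt="%d", header="i,j,k", comments="")

    @classmethod
    def from_csv(cls, vertices_path, faces_path) -> "CorticalMesh":
        v = np.loadtxt(vertices_path, delimiter=",", skiprows=1)
        f = np.loadtxt(faces_path, delimiter=",", skiprows=1, dtype=int)
        return cls.from_vertices_faces(v, np.atleast_2d(f))

    def to_gifti(self, path) -> None:
        import nibabel as nib

        g = nib.gifti.GiftiImage(darrays=[
            nib.gifti.GiftiDataArray(self.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"),
            nib.gifti.GiftiDataArray(self.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"),
        ])
        nib.save(g, path)

    @classmethod
    def from_gifti(cls, path) -> "CorticalMesh":
        import nibabel as nib

        g = nib.load(path)
        v = g.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
        f = g.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
        return cls.from_vertices_faces(np.asarray(v, float), np.asarray(f, int))


@dataclass
class LeadField:
    """Sensor gain matrix in T/(A·m).

    ``moment_convention`` is ``"fixed-normal"`` (one column per vertex,
    dipole along the vertex normal) or ``"free"`` (three columns per
    vertex, unit x/y/z moments, vertex-major ordering).
    """

    matrix: np.ndarray
    source_positions_mm: np.ndarray
    moment_convention: str
    outside_mask: np.ndarray | None = None

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.source_positions_mm.shape[0]


def _check_sphere_geometry(dipole_pos: np.ndarray, sensors: SensorArray, sphere: SphereModel):
    if np.linalg.norm(sensors.positions - dipole_pos, axis=1).min() < 1e-12:
        raise SingularGeometryError("dipole coincident with a sensor")
    r0 = dipole_pos - sphere.center
    if np.linalg.norm(r0) >= sphere.radius:
        raise GeometryError("dipole must lie strictly inside the sphere")
    rs = np.linalg.norm(sensors.positions - sphere.center, axis=1)
    if np.any(rs <= sphere.radius):
        raise GeometryError("all sensors must lie strictly outside the sphere")


def _sarvas_projected(r0s: np.ndarray, qs: np.ndarray, sensors: SensorArray,
                      sphere: SphereModel) -> np.ndarray:
    """Sarvas field for k dipoles, projected on sensor orientations → (n_chan, k)."""
    r = sensors.positions - sphere.center          # (n, 3)
    r0 = np.atleast_2d(r0s)                        # (k, 3)
    q = np.atleast_2d(qs)                          # (k, 3)
    a_vec = r[:, None, :] - r0[None, :, :]         # (n, k, 3)
    a = np.linalg.norm(a_vec, axis=2)              # (n, k)
    if np.any(a < 1e-12):
        raise SingularGeometryError("dipole coincident with a sensor")
    R = np.linalg.norm(r, axis=1)[:, None]         # (n, 1)
    r0_dot_r = r @ r0.T                            # (n, k)
    F = a * (R * a + R**2 - r0_dot_r)
    a_dot_r = np.einsum("nkj,nj->nk", a_vec, r)
    c1 = a**2 / R + a_dot_r / a + 2.0 * a + 2.0 * R             # (n, k)
    c2 = a + 2.0 * R + a_dot_r / a                              # (n, k)
    grad_f = c1[:, :, None] * r[:, None, :] - c2[:, :, None] * r0[None, :, :]
    q_x_r0 = np.cross(q, r0)                                    # (k, 3)
    qr0_dot_r = r @ q_x_r0.T                                    # (n, k)
    b_vec = (F[:, :, None] * q_x_r0[None, :, :] - qr0_dot_r[:, :, None] * grad_f)
    b_vec *= MU0_OVER_4PI / (F**2)[:, :, None]
    return np.einsum("nkj,nj->nk", b_vec, sensors.orientations)


def sarvas_field(dipole_pos, dipole_moment, sensors: SensorArray,
                 sphere: SphereModel) -> np.ndarray:
    """Magnetic field of one current dipole, projected per channel.

    Parameters are in SI units: ``dipole_pos`` in metres, ``dipole_moment``
    in A·m.  Returns one value per channel in tesla.  The field is linear
    in the moment, and both a radial moment and a dipole at the sphere
    center produce an identically zero field.
    """
    dipole_pos = np.asarray(dipole_pos, dtype=float).reshape(3)
    dipole_moment = np.asarray(dipole_moment, dtype=float).reshape(3)
    _check_sphere_geometry(dipole_pos, sensors, sphere)
    return _sarvas_projected(dipole_pos - sphere.center, dipole_moment, sensors, sphere)[:, 0]


def build_leadfield(mesh: CorticalMesh, sensors: SensorArray, sphere: SphereModel,
                    moment_convention: str = "fixed-normal") -> LeadField:
    """Lead-field matrix for every mesh vertex (mesh in mm, output T/(A·m)).

    Vertices outside the sphere are flagged and their columns zeroed; a
    fully interior mesh never triggers the flag.
    """
    if moment_convention not in ("fixed-normal", "free"):
        raise DataError(f"unknown moment convention {moment_convention!r}")
    pos_m = mesh.vertices / 1e3
    r0s = pos_m - sphere.center
    dist = np.linalg.norm(r0s, axis=1)
    outside = dist >= sphere.radius
    if outside.any():
        warnings.warn(f"{outside.sum()} mesh vertices lie outside the sphere; "
                      "their lead-field columns are zeroed", stacklevel=2)
    rs = np.linalg.norm(sensors.positions - sphere.center, axis=1)
    if np.any(rs <= sphere.radius):
        raise GeometryError("all sensors must lie strictly outside the sphere")
    inside = ~outside
    cols_xyz = np.zeros((sensors.n_channels, mesh.n_vertices, 3))
    eye = np.eye(3)
    for j in range(3):
        q = np.tile(eye[j], (int(inside.sum()), 1))
        cols_xyz[:, inside, j] = _sarvas_projected(r0s[inside], q, sensors, sphere)
    if moment_convention == "free":
        matrix = cols_xyz.reshape(sensors.n_channels, mesh.n_vertices * 3)
    else:
        matrix = np.einsum("nvj,vj->nv", cols_xyz, mesh.normals)
    return LeadField(matrix, mesh.vertices.copy(), moment_convention,
                     outside_mask=outside if outside.any() else None)


def nearest_vertex(position_mm, mesh: CorticalMesh) -> int:
    """Index of the mesh vertex closest to ``position_mm`` (ties → lowest index)."""
    d = np.linalg.norm(mesh.vertices - np.asarray(position_mm, dtype=float), axis=1)
    return int(np.argmin(d))


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    ga = np.pi * (3.0 - np.sqrt(5.0))
    return np.column_stack([rho * np.cos(ga * i), rho * np.sin(ga * i), z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def generate_fixture_geometry(n_vertices: int = 2000, seed: int = 0,
                              n_channels: int = 275,
                              dipole_positions_mm=DEFAULT_DIPOLES_MM,
                              ) -> tuple[CorticalMesh, SensorArray, SphereModel]:
    """Deterministic synthetic cortical shell + helmet sensor array.

    The shell is a corrugated sphere of base radius 70 mm: smooth radial
    plane-wave bumps give the vertex normals a substantial tangential
    component (a purely radial shell would be magnetically silent for
    normal-constrained dipoles), and the surface is locally blended
    toward each requested dipole position so that one vertex sits exactly
    at each dipole.  Sensors form a 275-channel helmet of radial point
    magnetometers at 120 mm radius; head sphere radius 90 mm.
    """
    if n_vertices < 12:
        raise DataError("n_vertices must be at least 12")
    rng = np.random.default_rng(seed)
    dirs = _fibonacci_sphere(n_vertices) @ _random_rotation(rng).T

    waves = []  # corrugation: smooth seeded plane waves, amp 3 mm
    for _ in range(3):
        k = rng.normal(size=3)
        k *= rng.uniform(8.0, 14.0) / np.linalg.norm(k)
        waves.append((k, rng.uniform(0, 2 * np.pi)))

    def corrugation(points):
        return sum(3.0 * np.sin(points @ k + phase) for k, phase in waves)

    base = np.full(n_vertices, 70.0)
    corr = corrugation(dirs)
    dipoles = [np.asarray(p, dtype=float) for p in dipole_positions_mm]
    for p in dipoles:
        # Blend the base radius toward the dipole radius and shift the
        # corrugation to zero *value* there while keeping its gradient, so
        # the surface passes through the dipole with a tilted normal (a
        # locally spherical patch would be magnetically silent for
        # normal-constrained dipoles).
        d_hat = p / np.linalg.norm(p)
        ang = np.arccos(np.clip(dirs @ d_hat, -1.0, 1.0))
        w = np.exp(-0.5 * (ang / 0.25) ** 2)
        base = (1.0 - w) * base + w * np.linalg.norm(p)
        corr = corr - w * float(corrugation(d_hat[None, :])[0])
        # deterministic local wave: zero value but guaranteed slope at the
        # dipole direction, so the snapped vertex normal is never radial
        t_hat = np.cross(d_hat, [0.0, 0.0, 1.0])
        t_hat /= np.linalg.norm(t_hat)
        corr = corr + 4.0 * w * np.sin(12.0 * ((dirs - d_hat) @ t_hat))

    vertices = dirs * (base + corr)[:, None]
    used = set()
    for p in dipoles:  # snap one vertex exactly onto each dipole
        d = np.linalg.norm(vertices - p, axis=1)
        d[list(used)] = np.inf
        i = int(np.argmin(d))
        vertices[i] = p
        used.add(i)

    hull = ConvexHull(dirs)
    faces = hull.simplices.copy()
    centers = dirs[faces].mean(axis=1)
    fn = np.cross(dirs[faces[:, 1]] - dirs[faces[:, 0]], dirs[faces[:, 2]] - dirs[faces[:, 0]])
    flip = np.einsum("fj,fj->f", fn, centers) < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    mesh = CorticalMesh.from_vertices_faces(vertices, faces)

    sphere = SphereModel(np.zeros(3), 0.09)
    if not sphere.contains(mesh.vertices / 1e3).all():
        raise GeometryError("fixture mesh escaped the head sphere")  # pragma: no cover

    sdirs = _fibonacci_sphere(int(np.ceil(n_channels * 1.45)))
    sdirs = sdirs[np.argsort(-sdirs[:, 2])[:n_channels]]  # helmet: keep topmost
    sensors = SensorArray(0.12 * sdirs, sdirs)
    return mesh, sensors, sphere


def save_geometry_json(path, mesh: CorticalMesh, sensors: SensorArray,
                       sphere: SphereModel) -> None:
    """Plain-text round-trip of a full geometry bundle."""
    payload = {
        "vertices_mm": mesh.vertices.tolist(),
        "faces": mesh.faces.tolist(),
        "sensor_positions_m": sensors.positions.tolist(),
        "sensor_orientations": sensors.orientations.tolist(),
        "sphere_center_m": sphere.center.tolist(),
        "sphere_radius_m": sphere.radius,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_geometry_json(path) -> tuple[CorticalMesh, SensorArray, SphereModel]:
    with open(path) as fh:
        p = json.load(fh)
    mesh = CorticalMesh.from_vertices_faces(np.asarray(p["vertices_mm"]), np.asarray(p["faces"]))
    sensors = SensorArray(np.asarray(p["sensor_positions_m"]), np.asarray(p["sensor_orientations"]))
    sphere = SphereModel(np.asarray(p["sphere_center_m"]), p["sphere_radius_m"])
    return mesh, sensors, sphere
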