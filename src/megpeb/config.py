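"""Flat key=value run configuration, hashing and run manifests."""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields

import numpy as np

from .exceptions import ConfigError
from .study import StudyConfig

CONFIG_VERSION = "1"


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run.

    The file dialect is one ``key = value`` pair per line, ``#`` comments,
    with mandatory ``version`` and ``seed`` keys.  The hash is computed on
    the canonically sorted key=value text, so it is stable under field
    ordering.
    """

    seed: int = 0
    n_vertices: int = 600
    n_channels: int = 275
    n_trials: int = 20
    snr_db: float = np.inf
    n_patches: int = 128
    sigma: float = 0.6
    truncation_order: int = 8
    height_T: float = 5.0
    extent_k: int = 10
    blob_radius_mm: float = 10.0
    peak_T: float = 10.0
    label_radius_mm: float = 10.0
    voi_radius_mm: float = 10.0
    max_iter: int = 128
    tolerance: float = 1e-4
    version: str = CONFIG_VERSION

    def to_text(self) -> str:
        items = sorted(asdict(self).items())
        return "".join(f"{k} = {v}\n" for k, v in items)

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def read(cls, path) -> "RunConfig":
        values = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
                k, v = (part.strip() for part in line.split("=", 1))
                values[k] = v
        if "version" not in values:
            raise ConfigError(f"{path}: missing mandatory 'version' key")
        if "seed" not in values:
            raise ConfigError(f"{path}: missing mandatory 'seed' key")
        if values["version"] != CONFIG_VERSION:
            raise ConfigError(f"{path}: unsupported config version {values['version']!r}")
        kwargs = {}
        known = {f.name: f.type for f in fields(cls)}
        for k, v in values.items():
            if k not in known:
                raise ConfigError(f"{path}: unknown key {k!r}")
            if k == "version":
                kwargs[k] = v
            elif k in ("seed", "n_vertices", "n_channels", "n_trials", "n_patches",
                       "extent_k", "max_iter", "truncation_order"):
                kwargs[k] = int(v)
            else:
                kwargs[k] = float(v)
        return cls(**kwargs)

    def study_config(self, noise_levels_db=None, **overrides) -> StudyConfig:
        sc = StudyConfig(seed=self.seed, n_vertices=self.n_vertices,
                         n_channels=self.n_channels, n_trials=self.n_trials,
                         n_patches=self.n_patches, sigma=self.sigma,
                         truncation_order=self.truncation_order, height_T=self.height_T,
                         extent_k=self.extent_k, blob_radius_mm=self.blob_radius_mm,
                         peak_T=self.peak_T, label_radius_mm=self.label_radius_mm,
                         voi_radius_mm=self.voi_radius_mm, max_iter=self.max_iter,
                         tolerance=self.tolerance)
        if noise_levels_db is not None:
            sc.noise_levels_db = tuple(noise_levels_db)
        for k, v in overrides.items():
            setattr(sc, k, v)
        return sc


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Checksums and timings of a pipeline stage's outputs."""

    config_hash: str
    software_version: str
    files: dict = field(default_factory=dict)
    wall_clock_s: dict = field(default_factory=dict)
    log_path: str = ""

    def add_file(self, path) -> None:
        self.files[str(path)] = file_sha256(path)

    def record_time(self, stage: str, seconds: float) -> None:
        self.wall_clock_s[stage] = round(seconds, 3)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))

    def verify(self) -> list[str]:
        """Paths whose current checksum no longer matches the manifest."""
        bad = []
        for path, digest in self.files.items():
            try:
                ok = file_sha256(path) == digest
            except OSError:
                ok = False
            if not ok:
                bad.append(path)
        return bad


class StageTimer:
    def __init__(self, manifest: RunManifest, stage: str):
        self.manifest, self.stage = manifest, stage

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.manifest.record_time(self.stage, time.perf_counter() - self.t0)
        return False
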