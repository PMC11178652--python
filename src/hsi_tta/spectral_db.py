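"""Synthetic spectral database and pixel-wise nearest-neighbor retrieval.

The database pairs N uniformly sampled tissue parameter vectors with their
forward-simulated, camera-resampled, L1-normalized spectra. Converting a
hyperspectral image into its "digital twin" means replacing every pixel by
the database record whose spectrum is closest (Euclidean distance in the
L1-normalized 100-band camera space), which annotates the image with the
generative parameters (StO2, VHb, ...) of the matched records.

The nearest-neighbor index is an exact chunked brute-force search: distances
come from the squared-norm expansion ``|q|^2 - 2 q.x + |x|^2`` evaluated with
BLAS in memory-bounded chunks, ties broken deterministically toward the
lowest record id, and the reported distance recomputed exactly for the
selected pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .errors import DataError
from . import optics
from .optics import (
    PARAM_FIELDS,
    PARAM_RANGES,
    CameraModel,
    ChromophoreTable,
    WavelengthGrid,
    camera_grid,
    l1_normalize,
    simulation_grid,
)

__all__ = [
    "NNIndex",
    "SyntheticDatabase",
    "HSICube",
    "TwinMap",
    "sample_params",
    "build_database",
    "nearest_spectrum",
    "generate_twin",
]


class NNIndex:
    """Exact nearest-neighbor search over row vectors, lowest-id tie-break."""

    def __init__(self, X: np.ndarray, chunk_rows: int = 512):
        self.X = np.ascontiguousarray(X, dtype=float)
        self.sq_norms = (self.X**2).sum(axis=1)
        self.chunk_rows = int(chunk_rows)

    def query(self, Q: np.ndarray, subset: np.ndarray | None = None):
        """Return (ids, distances) of the closest row for each query.

        ``subset`` restricts the search to the given record ids; returned ids
        are always into the full array.
        """
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        if Q.shape[1] != self.X.shape[1]:
            raise DataError(
                f"query dimension {Q.shape[1]} != index dimension {self.X.shape[1]}"
            )
        if subset is not None:
            subset = np.asarray(subset, dtype=np.int64)
            if subset.size == 0:
                raise DataError("nearest-neighbor subset is empty")
            X, n2 = self.X[subset], self.sq_norms[subset]
        else:
            X, n2 = self.X, self.sq_norms
        ids = np.empty(Q.shape[0], dtype=np.int64)
        for a in range(0, Q.shape[0], self.chunk_rows):
            qc = Q[a : a + self.chunk_rows]
            d2 = (qc**2).sum(axis=1)[:, None] - 2.0 * (qc @ X.T) + n2[None, :]
            # np.argmin returns the first minimum -> lowest-id tie-break
            ids[a : a + self.chunk_rows] = d2.argmin(axis=1)
        if subset is not None:
            ids = subset[ids]
        dists = np.linalg.norm(Q - self.X[ids], axis=1)
        return ids, dists


@dataclass
class SyntheticDatabase:
    """Paired parameter vectors and spectra with a nearest-neighbor index.

    ``params`` is (N, 8) in optics.PARAM_FIELDS order, ``spectra_cam`` the
    (N, 100) L1-normalized camera-space spectra, ``spectra_raw`` optionally
    the (N, 351) un-normalized simulation-grid reflectance.
    """

    params: np.ndarray
    spectra_cam: np.ndarray
    spectra_raw: np.ndarray | None = None
    meta: dict = field(default_factory=dict)
    _index: NNIndex | None = field(default=None, repr=False)

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        self.spectra_cam = np.asarray(self.spectra_cam, dtype=float)
        n = self.params.shape[0]
        if n < 1 or self.params.shape[1] != len(PARAM_FIELDS):
            raise DataError("database params must be a nonempty (N, 8) array")
        if self.spectra_cam.shape != (n, 100):
            raise DataError("database camera spectra must be (N, 100)")
        sums = np.abs(self.spectra_cam).sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise DataError("database camera spectra must be L1-normalized")

    def __len__(self) -> int:
        return self.params.shape[0]

    @property
    def sto2(self) -> np.ndarray:
        return self.params[:, PARAM_FIELDS.index("sto2")]

    @property
    def vhb(self) -> np.ndarray:
        return self.params[:, PARAM_FIELDS.index("vhb")]

    @property
    def index(self) -> NNIndex:
        if self._index is None:
            self._index = NNIndex(self.spectra_cam)
        return self._index

    def subset(self, rows) -> "SyntheticDatabase":
        """A new database over a row selection (records stay iid samples)."""
        raw = None if self.spectra_raw is None else self.spectra_raw[rows]
        return SyntheticDatabase(
            self.params[rows], self.spectra_cam[rows], raw, dict(self.meta)
        )

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("params", data=self.params)
            d.attrs["columns"] = list(PARAM_FIELDS)
            f.create_dataset("spectra_cam", data=self.spectra_cam)
            if self.spectra_raw is not None:
                f.create_dataset("spectra_raw", data=self.spectra_raw)
            f.create_group("meta").attrs["json"] = json.dumps(self.meta)

    @classmethod
    def load(cls, path) -> "SyntheticDatabase":
        with h5py.File(path, "r") as f:
            params = f["params"][...]
            cam = f["spectra_cam"][...]
            raw = f["spectra_raw"][...] if "spectra_raw" in f else None
            meta = json.loads(f["meta"].attrs["json"]) if "meta" in f else {}
        return cls(params, cam, raw, meta)


@dataclass
class HSICube:
    """H x W x 100 hyperspectral image on the camera grid."""

    values: np.ndarray
    grid: WavelengthGrid = field(default_factory=camera_grid)
    subject_id: str = ""
    image_id: str = ""
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != len(self.grid):
            raise DataError(
                f"cube must be (H, W, {len(self.grid)}), got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(f"non-finite value at pixel ({bad[0]}, {bad[1]})")
        if self.normalized:
            sums = self.values.sum(axis=2)
            if np.any(np.abs(sums - 1.0) > 1e-6):
                raise DataError("normalized flag set but pixel spectra do not sum to 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    def flat(self) -> np.ndarray:
        return self.values.reshape(-1, self.values.shape[2])

    def normalized_copy(self) -> "HSICube":
        if self.normalized:
            return self
        return HSICube(
            l1_normalize(self.values, axis=2),
            self.grid,
            self.subject_id,
            self.image_id,
            normalized=True,
        )


@dataclass
class TwinMap:
    """Per-pixel digital-twin annotation of a cube."""

    record_id: np.ndarray
    sto2_map: np.ndarray
    vhb_map: np.ndarray
    distance_map: np.ndarray

    def __post_init__(self):
        s = self.record_id.shape
        for a in (self.sto2_map, self.vhb_map, self.distance_map):
            if a.shape != s:
                raise DataError("twin map layers have inconsistent shapes")
        if np.any(self.distance_map < 0):
            raise DataError("negative nearest-neighbor distance")


def sample_params(
    n: int, ranges: dict | None = None, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw n parameter vectors, each field independent uniform within its bounds.

    ``ranges`` maps field name -> (lo, hi) overriding the defaults; bounds
    must stay inside optics.PARAM_RANGES.
    """
    if n < 1:
        raise DataError("need n >= 1 parameter samples")
    bounds = dict(PARAM_RANGES)
    for k, (lo, hi) in (ranges or {}).items():
        if k not in bounds:
            raise DataError(f"unknown parameter {k!r}")
        blo, bhi = PARAM_RANGES[k]
        if lo < blo or hi > bhi or lo > hi:
            raise DataError(f"bounds for {k!r} outside admissible range [{blo}, {bhi}]")
        bounds[k] = (float(lo), float(hi))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols = [rng.uniform(*bounds[k], size=n) for k in PARAM_FIELDS]
    return np.column_stack(cols)


def build_database(
    n: int = 500_000,
    ranges: dict | None = None,
    cam: CameraModel | None = None,
    table: ChromophoreTable | None = None,
    seed: int = 0,
    store_raw: bool = True,
) -> SyntheticDatabase:
    """Simulate, camera-resample and L1-normalize n records into a database."""
    cam = cam or CameraModel()
    table = table or ChromophoreTable.default()
    grid = simulation_grid()
    params = sample_params(n, ranges, seed)
    raw = optics.diffuse_reflectance_batch(params, grid, table)
    cam_spec = l1_normalize(optics.resample_batch(raw, grid, cam), axis=1)
    meta = {
        "seed": int(seed),
        "n": int(n),
        "ranges": {k: list(v) for k, v in (ranges or {}).items()},
        "sim_grid": [300.0, 1000.0, 2.0],
        "cam_grid": [500.0, 995.0, 5.0],
        "srf_kind": cam.srf_kind,
        "metric": "euclidean_l1normalized",
    }
    return SyntheticDatabase(params, cam_spec, raw if store_raw else None, meta)


def nearest_spectrum(
    query: np.ndarray, db: SyntheticDatabase, subset: np.ndarray | None = None
) -> tuple[int, float]:
    """Closest database record to one camera-space L1-normalized spectrum."""
    q = np.asarray(query, dtype=float)
    if q.shape != (100,):
        raise DataError(f"query must have 100 bands, got {q.shape}")
    ids, d = db.index.query(q[None, :], subset=subset)
    return int(ids[0]), float(d[0])


def generate_twin(cube: HSICube, db: SyntheticDatabase) -> TwinMap:
    """Pixel-wise nearest-neighbor retrieval over the full database."""
    cube = cube.normalized_copy()
    H, W = cube.shape
    ids, dists = db.index.query(cube.flat())
    return TwinMap(
        record_id=ids.reshape(H, W),
        sto2_map=db.sto2[ids].reshape(H, W),
        vhb_map=db.vhb[ids].reshape(H, W),
        distance_map=dists.reshape(H, W),
    )
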