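"""Out-of-distribution perfusion detection and hybrid image generation.

The test-time augmentation has three steps, operating entirely on the
digital-twin annotation of an image:

1. Reference statistics: pool the retrieved StO2/VHb values of the twin
   maps of *physiological* training images and reduce them to a median and
   a percentile band per parameter (default the interquartile range 25-75;
   a conservative 5-95 setting is also supported).
2. Detection: a pixel is out-of-distribution (OOD) if its retrieved StO2
   OR its retrieved VHb falls outside the band (boundary values are in).
3. Correction: each OOD pixel is replaced by the L1-normalized mean of its
   real spectrum and the nearest synthetic spectrum drawn from a
   median-constrained pool (database records whose StO2/VHb lie within box
   tolerances of the physiological medians). In-distribution pixels are
   passed through bit-exact.

Percentiles use linear interpolation between order statistics
(``numpy.percentile`` default), fixed so results are convention-stable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np

from .errors import DataError
from .spectral_db import HSICube, SyntheticDatabase, TwinMap
from .optics import l1_normalize

__all__ = [
    "PhysioStats",
    "OODMask",
    "fit_physio_stats",
    "detect_ood",
    "select_replacement_pool",
    "augment_image",
    "select_percentile_setting",
]

log = logging.getLogger(__name__)

DEFAULT_PERCENTILE_PAIRS = ((5.0, 95.0), (25.0, 75.0))
DEFAULT_TOL_STO2 = 0.05
DEFAULT_TOL_VHB = 0.02


@dataclass(frozen=True)
class PhysioStats:
    """Median and percentile band of StO2/VHb on physiological twin data."""

    median_sto2: float
    median_vhb: float
    lo_sto2: float
    hi_sto2: float
    lo_vhb: float
    hi_vhb: float
    percentile_pair: tuple[float, float]
    provenance: tuple[str, ...] = ()

    def __post_init__(self):
        if not (self.lo_sto2 <= self.median_sto2 <= self.hi_sto2):
            raise DataError("sto2 percentile bounds do not bracket the median")
        if not (self.lo_vhb <= self.median_vhb <= self.hi_vhb):
            raise DataError("vhb percentile bounds do not bracket the median")

    def to_json(self, path) -> None:
        d = asdict(self)
        d["percentile_pair"] = list(self.percentile_pair)
        d["provenance"] = list(self.provenance)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PhysioStats":
        with open(path) as fh:
            d = json.load(fh)
        d["percentile_pair"] = tuple(d["percentile_pair"])
        d["provenance"] = tuple(d.get("provenance", ()))
        return cls(**d)


@dataclass(frozen=True)
class OODMask:
    """Boolean raster, True where a pixel's perfusion is out-of-distribution."""

    flags: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "flags", np.asarray(self.flags, dtype=bool))

    @property
    def fraction(self) -> float:
        return float(self.flags.mean())


def fit_physio_stats(
    twins: Iterable[TwinMap],
    percentile_pair: tuple[float, float] = (25.0, 75.0),
    provenance: Sequence[str] = (),
) -> PhysioStats:
    """Pool StO2/VHb over all pixels of the given twin maps and take percentiles."""
    twins = list(twins)
    if not twins:
        raise DataError("cannot fit physiological statistics on an empty collection")
    plo, phi = percentile_pair
    if not (0 <= plo < phi <= 100):
        raise DataError(f"invalid percentile pair {percentile_pair!r}")
    sto2 = np.concatenate([t.sto2_map.ravel() for t in twins])
    vhb = np.concatenate([t.vhb_map.ravel() for t in twins])
    lo_s, med_s, hi_s = np.percentile(sto2, [plo, 50.0, phi])
    lo_v, med_v, hi_v = np.percentile(vhb, [plo, 50.0, phi])
    return PhysioStats(
        median_sto2=float(med_s),
        median_vhb=float(med_v),
        lo_sto2=float(lo_s),
        hi_sto2=float(hi_s),
        lo_vhb=float(lo_v),
        hi_vhb=float(hi_v),
        percentile_pair=(float(plo), float(phi)),
        provenance=tuple(provenance),
    )


def detect_ood(twin: TwinMap, stats: PhysioStats) -> OODMask:
    """Flag pixels whose StO2 or VHb leaves the physiological band (OR rule)."""
    out_s = (twin.sto2_map < stats.lo_sto2) | (twin.sto2_map > stats.hi_sto2)
    out_v = (twin.vhb_map < stats.lo_vhb) | (twin.vhb_map > stats.hi_vhb)
    return OODMask(out_s | out_v)


def select_replacement_pool(
    db: SyntheticDatabase,
    stats: PhysioStats,
    tol_sto2: float = DEFAULT_TOL_STO2,
    tol_vhb: float = DEFAULT_TOL_VHB,
) -> np.ndarray:
    """Record ids with StO2/VHb within box tolerances of the physiological medians.

    If the box is empty the tolerances are doubled until at least one record
    qualifies (each widening is logged); for N >= 1 this terminates.
    """
    if tol_sto2 <= 0 or tol_vhb <= 0:
        raise DataError("replacement-pool tolerances must be positive")
    ts, tv = float(tol_sto2), float(tol_vhb)
    while True:
        pool = np.where(
            (np.abs(db.sto2 - stats.median_sto2) <= ts)
            & (np.abs(db.vhb - stats.median_vhb) <= tv)
        )[0]
        if pool.size:
            return pool
        ts, tv = 2 * ts, 2 * tv
        log.warning(
            "replacement pool empty; widening tolerances to sto2=%.4f vhb=%.4f", ts, tv
        )


def augment_image(
    cube: HSICube,
    twin: TwinMap,
    ood: OODMask,
    db: SyntheticDatabase,
    stats: PhysioStats,
    pool: np.ndarray | None = None,
) -> HSICube:
    """Hybrid image: OOD pixels averaged with pool-constrained synthetic spectra.

    In-distribution pixels are copied bit-exact. Each OOD pixel is replaced
    by ``l1_normalize((s_real + s_synth) / 2)`` where ``s_synth`` is the
    nearest database spectrum within the median-constrained replacement
    pool.
    """
    cube = cube.normalized_copy()
    if ood.flags.shape != cube.shape:
        raise DataError("OOD mask shape does not match the cube")
    out = cube.values.copy()
    flags = ood.flags
    if flags.any():
        if pool is None:
            pool = select_replacement_pool(db, stats)
        real = out[flags]  # (n_ood, 100)
        ids, _ = db.index.query(real, subset=pool)
        hybrid = l1_normalize((real + db.spectra_cam[ids]) / 2.0, axis=1)
        out[flags] = hybrid
    return HSICube(
        out, cube.grid, cube.subject_id, cube.image_id + "+tta", normalized=True
    )


def select_percentile_setting(
    candidate_pairs: Sequence[tuple[float, float]],
    validation_scenes: Sequence,
    model,
    db: SyntheticDatabase,
    physio_twins: Sequence[TwinMap],
    tol_sto2: float = DEFAULT_TOL_STO2,
    tol_vhb: float = DEFAULT_TOL_VHB,
) -> tuple[float, float]:
    """Pick the percentile pair maximizing overall DSC on validation scenes.

    Runs the full augmentation + frozen-model + DSC pipeline for every
    candidate pair, scores with the hierarchical aggregation (mean over
    per-organ hierarchical scores), and returns the best pair; ties go to
    the first candidate in list order.
    """
    from . import evalkit, seg_model
    from .spectral_db import generate_twin

    if not candidate_pairs:
        raise DataError("no candidate percentile pairs")
    best_pair, best_score = None, -np.inf
    twins = {id(s): generate_twin(s.cube, db) for s in validation_scenes}
    for pair in candidate_pairs:
        stats = fit_physio_stats(physio_twins, percentile_pair=pair)
        pool = select_replacement_pool(db, stats, tol_sto2, tol_vhb)
        records = []
        for scene in validation_scenes:
            twin = twins[id(scene)]
            hybrid = augment_image(scene.cube, twin, detect_ood(twin, stats), db, stats, pool)
            pred = seg_model.predict(model, hybrid)
            for organ in np.unique(scene.mask[scene.mask > 0]):
                records.append(
                    evalkit.DSCRecord(
                        scene.subject_id,
                        scene.image_id,
                        int(organ),
                        evalkit.dsc(pred, scene.mask, int(organ)),
                    )
                )
        per_organ = evalkit.hierarchical_aggregate(records)
        score = float(np.mean(list(per_organ.values())))
        log.info("percentile pair %s -> overall DSC %.4f", pair, score)
        if score > best_score:
            best_pair, best_score = tuple(pair), score
    return best_pair
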