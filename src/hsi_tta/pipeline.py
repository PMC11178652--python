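"""End-to-end orchestration: database -> scenes -> twin -> OOD -> hybrid -> DSC.

The pipeline reproduces the full experimental protocol on synthetic scenes:

1. build (or load) the synthetic spectral database;
2. generate a subject-structured multi-state scene dataset and split it
   subject-disjointly into training and held-out subjects;
3. train the frozen toy segmentation model on the training subjects'
   physiological scenes;
4. fit physiological StO2/VHb statistics on the twin maps of those scenes;
5. for every held-out scene: retrieve the twin, detect OOD pixels,
   generate the hybrid image, and segment both original and hybrid;
6. score per-organ hierarchical DSC for baseline and augmented
   predictions, and quantify the embedded domain gap before/after.

Every stage logs shapes, OOD fractions and pool sizes; all randomness
derives from the seeds in the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError, StageError
from . import evalkit, scene_sim, seg_model, spectral_db, tta_core

__all__ = ["PipelineConfig", "run_pipeline", "PipelineResult"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a full run needs; round-trips losslessly through YAML."""

    db_n: int = 50_000
    db_seed: int = 11
    db_path: str | None = None  # load instead of build when set
    n_subjects: int = 12
    n_train_subjects: int = 7
    images_per_subject: int = 2
    states: tuple[str, ...] = (
        "physiological",
        "avascular",
        "arterial_ischemia",
        "venous_congestion",
    )
    scene_seed: int = 23
    scene_size: int = 32
    noise_sd: float = 0.02
    model_kind: str = "nearest_centroid"
    model_seed: int = 37
    percentile_pair: tuple[float, float] = (25.0, 75.0)
    tol_sto2: float = tta_core.DEFAULT_TOL_STO2
    tol_vhb: float = tta_core.DEFAULT_TOL_VHB
    augment: bool = True
    out_dir: str | None = None

    def __post_init__(self):
        if self.n_train_subjects >= self.n_subjects:
            raise ConfigError("need at least one held-out subject")
        for s in self.states:
            if s not in scene_sim.PERFUSION_STATES:
                raise ConfigError(f"unknown perfusion state {s!r}")
        if "physiological" not in self.states:
            raise ConfigError("pipeline requires physiological scenes for training")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["states"] = list(self.states)
        d["percentile_pair"] = list(self.percentile_pair)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        d["states"] = tuple(d.get("states", cls.states))
        d["percentile_pair"] = tuple(d.get("percentile_pair", cls.percentile_pair))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["states"] = list(self.states)
        d["percentile_pair"] = list(self.percentile_pair)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory results of a full run."""

    config: PipelineConfig
    dsc_baseline: dict  # state -> {organ -> hierarchical DSC}
    dsc_augmented: dict
    gap_report: evalkit.GapReport
    ood_fraction: dict  # state -> mean OOD pixel fraction
    stats: tta_core.PhysioStats
    model: seg_model.FrozenModel
    records: "object"  # pandas DataFrame of per-image records
    resub_ood_fraction: float = float("nan")
    paths: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    import pandas as pd

    # stage: database
    t0 = time.perf_counter()
    try:
        if config.db_path:
            db = spectral_db.SyntheticDatabase.load(config.db_path)
        else:
            db = spectral_db.build_database(
                n=config.db_n, seed=config.db_seed, store_raw=False
            )
    except Exception as e:
        raise StageError(f"stage 'database' failed: {e}") from e
    log.info("database: %d records (%.1fs)", len(db), time.perf_counter() - t0)

    # stage: scenes
    try:
        layout = scene_sim.default_layout(config.scene_size, config.scene_size)
        scenes = scene_sim.make_dataset(
            config.n_subjects,
            config.images_per_subject,
            states=config.states,
            seed=config.scene_seed,
            layout=layout,
            noise_sd=config.noise_sd,
        )
        train_scenes, test_scenes = scene_sim.split_subjects(
            scenes, config.n_train_subjects, seed=config.scene_seed
        )
    except Exception as e:
        raise StageError(f"stage 'scenes' failed: {e}") from e
    log.info("scenes: %d train / %d held-out", len(train_scenes), len(test_scenes))

    train_physio = [s for s in train_scenes if s.state.name == "physiological"]

    # stage: frozen model
    try:
        model = seg_model.train(train_physio, kind=config.model_kind, seed=config.model_seed)
    except Exception as e:
        raise StageError(f"stage 'train-model' failed: {e}") from e

    # stage: physiological statistics
    try:
        physio_twins = [spectral_db.generate_twin(s.cube, db) for s in train_physio]
        stats = tta_core.fit_physio_stats(
            physio_twins,
            percentile_pair=config.percentile_pair,
            provenance=[s.image_id for s in train_physio],
        )
        pool = tta_core.select_replacement_pool(db, stats, config.tol_sto2, config.tol_vhb)
        resub_ood = float(
            np.mean([tta_core.detect_ood(t, stats).fraction for t in physio_twins])
        )
    except Exception as e:
        raise StageError(f"stage 'fit-stats' failed: {e}") from e
    log.info(
        "stats: %s; replacement pool %d records; resubstitution OOD %.3f",
        stats, pool.size, resub_ood,
    )

    # stage: per-scene twin -> OOD -> hybrid -> predict -> score
    rows = []
    gap_entries = []
    ood_acc: dict[str, list[float]] = {}
    organ = layout.target_label
    for scene in test_scenes:
        sid = scene.image_id
        try:
            twin = spectral_db.generate_twin(scene.cube, db)
            ood = tta_core.detect_ood(twin, stats)
            cube_n = scene.cube.normalized_copy()
            if config.augment:
                hybrid = tta_core.augment_image(cube_n, twin, ood, db, stats, pool)
            else:
                hybrid = cube_n
            pred_base = seg_model.predict(model, cube_n)
            pred_tta = seg_model.predict(model, hybrid)
        except Exception as e:
            raise StageError(f"stage 'augment-predict' scene {sid!r} failed: {e}") from e
        ood_acc.setdefault(scene.state.name, []).append(ood.fraction)
        log.info(
            "scene %s: shape %s, OOD fraction %.3f", sid, scene.cube.shape, ood.fraction
        )
        for phase, pred in (("baseline", pred_base), ("augmented", pred_tta)):
            for org in np.unique(scene.mask[scene.mask > 0]):
                rows.append(
                    dict(
                        subject_id=scene.subject_id,
                        image_id=sid,
                        state=scene.state.name,
                        phase=phase,
                        organ_label=int(org),
                        dsc=evalkit.dsc(pred, scene.mask, int(org)),
                    )
                )
        gap_entries.append(
            (scene.state.name, "original",
             evalkit.median_masked_spectrum(cube_n, scene.mask, organ))
        )
        gap_entries.append(
            (scene.state.name, "augmented",
             evalkit.median_masked_spectrum(hybrid, scene.mask, organ))
        )

    df = pd.DataFrame(rows)

    def _agg(phase: str) -> dict:
        out = {}
        for state in config.states:
            sub = df[(df.phase == phase) & (df.state == state)]
            out[state] = evalkit.hierarchical_aggregate(sub)
        return out

    try:
        gap = evalkit.domain_gap(gap_entries)
    except Exception as e:
        raise StageError(f"stage 'domain-gap' failed: {e}") from e

    result = PipelineResult(
        config=config,
        dsc_baseline=_agg("baseline"),
        dsc_augmented=_agg("augmented"),
        gap_report=gap,
        ood_fraction={k: float(np.mean(v)) for k, v in ood_acc.items()},
        stats=stats,
        model=model,
        records=df,
        resub_ood_fraction=resub_ood,
    )

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stamp = {"config_hash": config.config_hash(),
                 "seeds": [config.db_seed, config.scene_seed, config.model_seed]}
        df.to_csv(out / "dsc_records.csv", index=False)
        report = {
            **stamp,
            "dsc_baseline": result.dsc_baseline,
            "dsc_augmented": result.dsc_augmented,
            "ood_fraction": result.ood_fraction,
            "resub_ood_fraction": resub_ood,
            "mean_gap": {f"{s}|{p}": v for (s, p), v in gap.mean_gap.items()},
            "explained_variance": gap.explained_variance.tolist(),
        }
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        stats.to_json(out / "stats.json")
        seg_model.save_model(model, out / "model.h5")
        result.paths = {
            "records": str(out / "dsc_records.csv"),
            "report": str(out / "report.json"),
            "stats": str(out / "stats.json"),
            "model": str(out / "model.h5"),
        }
    return result
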