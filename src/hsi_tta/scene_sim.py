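"""Synthetic labeled surgical scenes in four perfusion states.

Real intraoperative hyperspectral recordings of perfusion-altered organs are
not publicly available, so this module generates stand-in scenes end to end
from the forward model: simple geometric organ regions on a background, with
per-pixel tissue parameters drawn from class- and state-specific ranges,
forward-simulated, camera-resampled, noised and L1-normalized.

Design of the default scene:

* Three classes. A connective-tissue-like *background* (low blood volume,
  broad saturation), the *kidney analog* target organ, and a small *vein
  analog* region (blood-rich, partially desaturated). Class identity is
  carried primarily by scattering (``mus500``, ``b_mie``), which perfusion
  manipulation does not touch; perfusion state is carried by StO2/VHb.
  This mirrors surgical reality, where a congested kidney spectrally
  approaches venous blood and an ischemic one approaches poorly
  vascularized tissue.
* The four perfusion states follow the malperfusion taxonomy: arterial
  ischemia (inflow blocked: desaturated, reduced blood volume), venous
  congestion (outflow blocked: desaturated, blood pooling), avascular
  (both), physiological. States modify only the target organ's StO2/VHb
  sampling ranges.
* Within every class StO2 and VHb are coupled through a Gaussian copula
  (rho = 0.5): better-perfused tissue tends to be better oxygenated.
* Inter-subject variability: per subject (and state) the StO2/VHb sampling
  interval shrinks to 70 % of the state range and slides within it, so
  subjects are exchangeable but not identical and all true parameters stay
  inside the declared state ranges.
* Sensor noise: multiplicative Gaussian with relative standard deviation
  ``noise_sd`` (default 0.02), clipped at zero, then L1-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from .errors import DataError
from . import optics
from .optics import CameraModel, ChromophoreTable, PARAM_FIELDS, l1_normalize, simulation_grid
from .spectral_db import HSICube

__all__ = [
    "PerfusionState",
    "PERFUSION_STATES",
    "ClassSpec",
    "SceneLayout",
    "LabeledScene",
    "default_layout",
    "make_scene",
    "make_dataset",
    "split_subjects",
]

STO2_VHB_RHO = 0.5
SUBJECT_RANGE_SHRINK = 0.7


@dataclass(frozen=True)
class PerfusionState:
    """Named perfusion condition with StO2/VHb sampling ranges for the target organ."""

    name: str
    sto2_range: tuple[float, float]
    vhb_range: tuple[float, float]

    def __post_init__(self):
        for rng, (lo, hi) in (("sto2", self.sto2_range), ("vhb", self.vhb_range)):
            blo, bhi = optics.PARAM_RANGES[rng if rng == "sto2" else "vhb"]
            if not (blo <= lo <= hi <= bhi):
                raise DataError(f"state {self.name!r}: {rng} range outside bounds")


PERFUSION_STATES = {
    "physiological": PerfusionState("physiological", (0.55, 0.85), (0.03, 0.10)),
    "avascular": PerfusionState("avascular", (0.0, 0.15), (0.02, 0.08)),
    "arterial_ischemia": PerfusionState("arterial_ischemia", (0.0, 0.15), (0.01, 0.05)),
    "venous_congestion": PerfusionState("venous_congestion", (0.0, 0.20), (0.12, 0.30)),
}


@dataclass(frozen=True)
class ClassSpec:
    """A scene class: integer label, name, and per-parameter sampling ranges."""

    label: int
    name: str
    ranges: dict

    def bounds(self, key: str) -> tuple[float, float]:
        return self.ranges.get(key, optics.PARAM_RANGES[key])


_COMMON = {"g": (0.85, 0.92), "n_refr": (1.36, 1.40), "d_cm": (0.01, 0.1), "w_water": (0.8, 0.9)}

BACKGROUND = ClassSpec(0, "background", {
    "sto2": (0.40, 0.90), "vhb": (0.01, 0.05),
    "mus500": (15.0, 35.0), "b_mie": (0.3, 0.9), **_COMMON,
})
KIDNEY = ClassSpec(1, "kidney_analog", {
    "sto2": (0.55, 0.85), "vhb": (0.03, 0.10),
    "mus500": (10.0, 25.0), "b_mie": (1.8, 2.6), **_COMMON,
})
VEIN = ClassSpec(2, "vein_analog", {
    "sto2": (0.25, 0.50), "vhb": (0.10, 0.25),
    "mus500": (30.0, 50.0), "b_mie": (0.3, 0.6), **_COMMON,
})


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse in fractional image coordinates."""

    cy: float
    cx: float
    ry: float
    rx: float

    def mask(self, H: int, W: int) -> np.ndarray:
        yy, xx = np.mgrid[0:H, 0:W]
        return ((yy - self.cy * H) / (self.ry * H)) ** 2 + (
            (xx - self.cx * W) / (self.rx * W)
        ) ** 2 <= 1.0


@dataclass(frozen=True)
class SceneLayout:
    """Scene geometry: image shape, background class and organ regions."""

    height: int
    width: int
    background: ClassSpec
    regions: tuple[tuple[Ellipse, ClassSpec], ...]
    target_label: int = 1

    def __post_init__(self):
        if not self.regions:
            raise DataError("scene layout needs at least one organ region")
        if self.target_label not in {c.label for _, c in self.regions}:
            raise DataError("layout has no region with the target label")

    def label_mask(self) -> np.ndarray:
        mask = np.zeros((self.height, self.width), dtype=np.int64)
        for ell, cls in self.regions:
            mask[ell.mask(self.height, self.width)] = cls.label
        return mask

    def class_specs(self) -> dict[int, ClassSpec]:
        out = {self.background.label: self.background}
        out.update({c.label: c for _, c in self.regions})
        return out


def default_layout(height: int = 32, width: int = 32) -> SceneLayout:
    return SceneLayout(
        height=height,
        width=width,
        background=BACKGROUND,
        regions=(
            (Ellipse(0.42, 0.42, 0.28, 0.34), KIDNEY),
            (Ellipse(0.76, 0.78, 0.12, 0.15), VEIN),
        ),
    )


@dataclass
class LabeledScene:
    """A synthetic scene: cube, reference mask, per-pixel true parameters."""

    cube: HSICube
    mask: np.ndarray
    true_params: dict
    subject_id: str
    image_id: str
    state: PerfusionState

    def __post_init__(self):
        if self.mask.shape != self.cube.shape:
            raise DataError("mask shape does not match cube")


def _sample_class(
    n: int,
    cls: ClassSpec,
    rng: np.random.Generator,
    sto2_bounds: tuple[float, float],
    vhb_bounds: tuple[float, float],
) -> dict[str, np.ndarray]:
    """Per-pixel parameters for one class; StO2/VHb share a Gaussian copula."""
    z1 = rng.standard_normal(n)
    z2 = STO2_VHB_RHO * z1 + np.sqrt(1 - STO2_VHB_RHO**2) * rng.standard_normal(n)
    unit = {"sto2": norm.cdf(z1), "vhb": norm.cdf(z2)}
    out = {}
    for key in PARAM_FIELDS:
        lo, hi = cls.bounds(key)
        if key == "sto2":
            lo, hi = sto2_bounds
        elif key == "vhb":
            lo, hi = vhb_bounds
        u = unit.get(key)
        out[key] = lo + (hi - lo) * (u if u is not None else rng.uniform(0, 1, n))
    return out


def _subject_bounds(
    bounds: tuple[float, float], u: float, shrink: float = SUBJECT_RANGE_SHRINK
) -> tuple[float, float]:
    """Slide a shrunken interval inside ``bounds``; u in [0, 1] picks position."""
    lo, hi = bounds
    w = (hi - lo) * shrink
    start = lo + (hi - lo - w) * u
    return (start, start + w)


def make_scene(
    layout: SceneLayout,
    state: PerfusionState,
    cam: CameraModel | None = None,
    table: ChromophoreTable | None = None,
    noise_sd: float = 0.02,
    seed: int | np.random.Generator = 0,
    subject_id: str = "s0",
    image_id: str = "i0",
    subject_u: tuple[float, float] = (0.5, 0.5),
) -> LabeledScene:
    """Simulate one labeled scene in the given perfusion state.

    ``subject_u`` positions the subject-specific StO2/VHb sub-intervals of
    the target organ within the state ranges (0.5 = centered).
    """
    cam = cam or CameraModel()
    table = table or ChromophoreTable.default()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = simulation_grid()

    mask = layout.label_mask()
    flat = mask.ravel()
    npix = flat.size
    params = {k: np.zeros(npix) for k in PARAM_FIELDS}
    for label, cls in layout.class_specs().items():
        sel = flat == label
        if not sel.any():
            continue
        if label == layout.target_label:
            s_b = _subject_bounds(state.sto2_range, subject_u[0])
            v_b = _subject_bounds(state.vhb_range, subject_u[1])
        else:
            s_b, v_b = cls.bounds("sto2"), cls.bounds("vhb")
        drawn = _sample_class(int(sel.sum()), cls, rng, s_b, v_b)
        for k in PARAM_FIELDS:
            params[k][sel] = drawn[k]

    arr = np.column_stack([params[k] for k in PARAM_FIELDS])
    raw = optics.diffuse_reflectance_batch(arr, grid, table)
    spec = l1_normalize(optics.resample_batch(raw, grid, cam), axis=1)
    if noise_sd > 0:
        spec = spec * (1.0 + noise_sd * rng.standard_normal(spec.shape))
        spec = np.clip(spec, 1e-12, None)
    spec = l1_normalize(spec, axis=1)

    H, W = mask.shape
    cube = HSICube(
        spec.reshape(H, W, -1), cam.grid(), subject_id, image_id, normalized=True
    )
    true_params = {k: v.reshape(H, W) for k, v in params.items()}
    return LabeledScene(cube, mask, true_params, subject_id, image_id, state)


def make_dataset(
    n_subjects: int,
    images_per_subject: int,
    states=("physiological", "avascular", "arterial_ischemia", "venous_congestion"),
    seed: int = 0,
    layout: SceneLayout | None = None,
    noise_sd: float = 0.02,
    cam: CameraModel | None = None,
    table: ChromophoreTable | None = None,
) -> list[LabeledScene]:
    """Scenes for every (subject, state, image) combination.

    Each subject receives one set of per-state StO2/VHb sub-interval
    positions, drawn once, so images of the same subject share physiology.
    """
    if n_subjects < 1 or images_per_subject < 1:
        raise DataError("need at least one subject and one image per subject")
    layout = layout or default_layout()
    cam = cam or CameraModel()
    table = table or ChromophoreTable.default()
    states = [
        PERFUSION_STATES[s] if isinstance(s, str) else s for s in states
    ]
    master = np.random.default_rng(seed)
    scenes = []
    for si in range(n_subjects):
        subject_rng = np.random.default_rng(master.integers(2**31))
        subject_u = {
            st.name: (subject_rng.uniform(), subject_rng.uniform()) for st in states
        }
        for st in states:
            for ii in range(images_per_subject):
                scenes.append(
                    make_scene(
                        layout,
                        st,
                        cam=cam,
                        table=table,
                        noise_sd=noise_sd,
                        seed=np.random.default_rng(subject_rng.integers(2**31)),
                        subject_id=f"subject{si:02d}",
                        image_id=f"subject{si:02d}_{st.name}_{ii:02d}",
                        subject_u=subject_u[st.name],
                    )
                )
    return scenes


def split_subjects(
    scenes: list[LabeledScene], n_train_subjects: int, seed: int = 0
) -> tuple[list[LabeledScene], list[LabeledScene]]:
    """Subject-disjoint split; returns (train_scenes, heldout_scenes)."""
    subjects = sorted({s.subject_id for s in scenes})
    if not (0 < n_train_subjects < len(subjects)):
        raise DataError("split must leave at least one subject on each side")
    rng = np.random.default_rng(seed)
    train = set(rng.permutation(subjects)[:n_train_subjects])
    a = [s for s in scenes if s.subject_id in train]
    b = [s for s in scenes if s.subject_id not in train]
    return a, b
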