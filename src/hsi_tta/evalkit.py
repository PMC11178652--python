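"""Segmentation scoring and domain-gap quantification.

Scores follow the evaluation conventions of intraoperative segmentation
studies: per-image, per-organ Dice similarity coefficients (DSC) that are
hierarchically aggregated (mean over images within subject, then mean over
subjects), so subjects with many images do not dominate.

The domain gap between perfusion states is quantified on per-image median
organ spectra: a 2-component PCA is fitted on the union of all original and
augmented median spectra, every spectrum is embedded in that plane, a
Gaussian kernel density (Scott bandwidth) summarizes each state, and the
Euclidean distance between each state's embedded mean and the physiological
mean is reported before and after augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.decomposition import PCA

from .errors import DataError
from .spectral_db import HSICube

__all__ = [
    "DSCRecord",
    "GapReport",
    "dsc",
    "hierarchical_aggregate",
    "relative_decrease",
    "improvement_factor",
    "median_masked_spectrum",
    "domain_gap",
]


@dataclass(frozen=True)
class DSCRecord:
    subject_id: str
    image_id: str
    organ_label: int
    dsc: float

    def __post_init__(self):
        if not (0.0 <= self.dsc <= 1.0):
            raise DataError(f"DSC {self.dsc} outside [0, 1]")


def dsc(pred: np.ndarray, ref: np.ndarray, organ_label: int) -> float:
    """Dice coefficient 2|P∩R| / (|P|+|R|) for one label; both-empty -> 1."""
    pred, ref = np.asarray(pred), np.asarray(ref)
    if pred.shape != ref.shape:
        raise DataError(f"shape mismatch {pred.shape} vs {ref.shape}")
    P, R = pred == organ_label, ref == organ_label
    denom = P.sum() + R.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(P, R).sum() / denom)


def hierarchical_aggregate(records) -> dict[int, float]:
    """Per-organ score: mean over images within subject, then mean over subjects."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if not records:
            raise DataError("no DSC records to aggregate")
        df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        raise DataError("no DSC records to aggregate")
    per_subject = df.groupby(["organ_label", "subject_id"])["dsc"].mean()
    per_organ = per_subject.groupby("organ_label").mean()
    return {int(k): float(v) for k, v in per_organ.items()}


def relative_decrease(baseline: float, degraded: float) -> float:
    """Performance drop as a percentage of baseline: 100 (b - d) / b."""
    if baseline <= 0:
        raise DataError("relative decrease needs a positive baseline")
    return 100.0 * (baseline - degraded) / baseline


def improvement_factor(baseline: float, improved: float) -> float:
    """Multiplicative improvement over baseline: improved / baseline."""
    if baseline <= 0:
        raise DataError("improvement factor needs a positive baseline")
    return improved / baseline


def median_masked_spectrum(cube: HSICube, mask: np.ndarray, organ_label: int) -> np.ndarray:
    """Per-band median spectrum over the organ's pixels."""
    mask = np.asarray(mask)
    if mask.shape != cube.shape:
        raise DataError("mask shape does not match cube")
    sel = cube.values[mask == organ_label]
    if sel.shape[0] == 0:
        raise DataError(f"no pixels with label {organ_label}")
    return np.median(sel, axis=0)


@dataclass
class GapReport:
    """PCA embedding of median spectra with per-state densities and mean gaps."""

    embedding: pd.DataFrame  # columns: state, phase, pc1, pc2
    explained_variance: np.ndarray
    densities: dict  # (state, phase) -> gaussian_kde
    mean_gap: dict  # (state, phase) -> distance to physiological mean of that phase

    def __post_init__(self):
        ev = np.asarray(self.explained_variance, dtype=float)
        if np.any(np.diff(ev) > 1e-12) or np.any(ev < 0) or np.any(ev > 1):
            raise DataError("explained variance must be non-increasing fractions")
        self.explained_variance = ev


def plot_gap_report(report: GapReport, path) -> None:
    """Scatter of the 2-d embedding, one panel per phase, colored by state."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    phases = sorted(report.embedding["phase"].unique())
    fig, axes = plt.subplots(1, len(phases), figsize=(5 * len(phases), 4), squeeze=False)
    for ax, phase in zip(axes[0], phases):
        sub = report.embedding[report.embedding.phase == phase]
        for state, grp in sub.groupby("state"):
            ax.scatter(grp.pc1, grp.pc2, label=state, s=18, alpha=0.8)
        ax.set_title(phase)
        ax.set_xlabel(f"PC1 ({100 * report.explained_variance[0]:.0f}%)")
        ax.set_ylabel(f"PC2 ({100 * report.explained_variance[1]:.0f}%)")
    axes[0, -1].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_dsc_by_state(records, organ_label: int, path) -> None:
    """Box plots of per-subject hierarchical DSC, baseline vs augmented."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(
        [r.__dict__ for r in records])
    df = df[df.organ_label == organ_label]
    per_subject = (
        df.groupby(["state", "phase", "subject_id"])["dsc"].mean().reset_index()
    )
    states = sorted(df["state"].unique())
    fig, ax = plt.subplots(figsize=(1.8 * len(states) + 2, 4))
    width, ticks = 0.35, np.arange(len(states))
    for off, phase in ((-width / 2, "baseline"), (width / 2, "augmented")):
        data = [
            per_subject[(per_subject.state == s) & (per_subject.phase == phase)]
            ["dsc"].to_numpy()
            for s in states
        ]
        ax.boxplot(data, positions=ticks + off, widths=width * 0.9,
                   tick_labels=[""] * len(states))
    ax.set_xticks(ticks, states, rotation=20)
    ax.set_ylabel("hierarchical DSC")
    ax.set_ylim(-0.05, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def domain_gap(entries, reference_state: str = "physiological") -> GapReport:
    """Embed tagged median spectra and measure per-state distances to physiological.

    ``entries`` is an iterable of (state, phase, spectrum) with phase in
    {"original", "augmented"}. A joint PCA is fitted on all spectra of both
    phases; gaps are distances between embedded state means and the
    reference state's mean, per phase.
    """
    entries = [(s, p, np.asarray(v, dtype=float)) for s, p, v in entries]
    if not entries:
        raise DataError("no median spectra given")
    states = {s for s, _, _ in entries}
    if len(states) < 2:
        raise DataError("domain gap needs at least two perfusion states")
    if reference_state not in states:
        raise DataError(f"reference state {reference_state!r} missing from entries")
    X = np.stack([v for _, _, v in entries])
    pca = PCA(n_components=2, svd_solver="full").fit(X)
    Z = pca.transform(X)
    df = pd.DataFrame(
        {
            "state": [s for s, _, _ in entries],
            "phase": [p for _, p, _ in entries],
            "pc1": Z[:, 0],
            "pc2": Z[:, 1],
        }
    )
    densities, mean_gap = {}, {}
    for phase in sorted(df["phase"].unique()):
        ref_pts = df[(df.state == reference_state) & (df.phase == phase)][["pc1", "pc2"]]
        ref_mean = ref_pts.to_numpy().mean(axis=0)
        for state in sorted(states):
            pts = df[(df.state == state) & (df.phase == phase)][["pc1", "pc2"]].to_numpy()
            if pts.shape[0] < 2:
                raise DataError(f"need >= 2 images for state {state!r} phase {phase!r}")
            if pts.shape[0] >= 3:
                try:
                    densities[(state, phase)] = gaussian_kde(pts.T)
                except np.linalg.LinAlgError:
                    densities[(state, phase)] = gaussian_kde(
                        (pts + 1e-9 * np.random.default_rng(0).standard_normal(pts.shape)).T
                    )
            mean_gap[(state, phase)] = float(
                np.linalg.norm(pts.mean(axis=0) - ref_mean)
            )
    return GapReport(df, pca.explained_variance_ratio_, densities, mean_gap)
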