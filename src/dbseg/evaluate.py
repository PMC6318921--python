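"""Segmentation accuracy via MLPA-style aberration calling.

A per-locus binary classifier turns a segmentation into calls that can be
scored against ground truth independently of the segmenter's internals: a
probe ``p`` is called *normal* (positive) when the estimated mean of its
segment is within ``tau`` of the diploid value 2, aberrant (negative)
otherwise.  Sweeping the discrimination threshold ``tau`` traces an ROC
curve; its area (trapezoidal rule) summarizes how well the estimated
segment means separate normal from aberrant loci.  The gold standard is
drawn by uniform sampling near the true breakpoints — the regions where a
segmenter can actually fail — with labels taken from the *true* post-mixing
segment means.

Over-segmentation, invisible to the ROC (splitting a correct segment does
not change its mean), is tracked separately as the ratio of predicted to
true segment counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .prune import SegmentationResult

__all__ = [
    "GoldStandard",
    "RocCurve",
    "mlpa_tag",
    "build_gold_standard",
    "estimated_deviations",
    "roc_auc",
    "over_segmentation_ratio",
    "plot_roc",
]

_DIPLOID = 2.0


@dataclass
class GoldStandard:
    """Sampled test loci: profile index, probe location, and true label.

    ``labels`` is True for *normal* loci (true segment mean equal to 2
    within 1e-9) and False for aberrant ones.
    """

    profile_index: np.ndarray
    locations: np.ndarray
    labels: np.ndarray

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int((~self.labels).sum())


@dataclass
class RocCurve:
    """ROC sweep of the MLPA classifier threshold ``tau``."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def mlpa_tag(result: SegmentationResult, p: int, tau: float) -> bool:
    """True (normal) iff the mean of the segment containing ``p`` is within
    ``tau`` of 2; ties at exactly ``tau`` are called aberrant (strict <)."""
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    return bool(abs(result.mean_at(p) - _DIPLOID) < tau)


def build_gold_standard(
    profiles, flank: int = 200, per_side: int = 4, seed=0
) -> GoldStandard:
    """Sample labeled loci near every true breakpoint of every profile.

    For each breakpoint, ``per_side`` locations are drawn uniformly (with
    replacement) from up to ``flank`` probes on each side, clipped to the
    adjacent true segments so no sample crosses into a different segment.
    ``profiles`` only needs ``n``, ``true_breakpoints`` and ``true_means``
    attributes.  Deterministic by seed.
    """
    if flank < 1 or per_side < 1:
        raise ValueError("flank and per_side must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    pidx, locs, labels = [], [], []
    for i, prof in enumerate(profiles):
        edges = np.concatenate(([0], prof.true_breakpoints, [prof.n]))
        for j, b in enumerate(prof.true_breakpoints):
            left_lo = max(int(edges[j]), b - flank)
            right_hi = min(int(edges[j + 2]), b + flank)
            for lo, hi, mean in (
                (left_lo, b, prof.true_means[j]),
                (b, right_hi, prof.true_means[j + 1]),
            ):
                draws = rng.integers(lo, hi, size=per_side)
                pidx.extend([i] * per_side)
                locs.extend(int(v) for v in draws)
                labels.extend([abs(mean - _DIPLOID) < 1e-9] * per_side)
    return GoldStandard(
        profile_index=np.asarray(pidx, dtype=np.int64),
        locations=np.asarray(locs, dtype=np.int64),
        labels=np.asarray(labels, dtype=bool),
    )


def estimated_deviations(results: list[SegmentationResult], gold: GoldStandard) -> np.ndarray:
    """|estimated segment mean - 2| at every gold locus."""
    devs = np.empty(gold.locations.size, dtype=np.float64)
    for i, res in enumerate(results):
        mask = gold.profile_index == i
        if mask.any():
            devs[mask] = np.abs(
                np.asarray(res.mean_at(gold.locations[mask])) - _DIPLOID
            )
    return devs


def roc_auc(
    results: list[SegmentationResult],
    gold: GoldStandard,
    tau_grid: np.ndarray | None = None,
) -> RocCurve:
    """Sweep the classifier threshold and integrate the ROC curve.

    Default grid: 0 to ``max(2, max|mean - 2| + 0.01)`` in steps of 0.01.
    AUC is the trapezoidal area over (1 - specificity, sensitivity), with
    the degenerate endpoints (0, 0) and (1, 1) appended.
    """
    labels = gold.labels
    if labels.all() or not labels.any():
        raise ValueError("gold standard contains a single class; AUC undefined")
    devs = estimated_deviations(results, gold)
    if tau_grid is None:
        hi = max(_DIPLOID, float(devs.max()) + 0.01)
        tau_grid = np.arange(0.0, hi + 0.01, 0.01)
    tau_grid = np.asarray(tau_grid, dtype=np.float64)

    # predicted positive iff dev < tau  (strict)
    pred = devs[None, :] < tau_grid[:, None]
    P = labels.sum()
    N = labels.size - P
    tp = (pred & labels[None, :]).sum(axis=1)
    fp = (pred & ~labels[None, :]).sum(axis=1)
    sens = tp / P
    spec = (N - fp) / N

    fpr = np.concatenate(([0.0], 1.0 - spec, [1.0]))
    tpr = np.concatenate(([0.0], sens, [1.0]))
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=tau_grid, sensitivity=sens, specificity=spec, auc=auc)


def over_segmentation_ratio(results: list[SegmentationResult], profiles) -> float:
    """Total predicted segments / total true segments over the suite."""
    predicted = sum(r.n_segments for r in results)
    true = sum(int(np.asarray(p.true_breakpoints).size) + 1 for p in profiles)
    return predicted / true


def plot_roc(curve: RocCurve, path) -> None:
    """Write a simple ROC plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(1.0 - curve.specificity, curve.sensitivity, lw=1.5)
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"MLPA aberration calling, AUC = {curve.auc:.4f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
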