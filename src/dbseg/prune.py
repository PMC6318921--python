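"""Post-segmentation validation: prune false breakpoints, emit final segments.

The noise level sigma-hat that drives the recursion is deliberately an
underestimate, so the preliminary tree is expected to be mildly
over-segmented.  Once the tree exists, the *actual* dispersion of each leaf
segment is available, and the gap

    eta = min(Z over non-leaf nodes) - max(leaf segment sd)

diagnoses the result: if eta exceeds the safe gap lambda, every candidate
split is cleanly more significant than the noisiest leaf and all are kept.
Otherwise the threshold is re-derived as

    sigma' = max(leaf sd) + lambda

and only candidates with Z > sigma' survive.  Retention is a flat threshold
over all candidates regardless of tree depth — a child may legitimately be
more significant than its parent — and removing a breakpoint simply merges
the two adjacent sub-segments.  Final segment means are the arithmetic means
of the merged segments, which minimize the within-segment L2 error among
piecewise-constant fits with those breakpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .noise import NoiseEstimate
from .segment import SegTree
from .signals import CopyNumberSignal, Interval, build_prefix_sum, segment_mean_sd

__all__ = [
    "PruneReport",
    "SegmentationResult",
    "leaf_sds",
    "compute_eta",
    "prune",
    "prune_iterative",
    "finalize",
]


@dataclass
class PruneReport:
    """Audit record of one pruning pass.

    ``kept`` and ``removed`` are lists of ``(breakpoint, Z)`` pairs, sorted
    by breakpoint; together they cover every candidate of the tree.
    """

    eta: float
    sigma_prime: float
    kept: list[tuple[int, float]]
    removed: list[tuple[int, float]]

    def to_dict(self) -> dict:
        return {
            "eta": self.eta if math.isfinite(self.eta) else None,
            "sigma_prime": self.sigma_prime,
            "n_candidates": len(self.kept) + len(self.removed),
            "n_kept": len(self.kept),
            "kept": [[int(b), float(z)] for b, z in self.kept],
            "removed": [[int(b), float(z)] for b, z in self.removed],
        }


@dataclass
class SegmentationResult:
    """Final segmentation of one signal.

    ``breakpoints`` are strictly increasing probe indices in ``(0, n)``
    (0-based, first probe of the right-hand segment); segment ``i`` spans
    ``[edges[i], edges[i+1])`` with ``edges = [0, *breakpoints, n]``.
    """

    n: int
    breakpoints: np.ndarray
    means: np.ndarray
    significances: np.ndarray
    sigma_hat: float
    report: PruneReport | None = None
    tree: SegTree | None = field(default=None, repr=False)
    label: str | None = None

    @property
    def n_segments(self) -> int:
        return int(self.means.size)

    @property
    def edges(self) -> np.ndarray:
        return np.concatenate(([0], self.breakpoints, [self.n]))

    def segment_index(self, p) -> np.ndarray | int:
        """Index of the final segment containing probe ``p`` (vectorized)."""
        idx = np.searchsorted(self.breakpoints, p, side="right")
        return idx if np.ndim(p) else int(idx)

    def mean_at(self, p) -> np.ndarray | float:
        """Estimated mean of the segment containing probe ``p``."""
        m = self.means[np.searchsorted(self.breakpoints, p, side="right")]
        return m if np.ndim(p) else float(m)

    def fitted_values(self) -> np.ndarray:
        """Piecewise-constant fit, one value per probe."""
        return np.repeat(self.means, np.diff(self.edges))


def leaf_sds(tree: SegTree, signal: CopyNumberSignal) -> dict:
    """Sample sd of every leaf segment; also stored on ``node.leaf_sd``."""
    out = {}
    for node in tree.leaves():
        _, sd = segment_mean_sd(signal, node.iv)
        node.leaf_sd = sd
        out[node] = sd
    return out


def compute_eta(tree: SegTree, sds: dict) -> float:
    """Gap between the weakest accepted split and the noisiest leaf.

    Returns ``+inf`` for a single-leaf tree (nothing to prune).
    """
    zs = [node.z_sig for node in tree.internal()]
    if not zs:
        return math.inf
    return min(zs) - max(sds.values())


def prune(tree: SegTree, sds: dict, lam: float = 0.02) -> PruneReport:
    """Single-pass pruning of the candidate breakpoints.

    If ``eta > lam`` all candidates are kept and ``sigma' = max(leaf sd)``;
    otherwise ``sigma' = max(leaf sd) + lam`` and only candidates with
    ``Z > sigma'`` (strict) survive.
    """
    candidates = sorted((n.breakpoint, n.z_sig) for n in tree.internal())
    eta = compute_eta(tree, sds)
    max_sd = max(sds.values()) if sds else 0.0
    if eta > lam:
        return PruneReport(eta=eta, sigma_prime=max_sd, kept=candidates, removed=[])
    sigma_prime = max_sd + lam
    kept = [c for c in candidates if c[1] > sigma_prime]
    removed = [c for c in candidates if not c[1] > sigma_prime]
    return PruneReport(eta=eta, sigma_prime=sigma_prime, kept=kept, removed=removed)


def prune_iterative(
    tree: SegTree, signal: CopyNumberSignal, sds: dict, lam: float = 0.02
) -> PruneReport:
    """Repeat pruning until ``eta > lam``, re-deriving sigma' from the sds of
    the *merged* segments after each pass.  Optional; single-pass pruning is
    the default behavior.
    """
    report = prune(tree, sds, lam)
    removed = list(report.removed)
    kept = list(report.kept)
    while kept:
        edges = [0, *(b for b, _ in kept), signal.n]
        seg_sds = [
            segment_mean_sd(signal, Interval(a, b))[1]
            for a, b in zip(edges[:-1], edges[1:])
        ]
        eta = min(z for _, z in kept) - max(seg_sds)
        if eta > lam:
            break
        sigma_prime = max(seg_sds) + lam
        new_kept = [c for c in kept if c[1] > sigma_prime]
        removed.extend(c for c in kept if not c[1] > sigma_prime)
        if len(new_kept) == len(kept):
            break
        kept = new_kept
        report = PruneReport(
            eta=eta, sigma_prime=sigma_prime, kept=kept, removed=sorted(removed)
        )
    return report


def finalize(
    signal: CopyNumberSignal,
    kept: list[tuple[int, float]],
    sigma_hat: float = 0.0,
    report: PruneReport | None = None,
    tree: SegTree | None = None,
) -> SegmentationResult:
    """Assemble the final result from the retained breakpoints.

    Segments are the half-open intervals between consecutive breakpoints
    (with sentinels 0 and n); means come from the prefix sums.
    """
    kept = sorted(kept)
    bps = np.asarray([b for b, _ in kept], dtype=np.int64)
    if bps.size:
        if np.any(np.diff(bps) == 0):
            raise ValueError("duplicate breakpoints")
        if bps[0] <= 0 or bps[-1] >= signal.n:
            raise ValueError("breakpoints must lie strictly inside (0, n)")
    zs = np.asarray([z for _, z in kept], dtype=np.float64)
    S = build_prefix_sum(signal).S
    edges = np.concatenate(([0], bps, [signal.n]))
    means = np.diff(S[edges]) / np.diff(edges)
    return SegmentationResult(
        n=signal.n,
        breakpoints=bps,
        means=means,
        significances=zs,
        sigma_hat=float(sigma_hat),
        report=report,
        tree=tree,
        label=signal.label,
    )
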