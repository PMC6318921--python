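"""Synthetic copy-number profiles with normal-cell contamination.

Real tumor samples are mixtures: a fraction ``alpha`` of diploid normal
cells dilutes the tumor copy number ``p_i`` toward the diploid value 2,

    x_i = p_i * (1 - alpha) + 2 * alpha,

which shrinks every copy-number contrast by ``(1 - alpha)`` (and, because
mixing is affine, the probe noise by the same factor).  The generator
emulates the structure of array copy-number data: piecewise-constant
integer copy-number levels 1-4, Gaussian probe noise (template sd 0.4),
and per-sequence contamination between 30 and 70%.  Ground-truth
breakpoints and post-mixing segment means are recorded for evaluation.

Templates are Gaussian draws ``N(level, sigma^2)``; real copy-number
templates would add heavier tails and local trends, so detection results
on these profiles bound the clean-data behavior of the segmenter, not its
robustness to platform artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signals import CopyNumberSignal

__all__ = [
    "SegmentSpec",
    "SimulatedProfile",
    "sample_template",
    "simulate_profile",
    "make_test_suite",
    "fig2_scenario",
]

_LEVELS = (1, 2, 3, 4)

#: Fixed layout of the small demonstration scenario: seven segments, six
#: breakpoints, total length 10_000.  The levels alternate in direction so
#: that every scanned interval presents a sharp accumulated-error kink at
#: its dominant breakpoint; monotone staircase runs would degrade the
#: localization of any cumulative-sum scan.
_DEMO_LENGTHS = (1500, 1400, 1500, 1300, 1400, 1500, 1400)
_DEMO_LEVELS = (2, 3, 2, 3, 2, 3, 2)


@dataclass(frozen=True)
class SegmentSpec:
    """One ground-truth segment: ``length`` probes at integer ``copy_number``."""

    length: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"length must be >= 1, got {self.length}")
        if self.copy_number not in _LEVELS:
            raise ValueError(f"copy_number must be in {_LEVELS}, got {self.copy_number}")


@dataclass
class SimulatedProfile:
    """A generated profile with its ground truth.

    ``true_breakpoints`` / ``true_means`` describe the *post-mixing* signal;
    boundaries between segments whose post-mixing means coincide are
    dropped.  ``levels`` holds the tumor copy number of each merged segment.
    """

    signal: CopyNumberSignal
    true_breakpoints: np.ndarray
    true_means: np.ndarray
    levels: np.ndarray
    alpha: float
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.signal.n

    @property
    def n_true_segments(self) -> int:
        return int(self.true_means.size)

    @property
    def true_edges(self) -> np.ndarray:
        return np.concatenate(([0], self.true_breakpoints, [self.n]))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_template(copy_number: int, n: int, sigma: float = 0.4, rng=None) -> np.ndarray:
    """``n`` i.i.d. draws from ``N(copy_number, sigma^2)``.

    Stands in for a pure-tumor copy-number template at the given level.
    """
    if copy_number not in _LEVELS:
        raise ValueError(f"copy_number must be in {_LEVELS}, got {copy_number}")
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return _rng(rng).normal(float(copy_number), sigma, size=int(n))


def simulate_profile(
    specs: list[SegmentSpec],
    alpha: float = 0.0,
    sigma: float = 0.4,
    seed=None,
    label: str | None = None,
) -> SimulatedProfile:
    """Concatenate template draws per spec and apply contamination mixing.

    ``x = p * (1 - alpha) + 2 * alpha`` pointwise; true breakpoints are the
    spec boundaries, minus any boundary between segments whose post-mixing
    means are equal (i.e. equal copy number).
    """
    if not specs:
        raise ValueError("specs must be nonempty")
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    rng = _rng(seed)
    pure = np.concatenate(
        [sample_template(sp.copy_number, sp.length, sigma, rng) for sp in specs]
    )
    mixed = pure * (1.0 - alpha) + 2.0 * alpha

    bps, means, levels = [], [], []
    pos = 0
    for sp in specs:
        mean = sp.copy_number * (1.0 - alpha) + 2.0 * alpha
        if means and mean == means[-1]:
            pos += sp.length  # same post-mixing mean: no effective breakpoint
            continue
        if means:
            bps.append(pos)
        means.append(mean)
        levels.append(sp.copy_number)
        pos += sp.length
    return SimulatedProfile(
        signal=CopyNumberSignal(mixed, label=label),
        true_breakpoints=np.asarray(bps, dtype=np.int64),
        true_means=np.asarray(means, dtype=np.float64),
        levels=np.asarray(levels, dtype=np.int64),
        alpha=float(alpha),
        seed=seed if isinstance(seed, int) else None,
    )


def make_test_suite(
    n_sequences: int = 104,
    length_range: tuple[int, int] = (1_000, 100_000),
    seed=0,
    sigma: float = 0.4,
    alpha_choices=(0.3, 0.4, 0.5, 0.6, 0.7),
    seg_count_range: tuple[int, int] = (4, 12),
    min_seg_len: int = 30,
) -> list[SimulatedProfile]:
    """Generate the default synthetic test suite, deterministic by seed.

    Sequence lengths are log-uniform over ``length_range``; each sequence
    has a uniform number of segments in ``seg_count_range`` (inclusive)
    with Dirichlet-partitioned lengths floored at ``min_seg_len``, adjacent
    copy-number levels always distinct, and a contamination fraction drawn
    from ``alpha_choices``.  With the defaults (104 sequences, mean 8.5
    segments each) the suite totals roughly 880 true segments.
    """
    rng = _rng(seed)
    lo, hi = length_range
    profiles = []
    for idx in range(n_sequences):
        n = int(round(10 ** rng.uniform(np.log10(lo), np.log10(hi))))
        n_seg = int(rng.integers(seg_count_range[0], seg_count_range[1] + 1))
        n_seg = min(n_seg, max(1, n // (2 * min_seg_len)))
        extra = n - n_seg * min_seg_len
        lengths = min_seg_len + np.floor(rng.dirichlet(np.ones(n_seg)) * extra).astype(int)
        lengths[int(np.argmax(lengths))] += n - int(lengths.sum())
        levels = [int(rng.choice(_LEVELS))]
        for _ in range(n_seg - 1):
            levels.append(int(rng.choice([l for l in _LEVELS if l != levels[-1]])))
        alpha = float(rng.choice(alpha_choices))
        specs = [SegmentSpec(int(L), lv) for L, lv in zip(lengths, levels)]
        profiles.append(
            simulate_profile(specs, alpha=alpha, sigma=sigma, seed=rng, label=f"seq{idx:03d}")
        )
    return profiles


def fig2_scenario(seed=0, sigma: float = 0.4) -> SimulatedProfile:
    """Small fixed demonstration profile: 10^4 probes, seven segments.

    Piecewise-constant Gaussian signal with noise sd ``sigma`` (default
    0.4), six true breakpoints, no contamination, and every step at least
    1.5 noise sds.  The layout is a documented fixture; only the noise
    varies with the seed.
    """
    specs = [SegmentSpec(L, lv) for L, lv in zip(_DEMO_LENGTHS, _DEMO_LEVELS)]
    return simulate_profile(specs, alpha=0.0, sigma=sigma, seed=seed, label="demo")
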