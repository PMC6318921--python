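"""Core signal containers and O(1) range statistics.

The segmentation engine works on a one-dimensional per-probe copy-number
signal for a single chromosome (arm).  All range bookkeeping is 0-based and
half-open: an :class:`Interval` ``[start, end)`` covers probes ``start`` to
``end - 1``, and a breakpoint ``b`` is the index of the first probe of the
right-hand segment.  Range sums are served in O(1) from a cumulative
("summed-area") array with a leading zero, so any segment sum is a single
subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Interval",
    "CopyNumberSignal",
    "PrefixSumArray",
    "build_prefix_sum",
    "range_sum",
    "segment_mean_sd",
]


@dataclass(frozen=True)
class Interval:
    """Half-open probe index range ``[start, end)``.

    Attributes
    ----------
    start : int
        First probe index (inclusive), >= 0.
    end : int
        One past the last probe index (exclusive), > ``start``.
    """

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


class CopyNumberSignal:
    """Ordered per-probe copy-number measurements for one chromosome (arm).

    Parameters
    ----------
    values : array-like of float
        One measurement per probe; must be nonempty and finite.
    label : str, optional
        Chromosome / arm identifier carried through for reporting.
    """

    __slots__ = ("values", "n", "label")

    def __init__(self, values, label: str | None = None):
        arr = np.asarray(values, dtype=np.float64).reshape(-1)
        if arr.size == 0:
            raise ValueError("signal is empty")
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            raise ValueError(f"non-finite value at probe index {int(bad[0])}")
        self.values = np.ascontiguousarray(arr)
        self.n = int(arr.size)
        self.label = label

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lab = f", label={self.label!r}" if self.label else ""
        return f"CopyNumberSignal(n={self.n}{lab})"


class PrefixSumArray:
    """Cumulative sums ``S_0 .. S_n`` with ``S_0 = 0``, ``S_i = S_{i-1} + x_i``.

    The sum of any half-open range ``[i, j)`` is ``S_j - S_i``: two array
    references, independent of the range length.  Sums accumulate in double
    precision, which keeps relative error negligible for the signal lengths
    this package targets (up to ~1e6 probes).
    """

    __slots__ = ("S", "n")

    def __init__(self, S: np.ndarray):
        S = np.asarray(S, dtype=np.float64)
        if S.ndim != 1 or S.size < 2 or S[0] != 0.0:
            raise ValueError("prefix-sum array must be 1-D with S[0] == 0")
        self.S = S
        self.n = int(S.size - 1)

    @classmethod
    def from_signal(cls, signal: CopyNumberSignal) -> "PrefixSumArray":
        S = np.empty(signal.n + 1, dtype=np.float64)
        S[0] = 0.0
        np.cumsum(signal.values, out=S[1:])
        return cls(S)


def build_prefix_sum(signal: CopyNumberSignal) -> PrefixSumArray:
    """Build the integral (summed-area) array of a signal in a single pass."""
    return PrefixSumArray.from_signal(signal)


def _check_bounds(n: int, iv: Interval) -> None:
    if iv.end > n:
        raise IndexError(f"interval [{iv.start}, {iv.end}) out of bounds for n={n}")


def range_sum(S: PrefixSumArray, iv: Interval) -> float:
    """Sum of the signal over ``iv`` in O(1): ``S_end - S_start``."""
    _check_bounds(S.n, iv)
    return float(S.S[iv.end] - S.S[iv.start])


def segment_mean_sd(signal: CopyNumberSignal, iv: Interval) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation of a segment.

    The sd uses the ``len - 1`` denominator; a length-1 segment has sd 0 by
    convention (it can never justify a split).
    """
    _check_bounds(signal.n, iv)
    seg = signal.values[iv.start : iv.end]
    mean = float(seg.mean())
    sd = float(seg.std(ddof=1)) if seg.size > 1 else 0.0
    return mean, sd
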