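"""Per-probe noise level from trimmed first-order differences.

The recursion needs an estimate of the average noise standard deviation
sigma-hat on a chromosome before any segmentation exists.  First-order
differences ``d_i = x_{i+1} - x_i`` act as a high-pass filter: within a
constant segment they are pure noise with variance ``2 * sigma^2``, while a
difference straddling a breakpoint is inflated by the copy-number jump.
Trimming the most extreme ``gamma`` fraction of differences (``gamma / 2``
from each tail, default 2%) removes the breakpoint-contaminated values, and

    sigma-hat = sd(retained differences) / sqrt(2)

Trimming a Gaussian at its 1st/99th percentiles shrinks the sd by a factor
of about 0.935, so sigma-hat deliberately *under*-estimates the true noise
level; the final decision threshold is re-derived from actual leaf-segment
standard deviations during pruning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import CopyNumberSignal

__all__ = ["NoiseEstimate", "estimate_sigma"]


@dataclass(frozen=True)
class NoiseEstimate:
    """Result of the trimmed first-order-difference estimator.

    ``sigma_hat`` is ``sigma_tilde / sqrt(2)`` exactly, where ``sigma_tilde``
    is the sample sd of the retained differences; ``gamma`` is the total trim
    fraction (``gamma / 2`` per tail).
    """

    sigma_hat: float
    sigma_tilde: float
    gamma: float


def estimate_sigma(signal: CopyNumberSignal, gamma: float = 0.02) -> NoiseEstimate:
    """Estimate the average per-probe noise sd of a signal.

    Differences outside the ``gamma/2`` and ``100 - gamma/2`` empirical
    percentiles (linear interpolation) are discarded; ties at the cut are
    retained, which keeps the rule deterministic.  The retained sample is
    centered by its own mean via the ``ddof=1`` sample sd.
    """
    if not 0.0 <= gamma < 0.5:
        raise ValueError(f"gamma must be in [0, 0.5), got {gamma}")
    if signal.n < 3:
        raise ValueError("need at least 3 probes (2 differences) to estimate sigma")
    d = np.diff(signal.values)
    if gamma > 0.0:
        lo, hi = np.percentile(d, [50.0 * gamma, 100.0 - 50.0 * gamma])
        d = d[(d >= lo) & (d <= hi)]
    if d.size < 2:
        raise ValueError(
            "fewer than 2 differences retained after trimming; use a smaller gamma"
        )
    sigma_tilde = float(d.std(ddof=1))
    return NoiseEstimate(
        sigma_hat=sigma_tilde / float(np.sqrt(2.0)),
        sigma_tilde=sigma_tilde,
        gamma=float(gamma),
    )
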