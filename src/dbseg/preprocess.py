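"""Outlier mitigation before segmentation.

Single-probe outliers (very short deviant DNA stretches or technical
artifacts) can mislead a segmenter that looks for broad shifts.  Two
standard remedies are provided:

* Winsorization — clip every observation to ``mean +/- tau * sd``, where the
  mean and sd are taken over *all* observations of the input vector.  This is
  the default preprocessing step (``tau = 2.5``).
* A centered running median with edge replication, off by default; plain
  Winsorization is usually sufficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .signals import CopyNumberSignal

__all__ = ["WinsorizeParams", "winsorize", "median_filter"]


@dataclass(frozen=True)
class WinsorizeParams:
    """Winsorization band half-width, as a multiple ``tau`` of the global sd.

    ``tau`` must lie in [1.0, 5.0]; values outside the recommended [1.5, 3]
    range are accepted with a warning.  Default 2.5.
    """

    tau: float = 2.5

    def __post_init__(self) -> None:
        if not 1.0 <= self.tau <= 5.0:
            raise ValueError(f"tau={self.tau} outside the allowed range [1.0, 5.0]")
        if not 1.5 <= self.tau <= 3.0:
            warnings.warn(
                f"tau={self.tau} is outside the recommended range [1.5, 3.0]",
                stacklevel=3,
            )


def winsorize(
    signal: CopyNumberSignal, params: WinsorizeParams | float = 2.5
) -> CopyNumberSignal:
    """Clip extreme observations to ``mean +/- tau * sd`` of the whole vector.

    A constant signal (sd 0) is returned unchanged.  Values strictly inside
    the band are untouched, so the output has the same length and the same
    rank order inside the band.
    """
    if not isinstance(params, WinsorizeParams):
        params = WinsorizeParams(float(params))
    x = signal.values
    mu = float(x.mean())
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    if sd == 0.0:
        return CopyNumberSignal(x, label=signal.label)
    lo, hi = mu - params.tau * sd, mu + params.tau * sd
    return CopyNumberSignal(np.clip(x, lo, hi), label=signal.label)


def median_filter(signal: CopyNumberSignal, window: int = 5) -> CopyNumberSignal:
    """Centered running median with edge replication; ``window`` odd, >= 3."""
    window = int(window)
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    smoothed = ndimage.median_filter(signal.values, size=window, mode="nearest")
    return CopyNumberSignal(smoothed, label=signal.label)
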