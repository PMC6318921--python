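"""Scikit-learn style front end to the DBS pipeline.

:class:`DBSSegmenter` chains preprocessing (optional median filter, then
Winsorization), noise estimation, the recursive deviation scan, and pruning
into a single ``fit``.  It follows the clustering-estimator convention:
``fit_predict(X)`` returns a per-probe segment label, and the fitted
attributes expose breakpoints, segment means, significances, and the
thresholds that produced them.  :func:`segment_signal` is the equivalent
plain-function entry point.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import preprocess as _pre
from .noise import estimate_sigma
from .prune import SegmentationResult, finalize, leaf_sds, prune, prune_iterative
from .segment import DBSParams, segment_recursive
from .signals import CopyNumberSignal, build_prefix_sum

__all__ = ["DBSSegmenter", "segment_signal"]


def segment_signal(
    values,
    *,
    theta: float = 0.05,
    gamma: float = 0.02,
    lam: float = 0.02,
    min_seg_len: int = 20,
    window_ratio: int = 2,
    k_loc: float | None = 4.0,
    winsorize: bool = True,
    winsor_tau: float = 2.5,
    median_window: int | None = None,
    iterate_prune: bool = False,
    label: str | None = None,
) -> SegmentationResult:
    """Run the full DBS pipeline on one signal and return the segmentation.

    Parameters mirror :class:`DBSSegmenter`; see its docstring.  Segment
    means are computed on the preprocessed (Winsorized) signal.
    """
    sig = (
        values
        if isinstance(values, CopyNumberSignal)
        else CopyNumberSignal(values, label=label)
    )
    if median_window:
        sig = _pre.median_filter(sig, median_window)
    if winsorize:
        sig = _pre.winsorize(sig, winsor_tau)
    params = DBSParams(
        theta=theta,
        gamma=gamma,
        lam=lam,
        n0=min_seg_len,
        window_ratio=window_ratio,
        k_loc=k_loc,
    )
    sigma_hat = estimate_sigma(sig, gamma).sigma_hat if sig.n >= 3 else 0.0
    S = build_prefix_sum(sig)
    tree = segment_recursive(sig, S, sigma_hat, params)
    sds = leaf_sds(tree, sig)
    if iterate_prune:
        report = prune_iterative(tree, sig, sds, lam)
    else:
        report = prune(tree, sds, lam)
    return finalize(sig, report.kept, sigma_hat=sigma_hat, report=report, tree=tree)


class DBSSegmenter(BaseEstimator):
    """Deviation binary segmentation of a 1-D copy-number signal.

    Parameters
    ----------
    theta : float, default 0.05
        Significance level of the length-dependent CLT cut-off.
    gamma : float, default 0.02
        Trim fraction of the first-order-difference noise estimator.
    lam : float, default 0.02
        Safe gap added to the pruning threshold (signal units).
    min_seg_len : int, default 20
        Minimum number of probes per segment (the CLT needs this floor).
    window_ratio : int, default 2
        Common ratio of the geometric sliding-window sequence.
    k_loc : float or None, default 4.0
        Sharpness of the weaker-side localization combination (must be
        > 2); None uses the exact minimum.
    winsorize : bool, default True
        Clip outliers to ``mean +/- winsor_tau * sd`` before segmenting.
    winsor_tau : float, default 2.5
        Winsorization band half-width in global-sd units.
    median_window : int or None, default None
        Odd window of an optional centered median filter; None disables it.
    iterate_prune : bool, default False
        Repeat pruning until the eta gap clears the safe gap.

    Attributes
    ----------
    breakpoints_ : ndarray of int
        Retained breakpoints (0-based index of the first probe of the
        right-hand segment), strictly increasing.
    means_ : ndarray of float
        Mean of each final segment.
    significances_ : ndarray of float
        Chebyshev significance Z of each retained breakpoint.
    sigma_hat_, eta_, sigma_prime_ : float
        Noise estimate, pruning gap, and final significance threshold.
    labels_ : ndarray of int
        Segment index per probe of the fitted signal.
    n_segments_ : int
    result_ : SegmentationResult
        Full result object (includes the significance tree and audit report).

    Examples
    --------
    >>> import numpy as np
    >>> x = np.r_[np.zeros(100), np.ones(100)]
    >>> seg = DBSSegmenter().fit(x)
    >>> seg.breakpoints_
    array([100])
    """

    def __init__(
        self,
        theta: float = 0.05,
        gamma: float = 0.02,
        lam: float = 0.02,
        min_seg_len: int = 20,
        window_ratio: int = 2,
        k_loc: float | None = 4.0,
        winsorize: bool = True,
        winsor_tau: float = 2.5,
        median_window: int | None = None,
        iterate_prune: bool = False,
    ):
        self.theta = theta
        self.gamma = gamma
        self.lam = lam
        self.min_seg_len = min_seg_len
        self.window_ratio = window_ratio
        self.k_loc = k_loc
        self.winsorize = winsorize
        self.winsor_tau = winsor_tau
        self.median_window = median_window
        self.iterate_prune = iterate_prune

    @staticmethod
    def _as_1d(X) -> np.ndarray:
        arr = np.asarray(X, dtype=np.float64)
        if arr.ndim == 2 and arr.shape[1] == 1:
            arr = arr[:, 0]
        if arr.ndim != 1:
            raise ValueError(
                f"expected a 1-D signal or a single-column 2-D array, got shape {arr.shape}"
            )
        return arr

    def fit(self, X, y=None):
        """Segment the signal ``X`` (shape ``(n,)`` or ``(n, 1)``)."""
        x = self._as_1d(X)
        result = segment_signal(
            x,
            theta=self.theta,
            gamma=self.gamma,
            lam=self.lam,
            min_seg_len=self.min_seg_len,
            window_ratio=self.window_ratio,
            k_loc=self.k_loc,
            winsorize=self.winsorize,
            winsor_tau=self.winsor_tau,
            median_window=self.median_window,
            iterate_prune=self.iterate_prune,
        )
        self.result_ = result
        self.breakpoints_ = result.breakpoints
        self.means_ = result.means
        self.significances_ = result.significances
        self.sigma_hat_ = result.sigma_hat
        self.eta_ = result.report.eta
        self.sigma_prime_ = result.report.sigma_prime
        self.n_segments_ = result.n_segments
        self.labels_ = np.searchsorted(
            result.breakpoints, np.arange(result.n), side="right"
        )
        self.mean_signal_ = result.fitted_values()
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Fit and return the per-probe segment label."""
        return self.fit(X).labels_
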