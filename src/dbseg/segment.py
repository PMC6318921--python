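"""Deviation binary segmentation: CLT thresholds, deviation scans, and the
significance tree.

The recursion looks for one breakpoint at a time inside an interval.  The
deviation of a candidate part ``[i, j)`` from the scanned interval's mean
``mu`` is the accumulated error ``eps = sum(x_k - mu)``, normalized by a
length-dependent CLT cut-off:

    Z_{i,j} = eps_{i,j} / (T(theta, j - i) * sqrt(j - i)) = omega_{i,j} * eps_{i,j}

where ``T(theta, L)`` is the two-sided standard-normal quantile at level
``theta / L`` — the longer the part, the larger the deviation has to be in
raw units before it counts.  Splitting a candidate position ``p`` yields a
left and a right deviation; the weaker side's deviation
``min(|Z_left|, |Z_right|)`` localizes the breakpoint — a split is only
as credible as its weaker side, so balanced splits are preferred and
near-edge noise maxima are suppressed — while the Chebyshev combination
``max(|Z_left|, |Z_right|)`` scores its significance.  A split is accepted
when that score exceeds the noise level ``sigma_hat``.

Two scans implement this:

* :func:`scan_fixed` — endpoints fixed at the interval boundary; one pass,
  finds large jumps cheaply.
* :func:`scan_multiscale` — symmetric sliding windows of geometrically
  decreasing width; triggered only when the fixed scan finds nothing, it
  recovers short segments sandwiched inside long ones, which the fixed scan
  provably averages away.

Recursing until no interval yields a significant candidate produces a binary
tree whose non-leaf nodes carry the candidate breakpoints and their
significances; pruning (see :mod:`dbseg.prune`) then removes the
over-segmented tail of that tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri

from .signals import CopyNumberSignal, Interval, PrefixSumArray

__all__ = [
    "DBSParams",
    "SegNode",
    "SegTree",
    "ScanResult",
    "threshold_T",
    "weighted_Z",
    "localization_factor",
    "window_set",
    "scan_fixed",
    "scan_multiscale",
    "segment_recursive",
]


@dataclass(frozen=True)
class DBSParams:
    """Tunable parameters of the recursion.

    theta : significance level of the CLT cut-off (default 0.05).
    gamma : trim fraction of the noise estimator (default 0.02).
    lam : safe gap added to the pruning threshold (default 0.02).
    n0 : minimum probes per segment (default 20); both children of any
        split must have at least ``n0`` probes.
    window_ratio : common ratio of the geometric window-width sequence
        (default 2; larger ratios scan fewer scales).
    k_loc : sharpness of the weaker-side localization combination
        ``(w_l^-k + w_r^-k)^(-1/k)``; must exceed 2 (below that the
        combination loses its balanced-split maximum), None selects the
        exact minimum.  Default 4.
    """

    theta: float = 0.05
    gamma: float = 0.02
    lam: float = 0.02
    n0: int = 20
    window_ratio: int = 2
    k_loc: float | None = 4.0

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ValueError(f"theta must be in (0, 1), got {self.theta}")
        if not 0.0 <= self.gamma < 0.5:
            raise ValueError(f"gamma must be in [0, 0.5), got {self.gamma}")
        if self.lam < 0.0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if self.n0 < 2:
            raise ValueError(f"n0 must be >= 2, got {self.n0}")
        if self.window_ratio < 2:
            raise ValueError(f"window_ratio must be >= 2, got {self.window_ratio}")
        if self.k_loc is not None and not self.k_loc > 2.0:
            raise ValueError(f"k_loc must be > 2 or None, got {self.k_loc}")


@dataclass
class ScanResult:
    """Best candidate split of one scan.

    ``b`` is the breakpoint (first probe of the right-hand part), ``z_sig``
    the Chebyshev significance at ``b``, ``z_loc`` the localization score
    that was maximized, and ``window`` the window half-width for the
    multi-scale scan (None for the fixed-endpoint scan).
    """

    b: int
    z_sig: float
    z_loc: float
    window: int | None = None


@dataclass(eq=False)
class SegNode:
    """Node of the significance tree: one scanned interval.

    Non-leaf nodes record the accepted candidate breakpoint and its
    significance; ``leaf_sd`` is filled for leaves during pruning.
    """

    iv: Interval
    breakpoint: int | None = None
    z_sig: float | None = None
    left: "SegNode | None" = None
    right: "SegNode | None" = None
    leaf_sd: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.breakpoint is None


@dataclass
class SegTree:
    """Binary tree of scanned intervals produced by the recursion."""

    root: SegNode

    def nodes(self):
        """Pre-order iteration (deterministic)."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if not node.is_leaf:
                stack.append(node.right)
                stack.append(node.left)

    def leaves(self):
        return (n for n in self.nodes() if n.is_leaf)

    def internal(self):
        return (n for n in self.nodes() if not n.is_leaf)


def threshold_T(theta: float, L: int) -> float:
    """Length-dependent CLT cut-off ``T = Phi^-1(1 - theta / (2L))``.

    Strictly increasing in ``L`` and decreasing in ``theta``; returns 0 in
    the degenerate case ``theta / L >= 1``.
    """
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    if not 0.0 < theta < 1.0:
        raise ValueError(f"theta must be in (0, 1), got {theta}")
    q = theta / (2.0 * L)
    if q >= 0.5:
        return 0.0
    return float(ndtri(1.0 - q))


def _threshold_vec(theta: float, L: np.ndarray) -> np.ndarray:
    q = theta / (2.0 * np.asarray(L, dtype=np.float64))
    return ndtri(1.0 - np.minimum(q, 0.5))


def weighted_Z(S: PrefixSumArray, i: int, j: int, mu: float, theta: float) -> float:
    """Weighted deviation ``Z_{i,j}`` of part ``[i, j)`` from mean ``mu``.

    ``mu`` is the mean of the *parent* interval being scanned, not of
    ``[i, j)`` itself (the latter would make the statistic identically
    zero).  O(1) given the prefix sums.
    """
    if not 0 <= i < j <= S.n:
        raise IndexError(f"invalid part [{i}, {j}) for n={S.n}")
    L = j - i
    eps = S.S[j] - S.S[i] - L * mu
    return float(eps / (threshold_T(theta, L) * np.sqrt(L)))


def localization_factor(
    omega_left: float, omega_right: float, k: float | None = 4.0
) -> float:
    """Weaker-side combination ``(w_l^-k + w_r^-k)^(-1/k)`` of the two weights.

    A smooth minimum: it tends to the *smaller* weight (the side with more
    probes), so near the interval ends — where the short side is noise
    dominated — it vanishes, and along a scan it peaks where the two
    weights cross, i.e. at the balanced split.  Multiplied by the shared
    accumulated error ``|eps|`` it is the localization score of the scans:
    a split is only as credible as its weaker side.  This is the dual of
    the Chebyshev (maximum) combination used for significance.

    ``k`` must exceed 2: along the scan trajectory the weight crossing is
    a local maximum of the combination only when the exponent is steep
    enough (the curvature there is ``(1/2 - k/4) / L^2`` in log scale, so
    shallower exponents turn the balanced point into a *minimum* and push
    the argmax toward the interval ends).  ``k = None`` selects the exact
    minimum, which restores the hard balanced maximum but drags the argmax
    toward the interval center near off-center breakpoints; the default
    ``k = 4`` keeps both properties to good approximation.
    """
    if omega_left <= 0 or omega_right <= 0:
        raise ValueError("weights must be positive")
    if k is None:
        return float(min(omega_left, omega_right))
    if not k > 2.0:
        raise ValueError(f"k must be > 2 or None, got {k}")
    return float((omega_left**-k + omega_right**-k) ** (-1.0 / k))


def window_set(n: int, params: DBSParams) -> list[int]:
    """Geometric sliding-window widths, largest first.

    Starts at ``n // 2`` and divides by ``window_ratio`` (integer floor)
    until the width falls below ``max(2, n0)``.
    """
    floor_w = max(2, params.n0)
    widths: list[int] = []
    w = n // 2
    while w >= floor_w:
        widths.append(w)
        w //= params.window_ratio
    return widths


class _ScanCache:
    """Per-signal lookup tables shared by every scan of one recursion.

    ``T[L]`` is the CLT cut-off for part length ``L`` and ``U[L] = T[L] *
    sqrt(L)`` its reciprocal-weight form, both for ``L = 1..n`` (index 0
    unused).  Because a fixed-endpoint scan visits the contiguous length
    range ``n0..n-n0``, the per-position weight vectors are plain views
    into ``U`` — building the tables once removes the normal-quantile
    evaluation (and most array allocation) from the recursion's hot path.
    """

    __slots__ = ("T", "U")

    def __init__(self, theta: float, n: int):
        L = np.arange(1, n + 1)
        self.T = np.empty(n + 1)
        self.T[0] = np.nan
        self.T[1:] = _threshold_vec(theta, L)
        self.U = np.empty(n + 1)
        self.U[0] = np.nan
        np.sqrt(L, out=self.U[1:])
        self.U[1:] *= self.T[1:]


def scan_fixed(
    S: PrefixSumArray,
    iv: Interval,
    params: DBSParams,
    cache: _ScanCache | None = None,
) -> ScanResult | None:
    """One-pass fixed-endpoint scan of ``iv`` for the best candidate split.

    For every admissible ``p`` (both sides >= ``n0``), the localization
    score ``D_p * |eps_left|`` is computed against the interval mean; the
    returned candidate is its argmax (smallest index on ties), scored by
    the Chebyshev significance ``max(|Z_left|, |Z_right|)``.  Returns None
    when the interval is too short to split.
    """
    s, e = iv.start, iv.end
    n = e - s
    n0 = params.n0
    if n < 2 * n0:
        return None
    if cache is None:
        cache = _ScanCache(params.theta, n)
    mu = (S.S[e] - S.S[s]) / n
    # candidate split positions p = s+n0 .. e-n0; left lengths n0 .. n-n0
    ul = cache.U[n0 : n - n0 + 1]  # 1/omega_left, a view
    ur = ul[::-1]  # right lengths run in reverse over the same range
    abs_eps = S.S[s + n0 : e - n0 + 1] - S.S[s]
    abs_eps -= mu * np.arange(n0, n - n0 + 1)  # eps_right = -eps_left exactly
    np.abs(abs_eps, out=abs_eps)
    k = params.k_loc
    if k is None:
        z_loc = abs_eps / np.maximum(ul, ur)
    elif k == 4.0:
        # D = (u_l^4 + u_r^4)^(-1/4), spelled with multiplies and square
        # roots: a generic pow here is the hot spot of the whole recursion
        d = ul * ul
        d *= d
        d += d[::-1].copy()
        np.sqrt(d, out=d)
        np.sqrt(d, out=d)
        z_loc = abs_eps / d
    else:
        z_loc = abs_eps * (ul**k + ur**k) ** (-1.0 / k)
    i = int(np.argmax(z_loc))
    z_sig = abs_eps[i] / min(ul[i], ur[i])
    return ScanResult(b=int(s + n0 + i), z_sig=float(z_sig), z_loc=float(z_loc[i]))


def scan_multiscale(
    S: PrefixSumArray,
    iv: Interval,
    params: DBSParams,
    cache: _ScanCache | None = None,
) -> ScanResult | None:
    """Sliding-window scan of ``iv`` across geometric scales.

    For each window half-width ``w`` and each position ``p`` with
    ``[p - w, p + w)`` inside ``iv``, the deviation of ``[p - w, p)`` from
    the local mean over the union window is scored.  Both sides have equal
    length, hence equal weight, and their accumulated errors cancel, so
    the Chebyshev significance reduces to ``omega_w * |eps|``.  The global
    argmax over ``(p, w)`` is returned; ties prefer the smallest ``p``,
    then the largest ``w``.
    """
    s, e = iv.start, iv.end
    n = e - s
    best: tuple[float, int, int, float] | None = None  # (z_loc, p, -w, z_sig)
    k = params.k_loc
    for w in window_set(n, params):
        if e - w + 1 <= s + w:
            continue
        # eps of [p-w, p) against the union-window mean reduces to
        # S_p - (S_{p-w} + S_{p+w}) / 2, evaluated here with slice views
        left = S.S[s : e - 2 * w + 1]
        mid = S.S[s + w : e - w + 1]
        right = S.S[s + 2 * w : e + 1]
        abs_eps = left + right
        abs_eps *= -0.5
        abs_eps += mid
        np.abs(abs_eps, out=abs_eps)
        Tw = cache.T[w] if cache is not None else threshold_T(params.theta, w)
        om = 1.0 / (Tw * np.sqrt(w))
        D = om if k is None else (2.0 * om**-k) ** (-1.0 / k)
        i = int(np.argmax(abs_eps))
        cand = (float(D * abs_eps[i]), int(s + w + i), -w, float(om * abs_eps[i]))
        if (
            best is None
            or cand[0] > best[0]
            or (cand[0] == best[0] and (cand[1], cand[2]) < (best[1], best[2]))
        ):
            best = cand
    if best is None:
        return None
    return ScanResult(b=best[1], z_sig=best[3], z_loc=best[0], window=-best[2])


def segment_recursive(
    signal: CopyNumberSignal,
    S: PrefixSumArray,
    sigma_hat: float,
    params: DBSParams | None = None,
) -> SegTree:
    """Build the full significance tree by recursive binary segmentation.

    Each interval is scanned with fixed endpoints first; if no candidate
    exceeds ``sigma_hat``, the multi-scale scan gets one chance.  Accepted
    splits recurse on both children (fixed scan first again).  Intervals
    shorter than ``2 * n0`` become leaves immediately.  The core is fully
    deterministic.
    """
    if params is None:
        params = DBSParams()
    cache = _ScanCache(params.theta, signal.n)
    root = SegNode(iv=Interval(0, signal.n))
    stack = [root]
    while stack:
        node = stack.pop()
        iv = node.iv
        if len(iv) < 2 * params.n0:
            continue
        res = scan_fixed(S, iv, params, cache=cache)
        if res is None or not res.z_sig > sigma_hat:
            res = scan_multiscale(S, iv, params, cache=cache)
        if res is not None and res.z_sig > sigma_hat:
            node.breakpoint = res.b
            node.z_sig = res.z_sig
            node.left = SegNode(iv=Interval(iv.start, res.b))
            node.right = SegNode(iv=Interval(res.b, iv.end))
            stack.append(node.right)
            stack.append(node.left)
    return SegTree(root)
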