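# Methods

This note records the model, the numerical choices, and the places where
the design was genuinely open, in enough detail to reimplement the
package from scratch.

## Signal model

A chromosome (arm) is observed as `x_i = y_i + ε_i`, `i = 0..n−1`, with
`y` piecewise constant (the true copy number) and `ε` i.i.d. zero-mean
noise of unknown sd `σ`.  A breakpoint is the index of the first probe of
the right-hand segment; all coordinates are 0-based half-open.  The
algorithm is index-based: genomic positions, GC content and allele-specific
(BAF) information are out of scope.

## Preprocessing

Winsorization clips every value to `μ̂ ± τσ̂`, with `μ̂`, `σ̂` the mean
and sample sd of the *whole* input vector and `τ = 2.5` (accepted range
[1.0, 5.0], warning outside [1.5, 3.0]).  A constant vector passes
through unchanged.  A centered running median (odd window, edge
replication, `scipy.ndimage.median_filter`) is available but off by
default; plain Winsorization is normally sufficient.  Segment means are
reported on the preprocessed signal.

## Noise level

`σ̂` comes from first-order differences `d_i = x_{i+1} − x_i`: values
outside the empirical `γ/2` and `1 − γ/2` percentiles (linear
interpolation; ties at the cut retained; `γ = 0.02`) are discarded —
differences straddling breakpoints land in those tails — and
`σ̂ = sd(retained) / √2` with the `(m − 1)` denominator (which also
centers the retained sample; the differences' mean is ~0 regardless).
Trimming a pure Gaussian at its 1st/99th percentiles shrinks the sd by
the truncated-normal factor `√(1 − 2aφ(a)/0.98) ≈ 0.935`, `a = Φ⁻¹(0.99)`,
so for true `σ = 0.4` the estimator concentrates near 0.374.  This
underestimate is intentional: the recursion should err toward
over-segmentation, because pruning can remove false breakpoints but
nothing can recover a missed one.

## Scan statistics

With prefix sums `S_0 = 0, S_i = S_{i−1} + x_i`, the accumulated error of
part `[i, j)` against the scanned interval's mean `μ̂` is
`ε = S_j − S_i − (j−i)μ̂`, an O(1) quantity.  The weighted deviation is
`Z_ij = ε / (T(θ, L)·√L)` where `T(θ, L) = Φ⁻¹(1 − θ/2L)` is the
two-sided normal quantile at the length-corrected level `θ/L` — the CLT
cut-off.  `μ̂` is always the mean of the interval being scanned (for
windowed scans, of the union window), never of the part itself, which
makes the left and right errors cancel exactly: `ε_left + ε_right = 0`.

**Fixed-endpoint scan.**  For each admissible split `p` (both sides
≥ `n0 = 20` probes), with weights `ω = 1/(T√L)` per side, the scan
maximizes the localization score

    z_loc(p) = (ω_l^{−k} + ω_r^{−k})^{−1/k} · |ε_left|,    k = 4

and scores the argmax by the Chebyshev significance
`ℤ = max(|Z_l|, |Z_r|)`.  The weaker-side/stronger-side duality is
deliberate: when *searching*, a split is only as credible as its weaker
side; when *measuring*, the stronger side carries the evidence.

The exponent deserves a note, because the choice is sharp.  Along a scan,
`ω_l` falls and `ω_r` rises; the log-curvature of the combination at
their crossing (the balanced split) is `(1/2 − k/4)/L²`, so the crossing
is a local **maximum** only for `k > 2` — for shallower exponents
(including a literal Minkowski `k = 0.5` on the weights, which one might
write down first) the combination is instead maximized at maximally
unbalanced splits, where the short noisy side's weight explodes; on
equal-step staircases the recursion then peels off one segment per split
(linear depth), and strong breakpoints drift by tens of probes along the
accumulated-error ramp.  The opposite limit, the exact minimum
(`k_loc=None`), restores a hard balanced maximum but its one-sided weight
gradient (~`1/2L` in log scale) measurably drags the argmax toward the
interval center near off-center breakpoints.  `k = 4` keeps both
properties to good approximation and is the default; values ≤ 2 are
rejected.

**Multi-scale scan.**  Run only when the fixed scan finds nothing
significant: a short segment sandwiched in a long interval contributes an
`ε` that the long sides average away.  Window half-widths form the
geometric sequence `n/2, n/4, …` (integer floor, ratio configurable,
default 2) down to `max(2, n0)`.  For each `(p, w)` the deviation of
`[p−w, p)` against the mean of `[p−w, p+w)` is scored; both sides have
equal length and cancelling errors, so every combination reduces to
`ω_w·|ε|` up to a constant and the Chebyshev significance equals
`ω_w·|ε|`.  Ties prefer the smallest `p`, then the largest `w`.  The
smallest admissible window bounds how sharply segments shorter than `n0`
can be localized (a 30-probe pulse is pinned only to within the ~39-probe
minimum window of a 10^4 signal).

**Recursion.**  Fixed scan first; if its best `ℤ > σ̂` (strictly), split
and recurse on both children (fixed scan first again); otherwise give the
multi-scale scan one chance; otherwise the interval is a leaf.  Intervals
shorter than `2·n0` are leaves immediately.  The core is deterministic —
no permutation tests anywhere — and all per-length cut-offs are
precomputed once per signal, so a scan position costs O(1) and the whole
recursion O(n log n).

## Pruning

After the tree is built, each leaf's sample sd is the honest local noise
estimate.  With `η = min(ℤ over non-leaf nodes) − max(leaf sd)` (`+∞` for
a single-leaf tree): if `η > λ` all candidates are kept and
`σ̂′ = max(leaf sd)`; otherwise `σ̂′ = max(leaf sd) + λ` and exactly the
candidates with `ℤ > σ̂′` survive.  Retention is a flat threshold over
all candidates regardless of depth — a child may out-significance its
parent, and a rejected ancestor with an accepted descendant leaves the
descendant in place.  Removing a breakpoint merges its two sub-segments.
`λ = 0.02` trades sensitivity against robustness and is *not* tuned
automatically.  Pruning is single-pass by default; `iterate_prune=True`
repeats it against the merged segments' sds until `η > λ`.  Final
segment means are the arithmetic means between consecutive kept
breakpoints (the L2-optimal piecewise-constant fit for those
breakpoints).

## Synthetic data

`simulate_profile` draws each segment from a Gaussian template
`N(level, σ²)`, `level ∈ {1,2,3,4}`, `σ = 0.4`, and applies normal-cell
contamination `x = p(1−α) + 2α`, which shrinks contrasts *and* noise by
`(1−α)`; boundaries between equal post-mixing means are dropped from the
truth.  The default suite (`make_test_suite`) has 104 sequences with
log-uniform lengths 10³–10⁵, 4–12 segments each (Dirichlet-partitioned
lengths, 30-probe floor, adjacent levels always distinct — a boundary
between equal levels would not be a breakpoint), and `α` drawn per
sequence from {0.3, 0.4, 0.5, 0.6, 0.7}; it totals ≈ 880 true segments.
Real array data differ in ways the generator does not emulate — heavier
tails, wavy local trends, probe-specific variance — so green results here
bound clean-data behavior, not robustness to platform artifacts.

`fig2_scenario` is a fixed demonstration layout: 10⁴ probes, seven
segments (lengths 1500/1400/1500/1300/1400/1500/1400), levels
2,3,2,3,2,3,2, `σ = 0.4`, no contamination; only the noise varies with
the seed.  The alternating levels are deliberate fixture design: every
interval the recursion scans then presents a sharp accumulated-error kink
at its dominant breakpoint, the regime in which a cumulative-sum scan
localizes to a few probes.  A monotone run of levels makes one side of
some kink's slope `|segment mean − interval mean| ≈ 0`, and the argmax
then wanders `O(σ²/slope²)` probes — a property of the statistic, not of
the implementation, and worth knowing when interpreting real profiles
with staircase-like amplifications.

## Evaluation

A per-locus binary classifier turns a segmentation into testable calls:
probe `p` is *normal* iff `|μ_k − 2| < τ` for its segment's estimated
mean `μ_k` (ties aberrant).  The gold standard samples, for every true
breakpoint, up to 4 locations per side uniformly within 200 probes
(clipped to the adjacent true segments), labeled from the *true*
post-mixing means; under the default suite this yields roughly 1:3
positive:negative imbalance.  Sweeping `τ` from 0 in steps of 0.01 up to
`max(2, max|μ̂−2|+0.01)` traces the ROC; AUC is the trapezoidal area with
the degenerate endpoints appended.  Over-segmentation — invisible to the
ROC, since splitting a correct segment leaves its mean unchanged — is
reported separately as predicted/true total segment count.

## Problem sizes and defaults

The shipped checks use 50 replicates of the 10⁴-probe demonstration
profile for the noise estimator, 100 replicates of 10⁴ pure-noise probes
for the null calibration, the 104-sequence suite (~2.3 M probes in
total) for the accuracy floor, and 16 k- vs 160 k-probe staircases at
matched breakpoint density (one segment per ~2000 probes) for the
scaling trend; together they run in a few seconds on one core.  Defaults:
`θ = 0.05`, `γ = 0.02`, `λ = 0.02`, `n0 = 20`, window ratio 2,
`k_loc = 4`, Winsorization `τ = 2.5` (on), median filter off.

## Known limitations

* Breakpoints are placed once, at discovery; there is no post-hoc
  refinement step, so the first split of a many-breakpoint interval can
  carry a few probes of localization error that pruning cannot repair
  (it can only delete).
* Segments shorter than `n0 = 20` probes are invisible by construction,
  and short segments generally are localized only to within the smallest
  admissible window.
* The `η`-gap pruning uses a single global `σ̂′` per chromosome; strongly
  heteroscedastic noise (e.g. amplified regions with inflated variance)
  raises `max(leaf sd)` and can let weak false breakpoints elsewhere
  survive the keep-all branch.
* Low-density platforms (array CGH-scale) violate the CLT sample-size
  assumptions that the thresholds rest on.
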