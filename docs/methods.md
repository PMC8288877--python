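# Methods

## Model and estimators

### Matrix representation

A temporal network is a sequence of `T` weighted snapshots on a fixed set
of `n` nodes. The expanded matrix `M` enumerates all ordered node pairs
as rows (`row = source·n + target`, self-pairs included so the row count
is exactly `n²`; generators never emit self-loops, so those rows are
all-zero and removed by filtering). Undirected data populate both ordered
pairs, i.e. one undirected link contributes two (identical) rows. Column
`t` reproduces snapshot `t` exactly, and the construction round-trips.

Weights must come from a finite alphabet; continuous weights are
uniformly binned into `B` levels (default `B = 10`) over the observed
non-zero range, with 0 reserved for absence. `N` always denotes the
number of distinct values actually present in the matrix at hand, zeros
included.

### Filtering

Rows are sorted by activation rate `a_i` (fraction of non-zero entries)
descending, ties broken by original row index so the sort is
deterministic and idempotent. With `m60` the smallest row count whose
cumulative activation reaches 60% of the total and `m10` the number of
rows with `a_i ≥ 0.1`, the retained count is `m60` when `m60 < m_θ`, and
otherwise `max(m_θ, m10)` capped at the number of non-zero rows
(default `m_θ = 1000`). The second branch is deliberately read as "keep
everything at least 10% active, but no fewer than the `m_θ` most active
links": a literal infimum of `{m : a_m ≥ 0.1}` under a descending sort
would always return 1 and cannot be what the rule intends. Activation
arithmetic uses integer occurrence counts, so threshold comparisons are
exact.

### 2D match lengths and entropy rate

For a square matrix, `Λ_v` is the smallest block side `k` such that the
`k × k` block with lower-right corner `v` occurs at no earlier anchor
`u ≤ v` (componentwise, `u ≠ v`) whose block lies fully in-bounds.
Conventions, chosen once and validated against literal enumeration:

* **Anchoring.** Blocks are read backward from their lower-right corner,
  consistent with scanning the history rectangle `(0, v]`.
* **No padding.** Anchors whose block would leave the matrix are skipped.
* **Saturation.** A size `k` with no admissible anchor at all cannot
  distinguish anything; cells where every admissible size is matched —
  or that have no admissible candidate, like the origin — carry
  `Λ = k_max(v) + 1`, where `k_max(v)` is the largest side that fits at
  `v`. This extends the estimator monotonically: more regularity always
  means larger `Λ`. A constant matrix saturates everywhere.

The entropy rate is `H = n² log₂ n² / Σ_v Λ_v²` bits per symbol. The
production implementation is level-wise: per side `k` it groups all
cells by a rolling polynomial hash of their block (two independent
64-bit hashes; row-window extension plus invertible vertical prefix
sums, all O(n²) per level) and resolves "occurs earlier" with a single
prefix-minimum sweep per hash group. Exactness is enforced in the test
suite by comparison with a brute-force enumerator on hundreds of small
matrices; runtime is a few levels × O(n² log n) for irregular matrices
and bounded by O(n³ log n) for perfectly regular ones (n = 300 runs in
well under a second either way).

### 1D match lengths (per-link predictability)

The per-link estimator uses substring match lengths with the same
saturation convention and

    H = T log₂ T / Σ_t Λ_t   (bits per symbol).

The match length enters **linearly** here: the recurrence time of a
length-`k` substring scales as `2^{kH}` (a substring covers `k` symbols,
a block `k²`). The square belongs only to the 2D estimator. This
calibration is what makes an IID binary sequence score `H ≈ 1` bit and
`PIL ≈ 0.5`, and a constant sequence `PIL = 1`.

### Fano inversion and normalization

`solve_fano(H, N)` returns the unique `Π ∈ [1/N, 1]` with
`H = h₂(Π) + (1 − Π) log₂(N − 1)`, by bracketed root-finding to 1e-9;
`H = 0 → Π = 1`, `H ≥ log₂ N → Π = 1/N` (the estimator may overshoot
`log₂ N` on small inputs; the clamp handles it), `N = 1 → Π = 1`. The
root is non-increasing in `H` and non-decreasing in `N` (at fixed low
entropy, a larger alphabet implies stronger concentration).

Normalization over a shuffled baseline is `(p − b)/(1 − b)` clamped to
`[0, 1]` (finite-sample noise can put `p` marginally below `b`), with the
saturated case `p = b = 1` defined as 1 and `b = 1 > p` undefined (NaN
with a warning). TTP uses global shuffles of the filtered matrix, PIL
uses within-row shuffles (which preserve each activation rate exactly);
baselines average over 10 shuffles by default — the underlying
publication does not state a count, and the shuffle spread at these
matrix sizes makes 10 ample. All shuffle seeds derive from one master
seed, so profiles are bit-reproducible.

Per-link Fano inversion uses the **row's own alphabet**, not the global
one: a link that never changes is perfectly predictable in isolation,
which is the behaviour a per-link measure should have. (Whether the
original analysis used the global alphabet instead is not documented;
this choice is the self-consistent one.)

### Predictive congruency

Non-square matrices are tiled by greedy Euclidean decomposition: carve
`⌊b/a⌋` squares of side `a = min(h, w)` along the longer axis, recurse on
the remainder, dissolve 1-wide strips into units. The tiling is exact
(`Σ e² + u = D`), deterministic, and produces sides in non-increasing
order. Each square of side ≥ 2 is scored by the 2D estimator with the
matrix-wide alphabet; units score the chance level `1/|A|`. Stage `i`
atomizes the `i − 1` smallest squares; the stage points `(N_i, p_i)` are
fitted by ordinary least squares and extrapolated to `N = 1`, clamped to
`[1/|A|, 1]`. With fewer than two distinct stages (Q ≤ 2) the coarsest
stage's weighted average is returned unmodified. The displayed relation
`(e²/(e²−1))(1/|A| − p_i) = kD` in the source material is a consistency
statement about the same line and is not used for computation. Whether
the original tiling allowed overlaps or sampling is not documented; the
greedy exact tiling is this package's documented choice.

## Generators (what the synthetic data emulate)

* **Temporal SBM** (defaults: 100 nodes, 4 communities, degree 3,
  T = 300, weights 1..10, `p_β = p_γ = 0.5`). The initial snapshot is a
  near-regular community graph built by biased stub matching (80% of
  stubs pair intra-community; bounded retries mean a few nodes may end
  one short of degree 3 when parity forbids exactness — the degree
  histogram is checked in tests). Topology is then frozen; weights evolve
  column by column, top to bottom: with probability `p_β·β` copy the
  weight just written for the previous link in the same column (the
  first link falls back to a fresh draw), with `p_γ·γ` keep the own
  previous weight, otherwise draw uniformly. The stationary symbol
  distribution stays uniform; `β` builds vertical (topological) runs,
  `γ` horizontal (temporal) ones. The mid-grid condition β = γ = 0.5 is
  used as the representative instance for the congruency-slope and
  Markov-bound checks.
* **2D FGN**: Gaussian field with target correlogram
  `C(r, φ) = r^{−γx} cos²φ + r^{−γy} sin²φ`, synthesized by spectral
  filtering on the periodic grid. The target is not positive
  semi-definite, so negative spectral weight is clipped; the synthesis is
  an approximation whose *ordering* in the exponents (and its
  anisotropy) is what the tests rely on. Note the target itself pins
  `C(1, φ) = 1` for every exponent, so nearest-neighbour correlation is
  always high; decay properties are meaningful only for `r ≥ 2`.
* **Evolving small world** (50 nodes, ring, average degree 2): each
  snapshot rewires `⌊p·E⌋` uniformly chosen links, keeping one endpoint
  and redrawing the other uniformly while avoiding self-loops and
  duplicates; the link count stays exactly `n`.
* **IID null**: uniform matrix over `N` symbols.

All generators are seed-deterministic. What they do **not** emulate:
bursty or circadian activity, degree heterogeneity, weight
non-stationarity, node churn. Passing the validation suite therefore
shows the estimators behave correctly on networks with controlled
memory structure, not that any particular real system is predictable.

## Numerical choices and problem sizes

* Logarithms are base 2 throughout; predictabilities are probabilities.
* Fano root-finding tolerance 1e-9 (absolute, in Π).
* Block hashing uses two independent 64-bit polynomial hashes; a
  collision would require both to collide simultaneously on structured
  integer data, and the oracle-equivalence tests guard the
  implementation.
* The validation suite runs the published-scale settings where they are
  cheap (small-world sweep at n = 50, T = 300, 10 seeds; SBM at
  100 nodes, T = 300) and reduced instances (40 nodes, T = 120) for
  structural property tests; sizes are stated in each test.

## Known limitations

* The 2D entropy estimator is asymptotic. At n = 128 the IID binary
  estimate is ≈ 0.91 bits rather than 1.0 — two finite-size effects
  (integer `Λ` jitter inflating `Σ Λ²`, and history rectangles smaller
  than the full matrix deflating it) do not cancel exactly. Because the
  Fano bound at `N = 2` is steep near `H = 1`, the TTP of an IID binary
  matrix computes to ≈ 0.67, approaching 0.5 only slowly with matrix
  side. Normalized quantities (NTTP) are robust to this bias because the
  shuffled baseline shares it; raw TTP values near chance should be read
  with that caveat.
* Congruency extrapolation inherits the variance of its smallest squares
  and is undefined (fallback) for matrices tiling into ≤ 2 squares.
* No confidence intervals beyond shuffle spread; no streaming input; no
  multilayer networks; deep-learning comparison predictors are out of
  scope.
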