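# Methods

## Model

The spiking–bursting process is a stationary binary vector process on N
nodes. A hidden dichotomous component is *spiking* with probability `ps`
and *bursting* with `pb = 1 − ps`. In a bursting bin every node reads 1; in
a spiking bin the word is an independent draw from a spatial distribution
`s_x` over the 2^N words (probability `s1` for the all-ones word). Words
are encoded as integers with node i on bit i, node 0 the least significant
bit — fixed throughout.

The lag-τ pair behavior of the hidden state is a 2×2 joint table. With the
scaling-invariant correlation parameter ε (`pss = ps²(1+ε)`):

```
pss = ps²(1+ε),  psb = pbs = ps·pb − ε·ps²,  pbb = pb² + ε·ps².
```

Nonnegativity of the cells bounds the parameters: `0 ≤ ε ≤ pb/ps`,
equivalently `ps ≤ 1/(1+ε)`. Only nonnegative correlations are supported
(negative ε would need the other branch of the `ps` bound and is outside
the package's scope). ε relates to the lag-τ Pearson coefficient by
`ε = ρ·pb/ps`.

The resulting one- and two-time tables are exact:

```
p(x≠1) = ps·s_x            p(1) = ps·s1 + pb
p(x≠1, y≠1) = pss·s_x·s_y  p(x≠1, y=1) = π·s_x,  π = pss·s1 + psb
p(1, 1) = pss·s1² + 2·psb·s1 + pbb
```

**Parameter redundancy.** Because a system-wide spontaneous spike and a
one-bin burst are observationally identical, the parameterization admits a
one-parameter family of relabelings that leaves the process invariant:
`s_x → s_x/α` (x ≠ 1), `s1 → 1 − (1−s1)/α`, `ps → α·ps`, `pss → α²·pss`,
with ε invariant. `scaling_transform` implements it; the admissible α
interval `[1−s1, ps_max/ps]` is computed from the constraints and reported
in the error message when violated. Tests verify the two-time table is
invariant elementwise to ≤1e−12 across the admissible range.

**Degenerate corners** (`s1 = 1`, or `ε = 0`; `ps ∈ {0,1}` is rejected at
validation) make every delayed information vanish identically; table
builders accept them and the information operations return exactly 0
without evaluating 0·log 0.

## Information measures

All logarithms are base 2. The closed form

```
i0(p, ε) = 2{p} + 2{1−p} − {pss} − 2{psb} − {pbb},   {q} = −q·log2 q,
```

is the delayed mutual information of the bare dichotomous component, and
every mutual information of the full model is `i0` at a rescaled first
argument: `I_xy = i0((1−s1)ps, ε)`, subsystem `I_A = i0((1−s_A)ps, ε)`
with `s_A` the subsystem-wide spontaneous-spike probability (a marginal of
`s_x`). The implementation evaluates `i0` in the equivalent
Kullback–Leibler regrouping

```
ln2 · i0 = pss·ln(1+ε) + 2·psb·log1p(−ε·p/(1−p)) + pbb·log1p(ε·p²/(1−p)²)
```

because the brace form suffers catastrophic cancellation for small
arguments (`i0 ~ C(ε)·p²` as p → 0 while individual terms are O(p·ln p));
the regrouped form is accurate to machine precision across the domain,
which the s1 → 1 limits require. A five-term expansion in the raw model
probabilities (`i_xy_expanded`) is kept as an independent route and the
test suite checks the three routes (closed form, expansion, generic MI on
the full 2^N×2^N joint) agree to ≤1e−12.

**MIB search** enumerates all `2^(N−1) − 1` canonical bipartitions (node 0
in A) exhaustively; the cap defaults to N = 12 and must be raised
explicitly beyond that. Bipartitions whose smaller subsystem entropy is 0
are excluded from the argmin (the normalization is undefined and a
zero-entropy subsystem carries no information); if all are excluded the
result carries a `degenerate` flag with Φ = 0. Ties are broken by the
smallest A-mask for determinism.

**Decoder-based Φ\*.** The mismatched decoding kernel
`q(y|x) = p(y_A|x_A)·p(y_B|x_B)` is built from marginalized pair tables;
a zero-probability conditioning state raises an error naming the state.
The scalar objective is maximized over β ∈ [0, 100]: a 64-point log-spaced
scan brackets the maximum and a bounded golden-section/Brent refinement
(xatol 1e−8) polishes it; the larger of scan and refinement is returned,
so unimodality is not blindly assumed. The objective is exactly 0 at β = 0
and underflow of `q^β` at large β is mapped to −∞ (the true objective is
far negative there, and the naive evaluation would spuriously return +∞).
`I*` is clipped into `[0, I_xy]`, making Φ\* ≥ 0 by construction as the
measure requires. In practice the maximizer sits near β ≈ 1 and approaches
1 as s1 → 1. Φ\* is evaluated on a caller-chosen bipartition (convention:
the balanced split with lowest-index nodes in A); a MIB-style search over
Φ\* is deliberately not the default.

## Sign analysis

For independent spiking (`s_A·s_B = s1` for every bipartition), Φ_eff
depends on the bipartition only through `s = s_A`:
`f(s) = i0((1−s1)ps) − i0((1−s)ps) − i0((1−s1/s)ps)` on `s1 < s < 1`, with
`f(s1/s) = f(s)` and zeros at both ends. The symmetric-point value
`g(s1) = f(√s1)` controls the sign: `g(0) = −i0(ps, ε) < 0`, `g → +0` as
`s1 → 1` (the whole-to-symmetric i0 ratio tends to 2), so g has a root.
Uniqueness of that root is numerical evidence, not a theorem: the package
certifies it per call by scanning g on a grid before bisecting
(xtol 1e−12), and raises `AnomalyError` on zero or multiple sign changes.
The scan grid combines a linear sweep (step 1e−3) with a log-spaced tail
down to 1e−9, because the root falls below any fixed linear step as
ps → ps_max. The analogous guard on f counts grid extrema and raises if
more than three appear (the case that would break the equivalence of the
g-criterion to the bipartition-minimum criterion).

**Weak-correlation asymptotics.** Second-order Taylor expansion of i0 in ε
gives `i0 ≈ ε²/(2 ln 2)·(ps/(1−ps))²` (the first-order term cancels
identically). The validity flag implements "ε small" as `|ε| ≤ 0.2`
together with the strict bound `ps < 1/(1+|ε|)`; 0.2 is our cutoff choice
— the exact statement is an asymptotic one and any finite cutoff is a
convention. Substituting the approximation into g = 0 collapses the
threshold to the ε-independent quadratic
`ps(√2−1)u² − u + (1−ps)(√2−1) = 0`, `u = √s1`, solved in the conjugate
(cancellation-free) form. Its ps → 0 limit is `(√2−1)² = 3 − 2√2 ≈ 0.1716`
— the universal sufficient spiking level — and the root decreases
monotonically in ps. Because the ε² factor scales Φ_eff without moving its
zero or changing the MIB's normalizing entropies, the sign verdict and the
threshold are ε-free in this limit; tests check the ε² collapse of
Φ_eff/ε² within 10% (and Φ\*/ε² within 25%, where the scaling is only
numerical) over ε ∈ {0.0125, 0.025, 0.05}.

**Spatially correlated spiking** is analyzed directionally only: if
`s1 > s_A·s_B` everywhere (positive correlation), necessary conditions for
positive Φ survive; if `s1 < s_A·s_B`, sufficient conditions survive. The
positivity report states which logic applies; no closed-form treatment of
correlated tables is attempted.

## Simulator

The exact model pins down only the one-lag pair table of the hidden state.
The simulator realizes the *minimal Markov completion*: a stationary
two-state chain started from (ps, pb) with stay probabilities `pss/ps` and
`pbb/pb`, whose one-step joint equals the exact table. This is an
implementation choice, not part of the model definition; at lags beyond
one the chain's effective correlation decays geometrically, so empirical
analysis defaults to τ = 1 and lag-τ analysis of simulated data must use
the chain-implied table. Independent spike tables are sampled per node;
general tables by inverse CDF over the 2^N words. Identical seeds give
identical realizations (`numpy.random.default_rng`).

Plug-in estimation replaces the tables by word(-pair) frequencies (the
pair table symmetrized to match stationarity) and feeds them through the
same definitional information routines. Convergence checks in the tests
use N = 3, T = 1e5 (total variation ≤ 0.01 against the exact tables) and
8-seed replicate spreads for the mutual information; these sizes were
chosen as the smallest at which multinomial sampling error is comfortably
inside the asserted tolerances.

## What the synthetic conditions do and do not show

All fixtures are generated from the model itself (independent spike
tables, the 6-node equal-rate configuration `P = s1^(1/6)` with the
symmetric 3|3 bipartition for measure comparison, `ps = 0.6`,
ε ∈ {0.05, 0.1, 0.2}). Passing tests certify the analytic structure —
closed forms, thresholds, scaling, estimator consistency *under the
model's own assumptions*: binary bins, a single system-wide burst driver,
spiking independent across time and (in the exact analysis) across nodes.
They do not certify behavior on real recordings, where bursts have
spatial structure, spiking is autocorrelated, and binning is a modeling
decision.

## Numerical conventions

- Probability hygiene: sum-to-one and nonnegativity enforced at 1e−12;
  values in [−1e−12, 0) clamped to 0.
- Root-finding: bracketing bisection only (robust, monotone), xtol 1e−12.
- β search: [0, 100], log-spaced coarse scan + bounded refinement,
  xatol 1e−8.
- Bipartition enumeration capped at N = 12 by default (4095 bipartitions,
  4096-state tables); the cap is an argument, not a hard limit.
- Acceptance-script problem sizes: the threshold limit is probed at
  ps = 1e−4, 1e−5, 1e−6; the mutual-information maximum on a
  100×99×{0.1, 0.5, 1, ε_max} grid (~3·10⁴ valid points); the ratio limit
  at s1 = 1 − 10^−k, k = 2..6 with one-step Richardson extrapolation.

## Known limitations

- Negative time correlations (ε < 0) are not implemented.
- The uniqueness of the g-root and the ≤3-extrema property of f are
  verified numerically on the standard grid, not proven; the guards raise
  rather than silently returning a root if violated.
- Plug-in estimates carry the usual positive MI bias O(#cells/T); no
  bias-corrected estimator is provided.
- The simulator's Markov completion is one of many processes consistent
  with the one-lag table; multi-lag statistics are not model predictions.
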