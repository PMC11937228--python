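# Methods

## Model and observation process

The motion model is a one-dimensional n-state velocity-jump process. The
hidden state is a continuous-time Markov chain: holding times in state `s`
are Exp(λ_s) (mean `1/λ_s`), and the embedded chain `P` (zero diagonal,
stochastic rows, irreducible) selects the next state. Position integrates
the state velocity exactly, so paths are piecewise linear. The chain is
assumed stationary at the start of observation: the initial state is drawn
from `π` with `πQ = 0`, which makes the increment process marginally
time-invariant.

Observations are positions at frame times `t_j = jΔt` corrupted by i.i.d.
Gaussian localization error with s.d. `σ`. The per-interval noisy increment
is therefore `Δy_j ~ N(Δx_j, 2σ²)` given the exact increment, and adjacent
noisy increments share one frame's error, giving them a `−σ²` noise
covariance.

Units are unconstrained; everything is expressed in the user's length and
time units. The dimensionless quantity that controls every approximation is
`λ_s Δt`, the expected number of switches out of state `s` per frame.

## Increment-density approximations

The density of one increment decomposes over the switch count `W` and the
ordered states visited. The package truncates this hierarchy with the
up-to-m-switch rule: intervals with more than `m` switches are treated as
if they had exactly `m`, so the `W = m` conditional density is weighted by
`P(W ≥ m)`. This preserves total mass exactly (the weights partition unity
for every start state), unlike simply dropping the tail.

Conditional ingredients, all with independently verified closed forms:

* `P(W=0 | s) = exp(−λ_s Δt)`; the increment is `N(v_s Δt, 2σ²)`.
* `P(W=1 | s1, s2) = λ1 (e^{−λ2Δt} − e^{−λ1Δt}) / (λ1 − λ2)`, with the
  limit `λΔt e^{−λΔt}` as the rates coincide. Given one switch, the switch
  time is a truncated exponential with rate `λ1 − λ2` on `[0, Δt]` (which
  may be negative — the truncation keeps it proper), and the exact
  increment is its linear image. The noise convolution is computed by
  completing the square: the result is an exponential prefactor times a
  difference of normal CDFs, evaluated via `log_ndtr` with a tail-flip so
  that both tails are accurate; the weights and the prefactor are combined
  in log space.
* `P(W≥2 | s1, s2)` is the hypoexponential CDF of `τ1 + τ2` at `Δt`,
  independent of the third state.
* Given `W = 2` and states `(s1, s2, s3)`, the pair `(τ1, τ2)` has density
  `∝ exp(−(λ1−λ3)τ1 − (λ2−λ3)τ2)` on the simplex `τ1, τ2 > 0,
  τ1 + τ2 < Δt`. Collapsing the increment constraint by the sifting
  property leaves a 1-D exponential integral in `τ1` over an interval
  `[E0(Δx), E1(Δx)]`. Rather than transcribing piecewise-linear endpoint
  formulas, the implementation intersects the four linear constraints
  (`τ1 ∈ [0, Δt]`, `τ2(τ1) ∈ [0, Δt − τ1]`) directly per evaluation point;
  this is equivalent, covers every ordering of the intermediate velocity,
  and is vectorized over the grid. Velocity ties reduce to 1-D marginals of
  the simplex density: `v2 = v3` leaves `Δx` a function of `τ1` alone,
  `v1 = v3` (which includes every `s3 = s1` case) a function of `τ2` alone,
  and `v1 = v2` a function of `τ1 + τ2`; all three marginals are explicit.

The two-switch noise convolution is evaluated as the expectation of the
Gaussian kernel over the simplex density with a tensor Gauss–Legendre rule
(default order 80 per axis, mapped to the triangle). The integrand is
smooth, so the rule converges spectrally; agreement with adaptive
quadrature of the defining convolution is at machine precision for the
regimes exercised in the tests. The evaluation is flagged
`branch: "quadrature"` in the optional metadata; the one-switch evaluation
reports `branch: "closed-form"`. The quadrature becomes inefficient only
when `σ√2` is far below ~2% of the support span; at such noise levels the
exact-increment densities are the better tool anyway.

Orders `m ≥ 3` are not implemented: the number of ordered state sequences
grows combinatorially and the two-switch machinery already covers the
regimes where the marginal approximation is useful.

## Track likelihood

The joint density of N increments is factorized into conditionals. Under
the up-to-one-switch truncation, the pair (increment, start state of the
next interval | start state of this interval) has the kernel

* stay: `N(v_s Δt, 2σ²) · e^{−λ_s Δt}`,
* move `s → u`: `f̃_{s,u}(Δy) · p_su · (1 − e^{−λ_s Δt})`,

because keeping the state across an interval is (to this order) a zero-
switch event and changing it a one-switch event. A standard forward filter
over the hidden start state — Bayes update plus per-step renormalization,
evidence accumulated in log space — then yields the joint density exactly
given the kernel: the recursion is algebra, not an additional
approximation, which is why it matches exhaustive state-sequence
enumeration to 1e-12 relative in the tests. The end state of the final
interval is marginalized (the kernel sums over it), consistent with the
factorized form. Vanishing evidence raises a diagnostic naming the first
offending increment.

Two deliberate approximations remain: the order-1 truncation of the kernel
(chosen for speed and simplicity; the kernel interface is the place to plug
a higher order), and the neglect of the `−σ²` noise covariance between
adjacent increments — each interval's emission uses variance `2σ²`
independently. The latter makes the predicted peaks of the pairwise joint
surface circular where the empirical ones are slightly oval; it is a known,
documented bias that grows with `σ`.

The independence baseline `Π_j P1(Δy_j)` is provided for comparison; on
slowly-switching data the filter's log-likelihood exceeds it because
consecutive increments are strongly informative about the shared hidden
state.

## Estimation

`VelocityJumpMLE` maximizes the summed forward-filter log-likelihood over
velocities, log rates, optionally softmax-parameterized free rows of `P`,
and log σ, with L-BFGS-B from multiple seeded restarts (default 5;
restarts matter because the surface is multimodal across state
relabelings). Fitted states are reported sorted by velocity to resolve
label degeneracy. Parameter sets that fail validation or produce degenerate
likelihoods are assigned a large penalty rather than aborting the search.
Bound-hitting is reported (`bounds_hit_`) rather than silently accepted.

## Synthetic data

All data in the tests and the acceptance script is generated by the
package's own simulator, which is exact: Gillespie state paths (overshoot
one holding time, truncate), piecewise-linear integration of the velocity
to frame times with no discretization error, i.i.d. Gaussian frame noise,
and switch counts per half-open interval `(t_{j−1}, t_j]` (a jump exactly
at a frame time belongs to the earlier interval — measure zero but
deterministic). Single-interval draws with stationary initial states are
vectorized and are marginally equivalent in law to consecutive increments
of a long track; pair draws share the middle frame's noise so that the
empirical pairwise density carries the true noise correlation that the
approximation neglects.

The bundled example networks (two-, three-, four- and six-state) reproduce
the qualitative topologies of motor-like motion: forward/backward runs,
a long-lived and a short-lived stationary state, a four-state network where
direction reversal requires passing through the stationary states (making
the total pause hypoexponential), and a six-state cyclic network with pause
states that mostly return to the previous direction. Their numeric defaults
are package choices, stamped `provenance: package-default`: speeds ±1,
`Δt = 1`, `σ = 0.05` (5% of the per-frame displacement), and baseline
moving-state rates `λ = 0.2` so that switching is infrequent at baseline
(`λΔt = 0.2`) and the `rate_multiplier` device (×5, ×10) pushes the model
into the frequent-switching regime where the approximations degrade — at
×10 the two-state network has `λΔt = 2` and its switch process is Poisson
with `P(W > 2) = 1 − 5e^{−2} ≈ 0.323`.

What the generator does not emulate: multi-dimensional motion, angular
reorientation, diffusive interludes, velocity distributions within a state,
non-exponential waiting times, non-Gaussian or frame-correlated noise
beyond the shared-frame structure, and detection/linking artifacts of real
tracking pipelines. Passing tests therefore demonstrate correctness of the
mathematics under the model's own assumptions, not robustness to their
violation.

## Numerical choices

* Stationary law via SVD of `Qᵀ`; the kernel vector with smallest singular
  value is taken, a second singular value below `1e-8 ‖Q‖` raises a
  degenerate-kernel error, and round-off negatives (> −1e-12) are clipped
  before normalization.
* Irreducibility by strongly-connected-components on the `p_su > 0`
  adjacency (threshold exactly `> 0`; config values are user-specified).
* Equal-rate branches switch to limit formulas when `|λ_i − λ_j|Δt < 1e-8`
  (cancellation in the `1/(λ1 − λ2)` denominators); velocity ties use
  `|v_i − v_j| < 1e-12 · max(1, v_max)`.
* `∫_0^L e^{−ct} dt` is computed via `expm1` with a series branch below
  `|cL| < 1e-12`; the simplex normalizer has closed forms in either
  variable plus a quadratic series when both exponents are small.
* Histogram comparisons default to 200 uniform bins spanning
  `[min_s v_sΔt − 5σ√2, max_s v_sΔt + 5σ√2]`, covering every Gaussian peak.
* The rejection oracle aborts if its estimated acceptance probability falls
  below 1e-6, bounding runtime on badly conditioned requests.
* Track CSVs serialize floats at 17 significant digits and are parsed with
  round-trip float precision, so write→read is bit-identical.

## Problem sizes

The test suite and acceptance script use: 100 random models/rate pairs for
the analytic invariants; 1e5 rejection or stationary-interval draws for
Monte-Carlo density comparisons (errors asserted per bin against 3 binomial
standard errors); 1e6 increments or increment pairs for the empirical
L1-error comparisons of `P1`, `P2` and the joint surface; 20 random inputs
for the enumeration check of the recursion; and 1e4 increments for
parameter recovery (velocities recovered within 5%, rates within 20% at
`λΔt = 0.1`). These sizes give comfortable separation between the compared
error norms at the package's default parameters.

## Known limitations

* The marginal and track approximations are biased when `λ_s Δt` is not
  small; the two-switch marginal extends the usable range but the track
  kernel is order 1 only.
* The noise-independence assumption in the track likelihood is a structural
  bias, visible in pairwise surfaces, that does not vanish with more data.
* `σ = 0` is supported by the simulator but not by the noisy densities
  (they would be degenerate); exact-increment densities cover that case.
* Likelihood-based fitting of the free transition probabilities is
  implemented but weakly identified on short tracks; fixing the topology
  (structural zeros) is strongly recommended.
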