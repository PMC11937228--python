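# vjump

Analytic increment densities and track likelihoods for **n-state
velocity-jump models** observed at discrete times with measurement noise.

Many motile systems — molecular motors stepping along microtubules,
run-and-tumble bacteria, intermittently paused cargo in axonal transport —
move at a roughly constant velocity until an internal state change switches
that velocity. Tracking experiments record only the position, at a fixed
frame interval Δt and with localization error, so the switching times and
the hidden state are never observed directly. `vjump` provides the forward
machinery for this setting: an exact simulator of the motion and of the
data-collection process, closed-form approximations to the probability
density of the observed displacement per frame, an approximate likelihood
for whole tracks, and maximum-likelihood parameter estimation built on it.

## Model

The hidden state `S(t) ∈ {1..n}` is a continuous-time Markov chain: the
holding time in state `s` is Exp(λ_s) and the next state is drawn from row
`s` of an embedded transition matrix `P` (zero diagonal, stochastic rows).
The agent moves with the state's velocity, `x(t) = Σ_s v_s T̂_s(t)` with
`T̂_s` the occupation time of state `s`. Observations are
`y_j = x(jΔt) + ε_j` with `ε_j ~ N(0, σ²)` i.i.d., so a noisy increment
satisfies `Δy_j | Δx_j ~ N(Δx_j, 2σ²)`. The chain starts from its
stationary law `π` (the kernel of `Qᵀ`, where `q_su = λ_s p_su`,
`q_ss = −λ_s`).

The density of a single increment, conditioned on the number of switches
`W` in the interval, is tractable for small `W`:

* `W = 0`: a Gaussian at `v_s Δt`;
* `W = 1`: a truncated-exponential switch-time density pushed through the
  linear map `Δx = v_1 τ_1 + v_2 (Δt − τ_1)`, convolved with the noise —
  available in closed exponential × normal-CDF form;
* `W = 2`: a bivariate exponential density on the holding-time simplex
  collapsed by the increment constraint, convolved with the noise.

The **up-to-m-switch approximation** `P_m(Δy)` treats intervals with more
than `m` switches as if they had exactly `m`; the package implements
`m = 1` and `m = 2`. For whole tracks, an up-to-one-switch kernel for
(increment, next start state | current start state) feeds a forward filter
whose per-step evidence terms multiply to an approximate joint density
`P_1(Δy_1, …, Δy_N)` — a likelihood usable with any inference method. These
approximations are accurate when switching is infrequent relative to the
frame interval (`λ_s Δt` small) and degrade as rates grow.

## Worked example

```python
import numpy as np
from vjump import *

model = validate_model(VelocityJumpModel(
    velocities=[1.0, -1.0], rates=[0.2, 0.2],
    transition_probs=[[0, 1], [1, 0]], state_names=["F", "B"]))
scheme = ObservationScheme(dt=1.0, sigma=0.05, n_increments=200)

print("stationary law:", stationary_distribution(model))

track = simulate_track(model, scheme, seed=7)
dy = track.increments

ll_filter, states = forward_filter(dy, model, scheme)
ll_naive = naive_product_loglik(dy, model, scheme)
print(f"forward-filter log-likelihood: {ll_filter:.2f}")
print(f"independent-product baseline:  {ll_naive:.2f}")

p1 = marginal_density(np.array([1.0, 0.0, -1.0]), model, scheme, order=1)
print("P1 at dy = +1, 0, -1:", np.round(p1, 4))

est = VelocityJumpMLE(transition_probs=[[0, 1], [1, 0]], dt=1.0,
                      sigma=None, n_restarts=2, random_state=0).fit(dy)
print("fitted velocities:", np.round(est.velocities_, 3))
print("fitted rates:     ", np.round(est.rates_, 3))
print("fitted sigma:     ", round(est.sigma_, 4))
```

Output:

```
stationary law: [0.5 0.5]
forward-filter log-likelihood: 79.54
independent-product baseline:  5.03
P1 at dy = +1, 0, -1: [2.3549 0.0906 2.3549]
fitted velocities: [-1.005  1.003]
fitted rates:      [0.193 0.236]
fitted sigma:      0.0486
```

The filter log-likelihood far exceeds the independence baseline: at
`λΔt = 0.2` consecutive increments are strongly correlated (the agent
usually keeps its velocity across frames), and the filter exploits that.
`P1` is bimodal with sharp peaks at `±vΔt` — each peak is the no-switch
Gaussian of one moving state — and a low bridge between them from intervals
containing one switch. From 200 noisy increments the MLE recovers the
velocities within ~0.5%, the rates within ~20%, and the noise level within
~3%.

A command-line interface mirrors the library:

```bash
vjump simulate --config model.yaml --seed 1 --out tracks.csv
vjump pdf --config model.yaml --order 2 --grid -1.5:1.5:301 --out pdf.json
vjump loglik --config model.yaml --tracks tracks.csv
vjump fit --config model.yaml --tracks tracks.csv --seed 1
vjump compare --config model.yaml --seed 1 --reps 200000
```

Configs are YAML; `vjump.io.example_network` emits ready-made two-, three-,
four- and six-state topologies (forward/backward motion plus stationary and
pause states) with documented package-default parameters and a
`rate_multiplier` knob to stress the approximations.

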