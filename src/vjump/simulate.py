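"""Exact simulation of the velocity-jump process and its observation model.

The hidden state path is simulated exactly (Gillespie: exponential holding
times, embedded-chain jumps), the location ``x(t)`` is the piecewise-linear
integral of the state velocity, and observations are ``y_j = x_j + eps_j``
with i.i.d. Gaussian measurement noise at frame times ``t_j = j*dt``.
Monte-Carlo oracles used as ground truth in tests also live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import VelocityJumpModel, stationary_distribution, validate_model

__all__ = [
    "ObservationScheme",
    "StatePath",
    "Track",
    "sample_state_path",
    "observe_track",
    "simulate_track",
    "draw_stationary_increments",
    "draw_stationary_increment_pairs",
    "empirical_density",
    "empirical_density2",
    "conditional_increment_oracle",
    "switch_count_distribution",
]


@dataclass(frozen=True)
class ObservationScheme:
    """Data-collection model: frame interval ``dt``, noise s.d. ``sigma``,
    and number of increments ``n_increments`` (so N+1 frames, T = N*dt)."""

    dt: float
    sigma: float
    n_increments: int = 1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")
        if self.n_increments < 1:
            raise ValueError("n_increments must be a positive integer")

    @property
    def total_time(self) -> float:
        return self.n_increments * self.dt


@dataclass
class StatePath:
    """Exact continuous-time trajectory of the hidden chain.

    ``states[k]`` occupies ``[jump_times[k], jump_times[k+1])``; the last
    state runs to ``duration``.
    """

    jump_times: np.ndarray
    states: np.ndarray
    duration: float


@dataclass
class Track:
    """Discrete-time observation of one agent with simulation ground truth."""

    times: np.ndarray
    exact_positions: np.ndarray
    noisy_positions: np.ndarray
    states_at_frames: np.ndarray
    switch_counts: np.ndarray  # W^j for interval j = 1..N
    seed: int | None = field(default=None)

    @property
    def increments(self) -> np.ndarray:
        """Noisy location increments ``dy_j = y_j - y_{j-1}``."""
        return np.diff(self.noisy_positions)

    @property
    def exact_increments(self) -> np.ndarray:
        return np.diff(self.exact_positions)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_state_path(
    model: VelocityJumpModel, duration: float, seed=None
) -> StatePath:
    """Simulate the hidden CTMC exactly over ``[0, duration]``.

    The initial state is drawn from the stationary distribution; holding
    times are Exp(lambda_s) and the next state is drawn from row ``s`` of
    the embedded matrix. Generation overshoots ``duration`` by one holding
    time and truncates.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not model._validated:
        validate_model(model)
    rng = _rng(seed)
    pi = stationary_distribution(model)
    cum_p = np.cumsum(model.transition_probs, axis=1)
    jump_times = [0.0]
    states = [int(rng.choice(model.n, p=pi))]
    t = 0.0
    while t < duration:
        s = states[-1]
        t += rng.exponential(1.0 / model.rates[s])
        if t >= duration:
            break
        jump_times.append(t)
        states.append(int(np.searchsorted(cum_p[s], rng.random(), side="right")))
    return StatePath(
        jump_times=np.asarray(jump_times),
        states=np.asarray(states, dtype=np.intp),
        duration=duration,
    )


def observe_track(
    path: StatePath,
    scheme: ObservationScheme,
    velocities: np.ndarray,
    seed=None,
) -> Track:
    """Observe a state path at frame times with Gaussian noise.

    ``x_j`` is the exact piecewise-linear integral of the velocity along the
    path (no time-discretization error); ``y_j = x_j + eps_j`` with
    ``eps_j ~ N(0, sigma^2)`` i.i.d.; ``W^j`` counts jumps in the half-open
    interval ``(t_{j-1}, t_j]``.
    """
    if path.duration < scheme.total_time - 1e-12:
        raise ValueError(
            f"path duration {path.duration} shorter than {scheme.total_time}"
        )
    rng = _rng(seed)
    velocities = np.asarray(velocities, dtype=float)
    n_frames = scheme.n_increments + 1
    frame_times = np.arange(n_frames) * scheme.dt

    # positions at path nodes (jump times plus the final horizon)
    node_t = np.append(path.jump_times, path.duration)
    seg_dur = np.diff(node_t)
    node_x = np.concatenate(([0.0], np.cumsum(velocities[path.states] * seg_dur)))
    x = np.interp(frame_times, node_t, node_x)

    eps = rng.normal(0.0, scheme.sigma, size=n_frames) if scheme.sigma > 0 else 0.0
    y = x + eps

    # jumps strictly after 0: a jump exactly at a frame time belongs to the
    # earlier interval (searchsorted side="right")
    interior = path.jump_times[1:]
    counts = np.searchsorted(interior, frame_times, side="right")
    w = np.diff(counts)
    state_idx = np.searchsorted(path.jump_times, frame_times, side="right") - 1
    return Track(
        times=frame_times,
        exact_positions=x,
        noisy_positions=np.asarray(y, dtype=float) if np.ndim(y) else x.copy(),
        states_at_frames=path.states[state_idx],
        switch_counts=w,
        seed=seed if isinstance(seed, int) else None,
    )


def simulate_track(
    model: VelocityJumpModel, scheme: ObservationScheme, seed=None
) -> Track:
    """Simulate a full track: hidden path plus noisy discrete observations."""
    rng = _rng(seed)
    path = sample_state_path(model, scheme.total_time, rng)
    return observe_track(path, scheme, model.velocities, rng)


def _simulate_intervals(model, dt, reps, rng, s0=None):
    """Vectorized simulation of one interval of length dt per replicate.

    Returns (exact increments, switch counts, end states). ``s0`` gives the
    initial states; default stationary.
    """
    n = model.n
    if s0 is None:
        pi = stationary_distribution(model)
        s = rng.choice(n, size=reps, p=pi)
    else:
        s = np.array(s0, dtype=np.intp, copy=True)
    cum_p = np.cumsum(model.transition_probs, axis=1)
    x = np.zeros(reps)
    w = np.zeros(reps, dtype=np.intp)
    t_rem = np.full(reps, float(dt))
    active = np.arange(reps)
    while active.size:
        lam = model.rates[s[active]]
        tau = rng.exponential(1.0 / lam)
        jump = tau < t_rem[active]
        done = active[~jump]
        x[done] += model.velocities[s[done]] * t_rem[done]
        t_rem[done] = 0.0
        ai = active[jump]
        tj = tau[jump]
        x[ai] += model.velocities[s[ai]] * tj
        t_rem[ai] -= tj
        w[ai] += 1
        u = rng.random(ai.size)
        s[ai] = (u[:, None] <= cum_p[s[ai]]).argmax(axis=1)
        active = ai
    return x, w, s


def draw_stationary_increments(
    model: VelocityJumpModel,
    scheme: ObservationScheme,
    reps: int,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw independent stationary-start (noisy increment, switch count) pairs.

    Each draw simulates one interval ``[0, dt]`` with the initial state from
    the stationary law; the noisy increment adds ``N(0, 2 sigma^2)`` noise
    (the difference of two independent frame errors). Marginally equivalent
    in law to consecutive increments of a long stationary track.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not model._validated:
        validate_model(model)
    rng = _rng(seed)
    dx, w, _ = _simulate_intervals(model, scheme.dt, reps, rng)
    dy = dx + rng.normal(0.0, np.sqrt(2.0) * scheme.sigma, size=reps)
    return dy, w


def draw_stationary_increment_pairs(
    model: VelocityJumpModel,
    scheme: ObservationScheme,
    reps: int,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw pairs of consecutive noisy increments (dy_1, dy_2).

    Two consecutive intervals share the middle frame's noise, so
    ``dy_1 = dx_1 + e_1 - e_0`` and ``dy_2 = dx_2 + e_2 - e_1`` are
    correlated through ``e_1`` exactly as in real tracks.
    """
    if not model._validated:
        validate_model(model)
    rng = _rng(seed)
    dx1, _, s_mid = _simulate_intervals(model, scheme.dt, reps, rng)
    dx2, _, _ = _simulate_intervals(model, scheme.dt, reps, rng, s0=s_mid)
    e0, e1, e2 = rng.normal(0.0, scheme.sigma, size=(3, reps))
    return dx1 + e1 - e0, dx2 + e2 - e1


def empirical_density(
    samples: np.ndarray,
    bins: int = 200,
    grid_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram density: returns (bin centers, density values).

    Bin masses sum to one; density is mass divided by bin width.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty sample")
    hist, edges = np.histogram(samples, bins=bins, range=grid_range)
    width = np.diff(edges)
    density = hist / (samples.size * width)
    return 0.5 * (edges[:-1] + edges[1:]), density


def empirical_density2(
    samples1: np.ndarray,
    samples2: np.ndarray,
    bins: int = 100,
    grid_range=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2D normalized histogram density for increment pairs.

    Returns (centers1, centers2, density) where the density integrates to one
    over the grid.
    """
    samples1 = np.asarray(samples1, dtype=float)
    samples2 = np.asarray(samples2, dtype=float)
    if samples1.size == 0 or samples2.size == 0:
        raise ValueError("empty sample")
    hist, e1, e2 = np.histogram2d(samples1, samples2, bins=bins, range=grid_range)
    area = np.outer(np.diff(e1), np.diff(e2))
    density = hist / (samples1.size * area)
    return 0.5 * (e1[:-1] + e1[1:]), 0.5 * (e2[:-1] + e2[1:]), density


def conditional_increment_oracle(
    model: VelocityJumpModel,
    dt: float,
    s_sequence,
    w: int,
    reps: int,
    seed=None,
    max_batches: int = 10_000,
) -> np.ndarray:
    """Rejection sampler for exact increments given a state sequence.

    Conditions on exactly ``w`` switches in ``[0, dt]`` with the prescribed
    ordered state sequence (length ``w + 1``): draw holding times
    ``tau_i ~ Exp(lambda_{s_i})``, accept iff the first ``w`` sum to at most
    ``dt`` while adding the next exceeds it, and return the exact increment
    of each accepted draw. Aborts if the estimated acceptance probability
    falls below 1e-6.
    """
    s_seq = np.asarray(s_sequence, dtype=np.intp)
    if s_seq.size != w + 1:
        raise ValueError("state sequence must have length w + 1")
    if np.any(s_seq[1:] == s_seq[:-1]):
        raise ValueError("consecutive states in the sequence must differ")
    rng = _rng(seed)
    lam = model.rates[s_seq]
    vel = model.velocities[s_seq]
    out: list[np.ndarray] = []
    got = 0
    tried = 0
    batch = max(4 * reps, 10_000)
    for _ in range(max_batches):
        tau = rng.exponential(1.0 / lam, size=(batch, w + 1))
        head = tau[:, :w].sum(axis=1)
        accept = (head <= dt) & (head + tau[:, w] > dt)
        tried += batch
        taus = tau[accept]
        if taus.size:
            dx = taus[:, :w] @ vel[:w] + vel[w] * (dt - taus[:, :w].sum(axis=1))
            out.append(dx)
            got += dx.size
        if got >= reps:
            break
        if tried >= 2_000_000 and got / tried < 1e-6:
            raise RuntimeError(
                f"acceptance probability ~{got / tried:.2e} below 1e-6; aborting"
            )
    else:
        raise RuntimeError("rejection sampler did not reach the requested reps")
    return np.concatenate(out)[:reps]


def switch_count_distribution(
    model: VelocityJumpModel,
    dt: float,
    reps: int,
    seed=None,
    w_max: int = 6,
) -> dict:
    """Monte-Carlo estimate of the per-interval switch-count law P(W = w).

    Stationary-start simulation; returns the pmf for ``w = 0..w_max`` plus
    the tail mass ``P(W > w_max)``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not model._validated:
        validate_model(model)
    rng = _rng(seed)
    _, w, _ = _simulate_intervals(model, dt, reps, rng)
    pmf = np.bincount(np.minimum(w, w_max + 1), minlength=w_max + 2) / reps
    return {
        "w": np.arange(w_max + 1),
        "pmf": pmf[: w_max + 1],
        "tail": pmf[w_max + 1],
        "reps": reps,
    }
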