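"""Joint density of a sequence of noisy increments via a forward filter.

Consecutive increments are correlated because the hidden state at the end of
one frame interval is the state at the start of the next. Under the
up-to-one-switch truncation the pair (increment, next start state) given the
current start state has an explicit kernel, and the joint density of N
increments factorizes into per-step evidence terms computed by a standard
forward (filtering) recursion over the hidden start state. Noise increments
of adjacent intervals are treated as independent (their -sigma^2 covariance
is neglected), a documented bias of the approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .increment_density import (
    marginal_density,
    no_switch_weight,
    one_switch_noisy_density,
    zero_switch_density,
)
from .model import VelocityJumpModel, stationary_distribution, validate_model
from .simulate import ObservationScheme

__all__ = [
    "FilterState",
    "pairwise_interval_density",
    "pairwise_kernel",
    "forward_filter",
    "naive_product_loglik",
    "joint_pair_density",
]


@dataclass
class FilterState:
    """Filter distribution over the hidden start state of interval ``j``.

    ``state_probs[s]`` is P(start state of interval j is s | past increments)
    and ``log_evidence`` is the accumulated log joint density of the
    increments processed so far.
    """

    state_probs: np.ndarray
    log_evidence: float
    interval_index: int


def pairwise_interval_density(
    dy, s: int, u: int, model: VelocityJumpModel, scheme: ObservationScheme
):
    """Up-to-one-switch kernel P1(dy, next start state = u | start state = s).

    Staying (u == s) can only happen with zero switches; changing state
    (u != s) is attributed to exactly one switch, weighted by the embedded
    transition probability and P(W >= 1 | s).
    """
    if not 0 <= s < model.n or not 0 <= u < model.n:
        raise ValueError("invalid state index")
    w0 = no_switch_weight(model.rates[s], scheme.dt)
    if u == s:
        return zero_switch_density(dy, s, model, scheme) * w0
    if model.transition_probs[s, u] == 0.0:
        return np.zeros_like(np.asarray(dy, dtype=float)) if np.ndim(dy) else 0.0
    f1 = one_switch_noisy_density(dy, s, u, model, scheme)
    return f1 * model.transition_probs[s, u] * (1.0 - w0)


def pairwise_kernel(
    increments: np.ndarray, model: VelocityJumpModel, scheme: ObservationScheme
) -> np.ndarray:
    """Kernel tensor K[j, s, u] = pairwise density at increment j, vectorized."""
    dys = np.asarray(increments, dtype=float)
    n = model.n
    K = np.zeros((dys.size, n, n))
    for s in range(n):
        w0 = no_switch_weight(model.rates[s], scheme.dt)
        K[:, s, s] = zero_switch_density(dys, s, model, scheme) * w0
        for u in range(n):
            if u == s or model.transition_probs[s, u] == 0.0:
                continue
            K[:, s, u] = (
                one_switch_noisy_density(dys, s, u, model, scheme)
                * model.transition_probs[s, u]
                * (1.0 - w0)
            )
    return K


def forward_filter(
    increments,
    model: VelocityJumpModel,
    scheme: ObservationScheme,
    return_states: bool = True,
):
    """Forward recursion for the up-to-one-switch joint density of a track.

    Starts from the stationary law, and for each increment computes the
    evidence ``e_j = sum_{s,u} K_j[s,u] b_j[s]`` and the Bayes update
    ``b_{j+1}[u] = sum_s K_j[s,u] b_j[s] / e_j``. Returns the total log
    evidence ``sum_j log e_j`` (the approximate log joint density) and, if
    requested, the per-step filter states. Evidence is accumulated in log
    space with per-step renormalization of ``b``.
    """
    dys = np.asarray(increments, dtype=float)
    if dys.size < 1:
        raise ValueError("need at least one increment")
    if not model._validated:
        validate_model(model)
    K = pairwise_kernel(dys, model, scheme)
    b = stationary_distribution(model)
    log_ev = 0.0
    states: list[FilterState] = []
    for j in range(dys.size):
        if return_states:
            states.append(FilterState(b.copy(), log_ev, j + 1))
        m = K[j] * b[:, None]
        e = m.sum()
        if e <= 0.0 or not np.isfinite(e):
            raise FloatingPointError(
                f"zero-likelihood: evidence vanished at increment {j + 1}"
            )
        log_ev += np.log(e)
        b = m.sum(axis=0) / e
    if return_states:
        states.append(FilterState(b.copy(), log_ev, dys.size + 1))
        return log_ev, states
    return log_ev


def naive_product_loglik(
    increments, model: VelocityJumpModel, scheme: ObservationScheme
) -> float:
    """Independence baseline: sum of log marginal P1 over the increments."""
    dys = np.asarray(increments, dtype=float)
    if dys.size < 1:
        raise ValueError("need at least one increment")
    p = marginal_density(dys, model, scheme, order=1)
    if np.any(p <= 0.0):
        j = int(np.argmax(p <= 0.0))
        raise FloatingPointError(f"zero-likelihood: marginal vanished at increment {j + 1}")
    return float(np.sum(np.log(p)))


def joint_pair_density(
    grid1, grid2, model: VelocityJumpModel, scheme: ObservationScheme,
    naive: bool = False,
) -> np.ndarray:
    """Up-to-one-switch joint density surface P1(dy1, dy2) on a grid.

    P1(dy1, dy2) = sum_{s,u} pi_s K(dy1; s, u) sum_r K(dy2; u, r), with
    dy1 indexing the first axis. ``naive=True`` returns instead the
    independent-product surface P1(dy1) P1(dy2).
    """
    g1 = np.asarray(grid1, dtype=float)
    g2 = np.asarray(grid2, dtype=float)
    if not model._validated:
        validate_model(model)
    if naive:
        p1 = marginal_density(g1, model, scheme, order=1)
        p2 = marginal_density(g2, model, scheme, order=1)
        return np.outer(p1, p2)
    pi = stationary_distribution(model)
    K1 = pairwise_kernel(g1, model, scheme)  # (|g1|, s, u)
    K2 = pairwise_kernel(g2, model, scheme)  # (|g2|, u, r)
    second = K2.sum(axis=2)  # (|g2|, u)
    first = np.einsum("s,isu->iu", pi, K1)  # (|g1|, u)
    return first @ second.T
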