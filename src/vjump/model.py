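"""Model definition for the n-state velocity-jump process.

An agent moves in one dimension with a velocity prescribed by a hidden state
``s`` that evolves as a continuous-time Markov chain (CTMC): the holding time
in state ``s`` is Exp(lambda_s), after which the next state is drawn from row
``s`` of the embedded (discrete-time) transition matrix ``P``. Off-diagonal
entries of the generator are ``q_su = lambda_s * p_su`` and the diagonal is
``q_ss = -lambda_s``; the stationary law ``pi`` solves ``pi Q = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "VelocityJumpModel",
    "ModelValidationError",
    "validate_model",
    "rate_matrix",
    "stationary_distribution",
]

_ROW_SUM_TOL = 1e-12


class ModelValidationError(ValueError):
    """A velocity-jump model violates a structural invariant."""


@dataclass
class VelocityJumpModel:
    """Parameterization of an n-state one-dimensional velocity-jump model.

    Parameters
    ----------
    velocities : array-like, shape (n,)
        Velocity ``v_s`` of each state (length/time units).
    rates : array-like, shape (n,)
        Switching rate ``lambda_s`` of each state; mean holding time is
        ``1/lambda_s``. All strictly positive.
    transition_probs : array-like, shape (n, n)
        Embedded-chain matrix ``P``; ``p_su`` is the probability that the
        state after ``s`` is ``u``. Zero diagonal, rows sum to one.
    state_names : sequence of str, optional
        Labels such as ``F``, ``B``, ``SL``, ``SS``, ``PF``, ``PB``.
    """

    velocities: np.ndarray
    rates: np.ndarray
    transition_probs: np.ndarray
    state_names: list[str] | None = None
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.velocities = np.atleast_1d(np.asarray(self.velocities, dtype=float))
        self.rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        self.transition_probs = np.atleast_2d(
            np.asarray(self.transition_probs, dtype=float)
        )

    @property
    def n(self) -> int:
        """Number of states."""
        return self.velocities.shape[0]

    def name_of(self, s: int) -> str:
        if self.state_names is not None:
            return self.state_names[s]
        return str(s)


def validate_model(model: VelocityJumpModel) -> VelocityJumpModel:
    """Check every structural invariant of a velocity-jump model.

    Returns the model unchanged if valid; raises
    :class:`ModelValidationError` with a distinct diagnostic otherwise.
    The checks are: matching dimensions, strictly positive rates, zero
    diagonal of ``P``, entries in [0, 1], stochastic rows (tolerance 1e-12),
    and irreducibility (strong connectivity of the directed graph on edges
    with ``p_su > 0``).
    """
    n = model.n
    if model.rates.shape != (n,):
        raise ModelValidationError(
            f"dimension mismatch: {n} velocities but rates shape {model.rates.shape}"
        )
    if model.transition_probs.shape != (n, n):
        raise ModelValidationError(
            "dimension mismatch: transition_probs shape "
            f"{model.transition_probs.shape}, expected {(n, n)}"
        )
    if model.state_names is not None and len(model.state_names) != n:
        raise ModelValidationError(
            f"dimension mismatch: {len(model.state_names)} state names for {n} states"
        )
    if not np.all(model.rates > 0):
        bad = int(np.argmin(model.rates > 0))
        raise ModelValidationError(
            f"non-positive rate: lambda[{bad}] = {model.rates[bad]}"
        )
    P = model.transition_probs
    diag = np.diag(P)
    if np.any(diag != 0.0):
        bad = int(np.argmax(diag != 0.0))
        raise ModelValidationError(f"nonzero diagonal: p[{bad},{bad}] = {diag[bad]}")
    if np.any(P < 0) or np.any(P > 1):
        raise ModelValidationError("transition probability outside [0, 1]")
    row_sums = P.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > _ROW_SUM_TOL):
        bad = int(np.argmax(np.abs(row_sums - 1.0)))
        raise ModelValidationError(
            f"non-stochastic row: row {bad} sums to {row_sums[bad]!r}"
        )
    # strong connectivity on the boolean adjacency of strictly positive edges
    adj = csr_matrix((P > 0).astype(np.int8))
    n_comp, _ = connected_components(adj, directed=True, connection="strong")
    if n_comp != 1:
        raise ModelValidationError(
            f"reducible chain: {n_comp} strongly connected components"
        )
    model._validated = True
    return model


def rate_matrix(model: VelocityJumpModel) -> np.ndarray:
    """Generator (transition-rate matrix) ``Q`` of the CTMC.

    ``q_su = lambda_s * p_su`` for ``u != s`` and ``q_ss = -lambda_s``, so
    every row sums to zero.
    """
    Q = model.rates[:, None] * model.transition_probs
    np.fill_diagonal(Q, -model.rates)
    return Q


def stationary_distribution(model: VelocityJumpModel) -> np.ndarray:
    """Stationary law ``pi`` of the CTMC, the solution of ``pi Q = 0``.

    Computed from the kernel of ``Q^T`` by SVD: the right-singular vector of
    the smallest singular value. An irreducible chain has a one-dimensional
    kernel; if the second-smallest singular value is below ``1e-8 * ||Q||``
    the kernel is (numerically) degenerate and an error is raised.
    """
    Q = rate_matrix(model)
    _, sv, vt = np.linalg.svd(Q.T)
    if sv[0] == 0.0 or (model.n >= 2 and sv[-2] < 1e-8 * sv[0]):
        raise ModelValidationError(
            "degenerate kernel: stationary distribution is not unique"
        )
    pi = vt[-1]
    pi = pi * np.sign(pi.sum())
    if np.any(pi < -1e-12):
        raise ModelValidationError("degenerate kernel: kernel vector changes sign")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()
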