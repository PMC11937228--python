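"""Maximum-likelihood calibration of velocity-jump models from tracks.

`VelocityJumpMLE` is a scikit-learn-style estimator (fit / score /
get_params) that maximizes the forward-filter (up-to-one-switch) track
log-likelihood over velocities, switching rates, optionally the free entries
of the embedded transition matrix, and the noise s.d. sigma. `fit_mle` is a
thin functional wrapper.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .model import VelocityJumpModel, validate_model
from .simulate import ObservationScheme, Track
from .track_density import forward_filter

__all__ = ["VelocityJumpMLE", "fit_mle"]


def _as_increment_list(X, lengths=None) -> list[np.ndarray]:
    if isinstance(X, Track):
        return [X.increments]
    if isinstance(X, (list, tuple)):
        return [t.increments if isinstance(t, Track) else np.asarray(t, float) for t in X]
    X = np.asarray(X, dtype=float).ravel()
    if lengths is None:
        return [X]
    out, i = [], 0
    for ln in lengths:
        out.append(X[i : i + ln])
        i += ln
    return out


class VelocityJumpMLE(BaseEstimator):
    """Fit an n-state velocity-jump model to noisy tracking increments.

    Parameters
    ----------
    transition_probs : array-like (n, n)
        Embedded-chain topology; zero entries are structural zeros and stay
        fixed. Nonzero entries serve as initial values and, when
        ``fit_transitions=True``, rows with two or more nonzero entries are
        re-estimated via a softmax parameterization.
    dt : float
        Frame interval of the observation scheme.
    sigma : float or None
        Measurement-noise s.d.; estimated (log-parameterized) when None.
    velocities, rates : array-like or None
        Initial guesses; data-driven defaults when None.
    fix_velocities : bool
        Keep velocities at their initial values.
    fit_transitions : bool
        Also estimate the free transition probabilities.
    n_restarts : int
        Number of optimizer starts (first from the initial guess, the rest
        from seeded perturbations); multimodality across state relabelings
        makes restarts worthwhile.
    random_state : int or None
        Seed for the restart perturbations.

    Attributes
    ----------
    velocities_, rates_, transition_probs_, sigma_ : fitted parameters,
        states sorted by velocity (canonical order).
    log_likelihood_ : float
        Achieved total forward-filter log-likelihood.
    model_ : VelocityJumpModel
    converged_ : bool
    bounds_hit_ : bool
        Whether any parameter ended on its bound.
    """

    def __init__(
        self,
        transition_probs=None,
        dt: float = 1.0,
        sigma: float | None = None,
        velocities=None,
        rates=None,
        fix_velocities: bool = False,
        fit_transitions: bool = False,
        n_restarts: int = 5,
        random_state: int | None = None,
    ):
        self.transition_probs = transition_probs
        self.dt = dt
        self.sigma = sigma
        self.velocities = velocities
        self.rates = rates
        self.fix_velocities = fix_velocities
        self.fit_transitions = fit_transitions
        self.n_restarts = n_restarts
        self.random_state = random_state

    # -- parameter packing ------------------------------------------------
    def _free_rows(self, P0):
        return [s for s in range(P0.shape[0]) if (P0[s] > 0).sum() >= 2]

    def _pack(self, v, lam, P, sigma, P0):
        theta = [] if self.fix_velocities else list(v)
        theta += list(np.log(lam))
        if self.fit_transitions:
            for s in self._free_rows(P0):
                idx = np.flatnonzero(P0[s] > 0)
                w = np.log(np.maximum(P[s, idx], 1e-12))
                theta += list(w[:-1] - w[-1])
        if self.sigma is None:
            theta.append(np.log(sigma))
        return np.asarray(theta, dtype=float)

    def _unpack(self, theta, v0, P0):
        n = P0.shape[0]
        i = 0
        if self.fix_velocities:
            v = v0.copy()
        else:
            v = theta[:n].copy()
            i = n
        lam = np.exp(theta[i : i + n])
        i += n
        P = P0.copy()
        if self.fit_transitions:
            for s in self._free_rows(P0):
                idx = np.flatnonzero(P0[s] > 0)
                z = np.append(theta[i : i + idx.size - 1], 0.0)
                i += idx.size - 1
                ez = np.exp(z - z.max())
                P[s, idx] = ez / ez.sum()
        sigma = np.exp(theta[i]) if self.sigma is None else float(self.sigma)
        return v, lam, P, sigma

    # -- fitting ----------------------------------------------------------
    def fit(self, X, lengths=None):
        tracks = _as_increment_list(X, lengths)
        all_dy = np.concatenate(tracks)
        if self.transition_probs is None:
            raise ValueError("transition_probs topology is required")
        P0 = np.asarray(self.transition_probs, dtype=float)
        n = P0.shape[0]

        scale = max(np.abs(all_dy).max(), 1e-12)
        if self.velocities is not None:
            v0 = np.asarray(self.velocities, dtype=float)
        else:
            qs = np.linspace(0.05, 0.95, n)
            v0 = np.quantile(all_dy, qs) / self.dt
        lam0 = np.asarray(self.rates, float) if self.rates is not None else np.full(n, 0.1 / self.dt)
        sigma0 = float(self.sigma) if self.sigma is not None else 0.1 * scale

        n_v = 0 if self.fix_velocities else n
        bounds = []
        if not self.fix_velocities:
            bounds += [(-10 * scale / self.dt, 10 * scale / self.dt)] * n
        bounds += [(np.log(1e-4 / self.dt), np.log(100.0 / self.dt))] * n
        if self.fit_transitions:
            for s in self._free_rows(P0):
                bounds += [(-20.0, 20.0)] * (np.flatnonzero(P0[s] > 0).size - 1)
        if self.sigma is None:
            bounds += [(np.log(1e-6 * scale), np.log(10.0 * scale))]

        def neg_loglik(theta):
            v, lam, P, sigma = self._unpack(theta, v0, P0)
            try:
                model = validate_model(VelocityJumpModel(v, lam, P))
                scheme = ObservationScheme(self.dt, sigma, max(len(t) for t in tracks))
                return -sum(
                    forward_filter(t, model, scheme, return_states=False) for t in tracks
                )
            except (FloatingPointError, ValueError, np.linalg.LinAlgError):
                return 1e10

        theta0 = self._pack(v0, lam0, P0, sigma0, P0)
        rng = np.random.default_rng(self.random_state)
        best = None
        for r in range(max(1, self.n_restarts)):
            start = theta0 if r == 0 else theta0 + rng.normal(0, 0.5, theta0.size)
            start = np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds])
            res = minimize(neg_loglik, start, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res

        v, lam, P, sigma = self._unpack(best.x, v0, P0)
        order = np.argsort(v)  # canonical state order: sorted by velocity
        self.velocities_ = v[order]
        self.rates_ = lam[order]
        self.transition_probs_ = P[np.ix_(order, order)]
        self.sigma_ = sigma
        self.log_likelihood_ = -float(best.fun)
        self.model_ = validate_model(
            VelocityJumpModel(self.velocities_, self.rates_, self.transition_probs_)
        )
        self.converged_ = bool(best.success)
        atol = 1e-6
        self.bounds_hit_ = bool(
            np.any(
                [
                    min(x - lo, hi - x) < atol * max(1.0, abs(hi - lo))
                    for x, (lo, hi) in zip(best.x, bounds)
                ]
            )
        )
        self.optimizer_result_ = best
        return self

    def score(self, X, lengths=None) -> float:
        """Total forward-filter log-likelihood of X under the fitted model."""
        tracks = _as_increment_list(X, lengths)
        scheme = ObservationScheme(self.dt, self.sigma_, max(len(t) for t in tracks))
        return float(
            sum(forward_filter(t, self.model_, scheme, return_states=False) for t in tracks)
        )


def fit_mle(
    tracks,
    transition_probs,
    dt: float,
    sigma: float | None = None,
    **kwargs,
) -> dict:
    """Functional wrapper around :class:`VelocityJumpMLE`.

    Returns a dict with the fitted parameters, log-likelihood and optimizer
    diagnostics.
    """
    est = VelocityJumpMLE(transition_probs=transition_probs, dt=dt, sigma=sigma, **kwargs)
    est.fit(tracks)
    return {
        "velocities": est.velocities_,
        "rates": est.rates_,
        "transition_probs": est.transition_probs_,
        "sigma": est.sigma_,
        "log_likelihood": est.log_likelihood_,
        "converged": est.converged_,
        "bounds_hit": est.bounds_hit_,
        "estimator": est,
    }
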