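"""Analytic conditional densities of one noisy location increment.

Over one frame interval of length ``dt`` the increment ``dy`` is, conditional
on the number of state switches W and the ordered states visited, a simple
transform of the exponential holding times convolved with N(0, 2 sigma^2)
measurement noise. This module provides:

* the switch-probability weights P(W=0), P(W=1, ...), P(W>=2, ...) given the
  visited states (exponential / hypoexponential expressions);
* the conditional increment densities for zero, one and two switches, exact
  and noise-convolved (the one-switch convolution in closed exponential x
  normal-CDF form, the two-switch one by Gauss-Legendre quadrature over the
  holding-time simplex);
* the up-to-one-switch and up-to-two-switch marginal approximations
  P1(dy) and P2(dy), which treat intervals with more than m switches as if
  they had exactly m.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr
from scipy.stats import norm

from .model import VelocityJumpModel, stationary_distribution, validate_model
from .simulate import ObservationScheme

__all__ = [
    "no_switch_weight",
    "one_switch_weight",
    "two_plus_switch_weight",
    "zero_switch_density",
    "one_switch_exact_density",
    "one_switch_noisy_density",
    "two_switch_exact_density",
    "two_switch_noisy_density",
    "marginal_density",
]

# rate differences below this (times dt) switch to series/limit formulas
_RATE_TIE_TOL = 1e-8
_VEL_TIE_REL = 1e-12


def _vel_tie(v1: float, v2: float, vmax: float) -> bool:
    return abs(v1 - v2) < _VEL_TIE_REL * max(1.0, vmax)


def _expint(c: float, length) -> float:
    """Integral of exp(-c*t) for t in [0, length]; stable as c -> 0."""
    x = c * np.asarray(length, dtype=float)
    small = np.abs(x) < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        val = np.where(small, length * (1.0 - 0.5 * x), -np.expm1(-x) / np.where(c == 0, 1.0, c))
    return val if val.ndim else float(val)


def _simplex_norm(a: float, b: float, dt: float) -> float:
    """Integral of exp(-a*t1 - b*t2) over {t1, t2 > 0, t1 + t2 < dt}."""
    if abs(b * dt) > 1e-6:
        return (_expint(a, dt) - np.exp(-b * dt) * _expint(a - b, dt)) / b
    if abs(a * dt) > 1e-6:  # symmetric in (a, t1) <-> (b, t2)
        return (_expint(b, dt) - np.exp(-a * dt) * _expint(b - a, dt)) / a
    return dt * dt / 2.0 - (a + b) * dt**3 / 6.0 + (a * a + a * b + b * b) * dt**4 / 24.0


def _check_states(model: VelocityJumpModel, *states: int) -> None:
    for s in states:
        if not 0 <= s < model.n:
            raise ValueError(f"state index {s} outside 0..{model.n - 1}")


# ---------------------------------------------------------------------------
# switch-probability weights
# ---------------------------------------------------------------------------

def no_switch_weight(lambda_s: float, dt: float) -> float:
    """P(W = 0 | S1 = s) = exp(-lambda_s * dt): the holding time outlasts dt."""
    if lambda_s < 0 or dt < 0:
        raise ValueError("rate and dt must be non-negative")
    return float(np.exp(-lambda_s * dt))


def _one_switch_weight_rates(lam1: float, lam2: float, dt: float) -> float:
    if abs(lam1 - lam2) * dt < _RATE_TIE_TOL:
        lam = 0.5 * (lam1 + lam2)
        return float(lam * dt * np.exp(-lam * dt))
    return float(lam1 * (np.exp(-lam2 * dt) - np.exp(-lam1 * dt)) / (lam1 - lam2))


def one_switch_weight(s1: int, s2: int, model: VelocityJumpModel, dt: float) -> float:
    """P(W = 1 | S1 = s1, S2 = s2) = P(tau1 <= dt, tau2 > dt - tau1)."""
    if s1 == s2:
        raise ValueError("consecutive states must differ (p_ss = 0)")
    _check_states(model, s1, s2)
    return _one_switch_weight_rates(model.rates[s1], model.rates[s2], dt)


def _two_plus_weight_rates(lam1: float, lam2: float, dt: float) -> float:
    if abs(lam1 - lam2) * dt < _RATE_TIE_TOL:
        lam = 0.5 * (lam1 + lam2)
        return float(1.0 - np.exp(-lam * dt) * (1.0 + lam * dt))
    return float(
        1.0 - (lam2 * np.exp(-lam1 * dt) - lam1 * np.exp(-lam2 * dt)) / (lam2 - lam1)
    )


def two_plus_switch_weight(s1: int, s2: int, model: VelocityJumpModel, dt: float) -> float:
    """P(W >= 2 | S1 = s1, S2 = s2) = P(tau1 + tau2 <= dt).

    Hypoexponential CDF of the first two holding times; independent of the
    third state visited.
    """
    if s1 == s2:
        raise ValueError("consecutive states must differ (p_ss = 0)")
    _check_states(model, s1, s2)
    return _two_plus_weight_rates(model.rates[s1], model.rates[s2], dt)


# ---------------------------------------------------------------------------
# zero- and one-switch densities
# ---------------------------------------------------------------------------

def zero_switch_density(dy, s: int, model: VelocityJumpModel, scheme: ObservationScheme):
    """Density of dy given no switch and state s: N(v_s*dt, 2 sigma^2)."""
    _check_states(model, s)
    if scheme.sigma <= 0:
        raise ValueError("degenerate density for sigma = 0; use exact increments")
    return norm.pdf(dy, loc=model.velocities[s] * scheme.dt, scale=np.sqrt(2.0) * scheme.sigma)


def one_switch_exact_density(dx, s1: int, s2: int, model: VelocityJumpModel, dt: float):
    """Density of the exact increment dx given exactly one switch s1 -> s2.

    The switch time tau1 given one switch is a truncated exponential with
    rate lambda_1 - lambda_2 on [0, dt]; the increment
    ``dx = v1*tau1 + v2*(dt - tau1)`` is its monotone linear image, so the
    density is the change-of-variables push-forward, supported on the
    interval between ``v1*dt`` and ``v2*dt``.
    """
    if s1 == s2:
        raise ValueError("consecutive states must differ")
    _check_states(model, s1, s2)
    v1, v2 = model.velocities[s1], model.velocities[s2]
    if _vel_tie(v1, v2, np.abs(model.velocities).max()):
        raise ValueError("degenerate, use zero-switch form: v1 == v2")
    k = model.rates[s1] - model.rates[s2]
    c = v1 - v2
    t1 = (np.asarray(dx, dtype=float) - v2 * dt) / c
    norm_const = _expint(k, dt)
    inside = (t1 >= 0.0) & (t1 <= dt)
    out = np.where(inside, np.exp(-k * np.clip(t1, 0.0, dt)) / (norm_const * abs(c)), 0.0)
    return out if out.ndim else float(out)


def _logdiff_ndtr(a, b):
    """log(Phi(b) - Phi(a)) for b >= a, stable in both tails."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    flip = (a + b) > 0  # reflect to the left tail where log_ndtr is accurate
    lo = np.where(flip, -b, a)
    hi = np.where(flip, -a, b)
    log_hi = log_ndtr(hi)
    log_lo = log_ndtr(lo)
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = np.log1p(-np.exp(np.minimum(log_lo - log_hi, 0.0)))
    return log_hi + diff


def one_switch_noisy_density(
    dy, s1: int, s2: int, model: VelocityJumpModel, scheme: ObservationScheme,
    return_meta: bool = False,
):
    """Density of the noisy increment dy given one switch s1 -> s2.

    Convolution of the truncated-exponential increment density with
    N(0, 2 sigma^2), in closed form: completing the square in the switch
    time turns the integral into exponential factors times a difference of
    normal CDFs, evaluated in log space for stability. If the two states
    share a velocity the increment is deterministic and the result is the
    plain Gaussian at that velocity.
    """
    if scheme.sigma <= 0:
        raise ValueError("sigma must be positive")
    if s1 == s2:
        raise ValueError("consecutive states must differ")
    _check_states(model, s1, s2)
    dt = scheme.dt
    v1, v2 = model.velocities[s1], model.velocities[s2]
    s = np.sqrt(2.0) * scheme.sigma
    if _vel_tie(v1, v2, np.abs(model.velocities).max()):
        out = norm.pdf(dy, loc=v1 * dt, scale=s)
        return (out, {"branch": "velocity-tie-normal"}) if return_meta else out
    k = model.rates[s1] - model.rates[s2]
    c = v1 - v2
    m = np.asarray(dy, dtype=float) - v2 * dt
    # int_0^dt C exp(-k t) phi_s(m - c t) dt with C the truncation normalizer
    t_star = m / c - k * s * s / (c * c)
    log_amp = -k * m / c + k * k * s * s / (2.0 * c * c) - np.log(_expint(k, dt)) - np.log(abs(c))
    z0 = (0.0 - t_star) * abs(c) / s
    z1 = (dt - t_star) * abs(c) / s
    log_val = log_amp + _logdiff_ndtr(z0, z1)
    out = np.exp(log_val)
    out = np.where(np.isfinite(out), out, 0.0)
    out = out if out.ndim else float(out)
    return (out, {"branch": "closed-form"}) if return_meta else out


# ---------------------------------------------------------------------------
# two-switch densities
# ---------------------------------------------------------------------------

def _interval_intersect(lo, hi, slope, icpt, bound_lo, bound_hi):
    """Intersect [lo, hi] with {t : bound_lo <= slope*t + icpt <= bound_hi}.

    All arguments scalar except possibly icpt/bounds arrays; returns (lo, hi)
    arrays with lo > hi marking an empty interval.
    """
    if abs(slope) < 1e-300:
        ok = (icpt >= bound_lo) & (icpt <= bound_hi)
        lo = np.where(ok, lo, 1.0)
        hi = np.where(ok, hi, 0.0)
        return lo, hi
    t_a = (bound_lo - icpt) / slope
    t_b = (bound_hi - icpt) / slope
    t_lo = np.minimum(t_a, t_b)
    t_hi = np.maximum(t_a, t_b)
    return np.maximum(lo, t_lo), np.minimum(hi, t_hi)


def two_switch_exact_density(
    dx, s1: int, s2: int, s3: int, model: VelocityJumpModel, dt: float
):
    """Density of the exact increment dx given two switches s1 -> s2 -> s3.

    The holding-time pair (tau1, tau2) given W = 2 has density proportional
    to exp(-(l1-l3) tau1 - (l2-l3) tau2) on the simplex tau1, tau2 > 0,
    tau1 + tau2 < dt. Collapsing the Dirac constraint
    ``dx = v1 tau1 + v2 tau2 + v3 (dt - tau1 - tau2)`` onto tau2 leaves a
    one-dimensional exponential integral over the tau1 interval [E0, E1]
    obtained by intersecting the simplex with the constraint line; the
    endpoints are piecewise linear in dx and the antiderivative is explicit.
    Velocity ties (including the s3 == s1 case, where dx depends on tau2
    only) reduce to one-dimensional marginals of the same simplex density.
    The support is [v_min*dt, v_max*dt].
    """
    if s1 == s2 or s2 == s3:
        raise ValueError("consecutive states must differ")
    _check_states(model, s1, s2, s3)
    lam = model.rates
    v1, v2, v3 = (model.velocities[i] for i in (s1, s2, s3))
    vmax_abs = max(1.0, np.abs(model.velocities).max())
    a = lam[s1] - lam[s3]
    b = lam[s2] - lam[s3]
    Z = _simplex_norm(a, b, dt)
    dx = np.asarray(dx, dtype=float)
    scalar = dx.ndim == 0
    dx = np.atleast_1d(dx)
    vmin = min(v1, v2, v3) * dt
    vmax = max(v1, v2, v3) * dt
    out = np.zeros_like(dx)
    inside = (dx >= vmin) & (dx <= vmax)

    if _vel_tie(v2, v3, vmax_abs):
        if _vel_tie(v1, v2, vmax_abs):
            raise ValueError("degenerate: all three velocities equal")
        # dx depends on tau1 only: marginal of tau1 over the simplex
        t1 = (dx - v2 * dt) / (v1 - v2)
        ok = inside & (t1 >= 0.0) & (t1 <= dt)
        t1c = np.clip(t1, 0.0, dt)
        dens = np.exp(-a * t1c) * _expint(b, dt - t1c) / (Z * abs(v1 - v2))
        out[ok] = dens[ok]
    else:
        # sift in tau2: tau2(t1) = p*t1 + q with the simplex constraints
        p = (v1 - v3) / (v3 - v2)
        q = (v3 * dt - dx) / (v3 - v2)
        lo = np.zeros_like(dx)
        hi = np.full_like(dx, dt)
        # 0 <= tau2(t1)  and  tau2(t1) <= dt - t1
        lo, hi = _interval_intersect(lo, hi, p, q, 0.0, np.inf)
        lo, hi = _interval_intersect(lo, hi, p + 1.0, q, -np.inf, dt)
        beta = a + b * p
        width = np.maximum(hi - lo, 0.0)
        seg = np.exp(-beta * lo) * _expint(beta, width)
        dens = np.exp(-b * q) * seg / (Z * abs(v3 - v2))
        ok = inside & (hi > lo)
        out[ok] = dens[ok]
    return float(out[0]) if scalar else out


def _simplex_nodes(dt: float, order: int):
    """Tensor Gauss-Legendre nodes/weights mapped onto the (tau1, tau2) simplex."""
    x, w = np.polynomial.legendre.leggauss(order)
    xi = 0.5 * (x + 1.0)
    wi = 0.5 * w
    t1 = dt * xi[:, None] * np.ones(order)[None, :]
    t2 = (dt - t1) * xi[None, :]
    jac = dt * (dt - t1)  # d(t1, t2) / d(xi, eta)
    wgt = wi[:, None] * wi[None, :] * jac
    return t1.ravel(), t2.ravel(), wgt.ravel()


def two_switch_noisy_density(
    dy, s1: int, s2: int, s3: int, model: VelocityJumpModel,
    scheme: ObservationScheme, quad_order: int = 80, return_meta: bool = False,
):
    """Density of the noisy increment dy given two switches s1 -> s2 -> s3.

    Convolution of the two-switch exact density with N(0, 2 sigma^2),
    computed as the expectation of the Gaussian kernel over the smooth
    holding-time simplex density with fixed-order Gauss-Legendre quadrature
    (vectorized over the dy grid). No closed form is wired in; the branch is
    reported as "quadrature" in metadata.
    """
    if scheme.sigma <= 0:
        raise ValueError("sigma must be positive")
    if s1 == s2 or s2 == s3:
        raise ValueError("consecutive states must differ")
    _check_states(model, s1, s2, s3)
    lam = model.rates
    dt = scheme.dt
    v1, v2, v3 = (model.velocities[i] for i in (s1, s2, s3))
    a = lam[s1] - lam[s3]
    b = lam[s2] - lam[s3]
    Z = _simplex_norm(a, b, dt)
    t1, t2, wgt = _simplex_nodes(dt, quad_order)
    g = np.exp(-a * t1 - b * t2) / Z
    x_nodes = v1 * t1 + v2 * t2 + v3 * (dt - t1 - t2)
    dy = np.asarray(dy, dtype=float)
    scalar = dy.ndim == 0
    dy2 = np.atleast_1d(dy)
    s = np.sqrt(2.0) * scheme.sigma
    kern = np.exp(-0.5 * ((dy2[:, None] - x_nodes[None, :]) / s) ** 2) / (s * np.sqrt(2 * np.pi))
    out = kern @ (wgt * g)
    out = float(out[0]) if scalar else out
    return (out, {"branch": "quadrature", "quad_order": quad_order}) if return_meta else out


# ---------------------------------------------------------------------------
# marginal up-to-m-switch approximations
# ---------------------------------------------------------------------------

def marginal_density(
    dy, model: VelocityJumpModel, scheme: ObservationScheme, order: int = 1,
    quad_order: int = 80,
):
    """Up-to-m-switch approximation P_m(dy) of the increment density.

    ``order=1``: intervals with more than one switch are treated as having
    exactly one, so

        P1(dy) = sum_s pi_s [ e^{-l_s dt} f_0 + (1 - e^{-l_s dt})
                              sum_{u != s} p_su f_{s,u}(dy) ].

    ``order=2`` keeps the exact one-switch weight and adds the two-switch
    terms with the P(W >= 2) weight:

        P2(dy) = sum_s pi_s [ e^{-l_s dt} f_0
                 + sum_u p_su F_{s,u} f_{s,u}(dy)
                 + sum_u sum_{r != u} p_su p_ur H_{s,u} f_{s,u,r}(dy) ].
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    if not model._validated:
        validate_model(model)
    pi = stationary_distribution(model)
    P = model.transition_probs
    dy = np.asarray(dy, dtype=float)
    scalar = dy.ndim == 0
    dyv = np.atleast_1d(dy)
    out = np.zeros_like(dyv)
    for s in range(model.n):
        w0 = no_switch_weight(model.rates[s], scheme.dt)
        acc = w0 * zero_switch_density(dyv, s, model, scheme)
        for u in range(model.n):
            if u == s or P[s, u] == 0.0:
                continue
            f1 = one_switch_noisy_density(dyv, s, u, model, scheme)
            if order == 1:
                acc = acc + (1.0 - w0) * P[s, u] * f1
            else:
                acc = acc + one_switch_weight(s, u, model, scheme.dt) * P[s, u] * f1
                h = two_plus_switch_weight(s, u, model, scheme.dt)
                for r in range(model.n):
                    if r == u or P[u, r] == 0.0:
                        continue
                    f2 = two_switch_noisy_density(
                        dyv, s, u, r, model, scheme, quad_order=quad_order
                    )
                    acc = acc + h * P[s, u] * P[u, r] * f2
        out += pi[s] * acc
    return float(out[0]) if scalar else out
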