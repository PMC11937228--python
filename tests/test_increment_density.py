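import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import vjump.increment_density as incdens
from vjump import (
    ObservationScheme,
    VelocityJumpModel,
    conditional_increment_oracle,
    empirical_density,
    marginal_density,
    no_switch_weight,
    one_switch_exact_density,
    one_switch_noisy_density,
    one_switch_weight,
    stationary_distribution,
    two_plus_switch_weight,
    two_switch_exact_density,
    two_switch_noisy_density,
    validate_model,
    zero_switch_density,
)

rates_st = st.floats(min_value=0.01, max_value=20.0)
dt_st = st.floats(min_value=0.01, max_value=5.0)


def _model(velocities, rates):
    n = len(velocities)
    P = (np.ones((n, n)) - np.eye(n)) / (n - 1)
    return validate_model(VelocityJumpModel(velocities, rates, P))


class TestWeights:
    @pytest.mark.parametrize(
        "lam, dt, expected",
        [(1.0, 0.1, 0.9048374180), (1.0, 0.0, 1.0), (10.0, 0.1, 0.3678794412)],
    )
    def test_no_switch_values(self, lam, dt, expected):
        assert no_switch_weight(lam, dt) == pytest.approx(expected, abs=1e-9)

    def test_no_switch_rejects_negative(self):
        with pytest.raises(ValueError):
            no_switch_weight(-1.0, 0.1)

    def test_one_switch_equal_rates_is_poisson_pmf(self):
        m = _model([1.0, -1.0], [1.0, 1.0])
        assert one_switch_weight(0, 1, m, 1.0) == pytest.approx(np.exp(-1), abs=1e-12)

    def test_one_switch_against_quadrature_oracle(self):
        # defining double integral: tau1 in (0, dt], tau2 > dt - tau1
        m = _model([1.0, -1.0], [1.0, 2.0])
        dt = 1.0
        oracle = quad(
            lambda t1: 1.0 * np.exp(-1.0 * t1) * np.exp(-2.0 * (dt - t1)), 0, dt
        )[0]
        assert one_switch_weight(0, 1, m, dt) == pytest.approx(oracle, abs=1e-10)
        assert one_switch_weight(0, 1, m, dt) == pytest.approx(0.232544, abs=1e-6)

    def test_one_switch_vanishes_with_dt(self):
        m = _model([1.0, -1.0], [1.0, 2.0])
        assert one_switch_weight(0, 1, m, 1e-9) < 1e-8

    def test_two_plus_equal_rates_poisson_tail(self):
        m = _model([1.0, -1.0], [1.0, 1.0])
        assert two_plus_switch_weight(0, 1, m, 1.0) == pytest.approx(
            1 - 2 * np.exp(-1), abs=1e-12
        )

    def test_two_plus_against_quadrature_oracle(self):
        m = _model([1.0, -1.0], [1.0, 2.0])
        oracle = quad(
            lambda t1: 1.0
            * np.exp(-1.0 * t1)
            * (1 - np.exp(-2.0 * (1.0 - t1))),
            0,
            1.0,
        )[0]
        assert two_plus_switch_weight(0, 1, m, 1.0) == pytest.approx(oracle, abs=1e-10)
        assert two_plus_switch_weight(0, 1, m, 1.0) == pytest.approx(0.399576, abs=1e-6)

    def test_same_state_rejected(self):
        m = _model([1.0, -1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            one_switch_weight(1, 1, m, 1.0)
        with pytest.raises(ValueError):
            two_plus_switch_weight(0, 0, m, 1.0)

    @settings(derandomize=True, max_examples=100)
    @given(lam1=rates_st, lam2=rates_st, dt=dt_st)
    def test_weight_partition(self, lam1, lam2, dt):
        """exp(-l1 dt) + P(W=1) + P(W>=2) = 1 exactly for any rates."""
        m = _model([1.0, -1.0], [lam1, lam2])
        total = (
            no_switch_weight(lam1, dt)
            + one_switch_weight(0, 1, m, dt)
            + two_plus_switch_weight(0, 1, m, dt)
        )
        assert total == pytest.approx(1.0, abs=1e-10)


class TestZeroSwitchDensity:
    def test_peak_value(self):
        m = _model([1.0, -1.0], [1.0, 1.0])
        scheme = ObservationScheme(1.0, np.sqrt(0.005))  # 2 sigma^2 = 0.01
        assert zero_switch_density(1.0, 0, m, scheme) == pytest.approx(
            3.98942, abs=1e-5
        )

    def test_symmetry_and_normalization(self):
        m = _model([2.0, -1.0], [1.0, 1.0])
        scheme = ObservationScheme(1.0, 0.1)
        mu = 2.0
        for d in (0.05, 0.3):
            assert zero_switch_density(mu + d, 0, m, scheme) == pytest.approx(
                zero_switch_density(mu - d, 0, m, scheme), rel=1e-12
            )
        I = quad(lambda y: zero_switch_density(y, 0, m, scheme), -np.inf, np.inf)[0]
        assert I == pytest.approx(1.0, abs=1e-10)

    def test_sigma_zero_rejected(self):
        m = _model([1.0, -1.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="degenerate"):
            zero_switch_density(0.0, 0, m, ObservationScheme(1.0, 0.0))


class TestOneSwitchExact:
    def test_equal_rates_constant_density(self):
        m = _model([1.0, -1.0], [1.0, 1.0])
        xs = np.linspace(-0.99, 0.99, 21)
        assert np.allclose(one_switch_exact_density(xs, 0, 1, m, 1.0), 0.5)
        assert one_switch_exact_density(1.5, 0, 1, m, 1.0) == 0.0

    def test_normalizes(self):
        m = _model([1.0, -1.0], [1.0, 3.0])
        I = quad(lambda x: one_switch_exact_density(x, 0, 1, m, 1.0), -1, 1)[0]
        assert I == pytest.approx(1.0, abs=1e-10)

    def test_matches_rejection_oracle(self):
        m = _model([1.0, -1.0], [1.0, 3.0])
        reps = 100_000
        dx = conditional_increment_oracle(m, 1.0, [0, 1], 1, reps, seed=20)
        centers, dens = empirical_density(dx, bins=40, grid_range=(-1, 1))
        ana = one_switch_exact_density(centers, 0, 1, m, 1.0)
        width = 2.0 / 40
        se = np.sqrt(np.maximum(ana * width * (1 - ana * width), 1e-12) / reps) / width
        assert np.all(np.abs(dens - ana) < 3 * se + 1e-9)

    def test_velocity_tie_rejected(self):
        m = _model([1.0, 1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="zero-switch"):
            one_switch_exact_density(0.5, 0, 1, m, 1.0)


class TestOneSwitchNoisy:
    @pytest.mark.parametrize("lam", [(1.0, 1.0), (1.0, 3.0), (5.0, 0.3)])
    def test_closed_form_vs_quadrature(self, lam):
        """Closed form equals adaptive quadrature of the defining convolution
        on a 101-point grid spanning [a - 4 s, b + 4 s]."""
        m = _model([1.0, -1.0], list(lam))
        sigma = 0.05
        scheme = ObservationScheme(1.0, sigma)
        s = np.sqrt(2) * sigma
        grid = np.linspace(-1 - 4 * s, 1 + 4 * s, 101)
        cf = one_switch_noisy_density(grid, 0, 1, m, scheme)
        for y, v in zip(grid[::10], cf[::10]):
            q = quad(
                lambda x: one_switch_exact_density(x, 0, 1, m, 1.0)
                * np.exp(-((y - x) ** 2) / (2 * s * s))
                / (s * np.sqrt(2 * np.pi)),
                -1,
                1,
                limit=200,
            )[0]
            assert abs(v - q) < 1e-8

    def test_velocity_tie_equals_zero_switch_gaussian(self):
        m = _model([1.0, 1.0, -1.0], [1.0, 2.0, 1.0])
        scheme = ObservationScheme(1.0, 0.1)
        ys = np.linspace(0, 2, 11)
        assert np.allclose(
            one_switch_noisy_density(ys, 0, 1, m, scheme),
            zero_switch_density(ys, 0, m, scheme),
            rtol=1e-12,
        )

    def test_small_sigma_approaches_exact_density(self):
        m = _model([1.0, -1.0], [1.0, 3.0])
        span = 2.0
        scheme = ObservationScheme(1.0, 1e-4 * span / np.sqrt(2))
        mid = 0.0
        noisy = one_switch_noisy_density(mid, 0, 1, m, scheme)
        exact = one_switch_exact_density(mid, 0, 1, m, 1.0)
        assert noisy == pytest.approx(exact, rel=1e-3)

    def test_normalizes(self):
        m = _model([1.0, -1.0], [2.0, 0.5])
        scheme = ObservationScheme(1.0, 0.08)
        I = quad(
            lambda y: one_switch_noisy_density(y, 0, 1, m, scheme), -2, 2, limit=200
        )[0]
        assert I == pytest.approx(1.0, abs=1e-8)

    def test_branch_metadata(self):
        m = _model([1.0, -1.0], [1.0, 2.0])
        _, meta = one_switch_noisy_density(
            0.0, 0, 1, m, ObservationScheme(1.0, 0.05), return_meta=True
        )
        assert meta["branch"] == "closed-form"


class TestTwoSwitchExact:
    def test_support(self, three_state):
        dt = 1.0
        xs = np.array([-1.5, -1.01, 1.01, 1.5])
        assert np.all(two_switch_exact_density(xs, 0, 1, 2, three_state, dt) == 0)

    @pytest.mark.parametrize(
        "trip", [(0, 1, 2), (2, 1, 0), (1, 0, 2), (0, 1, 0), (1, 2, 1), (2, 0, 2)]
    )
    def test_normalizes(self, three_state, trip):
        I = quad(
            lambda x: two_switch_exact_density(x, *trip, three_state, 1.0),
            -1,
            1,
            limit=400,
        )[0]
        assert I == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize(
        "velocities, rates, seq",
        [
            ([1.0, 0.0, -1.0], [1.0, 1.0, 1.0], (0, 1, 2)),  # equal rates
            ([1.0, 0.0, -1.0], [1.0, 2.0, 0.5], (0, 1, 2)),  # unequal rates
            ([1.0, -1.0, 0.5], [1.0, 2.0, 0.5], (0, 1, 2)),  # sign change
            ([1.0, -1.0, 0.0], [1.0, 2.0, 0.5], (0, 1, 0)),  # s3 = s1
            ([1.0, 0.0, 0.0], [1.0, 2.0, 0.5], (1, 0, 2)),   # velocity tie v1=v3
            ([1.0, 0.0, 0.0], [1.0, 2.0, 0.5], (0, 1, 2)),   # velocity tie v2=v3
        ],
    )
    def test_matches_rejection_oracle(self, velocities, rates, seq):
        m = _model(velocities, rates)
        reps = 100_000
        dx = conditional_increment_oracle(m, 1.0, list(seq), 2, reps, seed=21)
        lo = min(velocities) * 1.0
        hi = max(velocities) * 1.0
        centers, dens = empirical_density(dx, bins=40, grid_range=(lo, hi))
        ana = two_switch_exact_density(centers, *seq, m, 1.0)
        width = (hi - lo) / 40
        se = np.sqrt(np.maximum(ana * width * (1 - ana * width), 1e-12) / reps) / width
        assert np.all(np.abs(dens - ana) < 3 * se + 1e-9)

    def test_consecutive_equal_states_rejected(self, three_state):
        with pytest.raises(ValueError):
            two_switch_exact_density(0.0, 0, 0, 1, three_state, 1.0)
        with pytest.raises(ValueError):
            two_switch_exact_density(0.0, 0, 1, 1, three_state, 1.0)


class TestTwoSwitchNoisy:
    def test_normalizes(self, three_state):
        scheme = ObservationScheme(1.0, 0.05)
        I = quad(
            lambda y: two_switch_noisy_density(float(y), 0, 1, 2, three_state, scheme),
            -2,
            2,
            limit=400,
        )[0]
        assert I == pytest.approx(1.0, abs=1e-6)

    def test_matches_defining_convolution(self, three_state):
        scheme = ObservationScheme(1.0, 0.05)
        s = np.sqrt(2) * 0.05
        for y in np.linspace(-1.2, 1.2, 9):
            q = quad(
                lambda x: two_switch_exact_density(x, 0, 1, 2, three_state, 1.0)
                * np.exp(-((y - x) ** 2) / (2 * s * s))
                / (s * np.sqrt(2 * np.pi)),
                -1,
                1,
                limit=400,
            )[0]
            v = two_switch_noisy_density(float(y), 0, 1, 2, three_state, scheme)
            assert abs(v - q) < 1e-6

    def test_large_sigma_gaussian_limit(self, three_state):
        # sigma >> support span: the convolution is dominated by the kernel
        span = 2.0
        sigma = 100.0 * span
        scheme = ObservationScheme(1.0, sigma)
        mean = quad(
            lambda x: x * two_switch_exact_density(x, 0, 1, 2, three_state, 1.0),
            -1,
            1,
            limit=400,
        )[0]
        s = np.sqrt(2) * sigma
        ys = np.linspace(-3 * s, 3 * s, 31)
        f = two_switch_noisy_density(ys, 0, 1, 2, three_state, scheme)
        gauss = np.exp(-((ys - mean) ** 2) / (2 * s * s)) / (s * np.sqrt(2 * np.pi))
        assert np.max(np.abs(f - gauss)) < 1e-3

    def test_branch_metadata(self, three_state):
        _, meta = two_switch_noisy_density(
            0.0, 0, 1, 2, three_state, ObservationScheme(1.0, 0.05), return_meta=True
        )
        assert meta["branch"] == "quadrature"


class TestMarginalDensity:
    @pytest.mark.parametrize("order", [1, 2])
    def test_normalizes(self, three_state, order):
        scheme = ObservationScheme(1.0, 0.05)
        grid = np.linspace(-1.6, 1.6, 3201)
        p = marginal_density(grid, three_state, scheme, order=order)
        assert np.trapezoid(p, grid) == pytest.approx(1.0, abs=1e-6)
        assert np.all(p >= 0)

    @pytest.mark.parametrize("order", [1, 2])
    def test_symmetric_two_state(self, two_state, order):
        scheme = ObservationScheme(1.0, 0.05)
        grid = np.linspace(0.0, 1.5, 50)
        assert np.allclose(
            marginal_density(grid, two_state, scheme, order=order),
            marginal_density(-grid, two_state, scheme, order=order),
            rtol=1e-10,
        )

    def test_invalid_order(self, two_state):
        with pytest.raises(ValueError, match="order"):
            marginal_density(0.0, two_state, ObservationScheme(1.0, 0.05), order=3)

    def test_low_rate_limit_is_gaussian_mixture(self):
        m = _model([1.0, -1.0, 0.0], [1e-4, 1e-4, 1e-4])
        scheme = ObservationScheme(1.0, 0.3)  # peaks of magnitude ~1
        pi = stationary_distribution(m)
        grid = np.linspace(-1.5, 1.5, 301)
        p1 = marginal_density(grid, m, scheme, order=1)
        mix = sum(
            pi[s] * zero_switch_density(grid, s, m, scheme) for s in range(3)
        )
        assert np.max(np.abs(p1 - mix)) < 1e-4

    def test_order2_reduces_to_order1_without_two_switch_mass(
        self, three_state, monkeypatch
    ):
        """Forcing the two-switch weight to zero (and returning its mass to
        the one-switch branch) collapses P2 onto P1."""
        scheme = ObservationScheme(1.0, 0.05)
        grid = np.linspace(-1.5, 1.5, 101)
        p1 = marginal_density(grid, three_state, scheme, order=1)
        monkeypatch.setattr(incdens, "two_plus_switch_weight", lambda *a: 0.0)
        monkeypatch.setattr(
            incdens,
            "one_switch_weight",
            lambda s1, s2, model, dt: 1.0 - np.exp(-model.rates[s1] * dt),
        )
        p2 = marginal_density(grid, three_state, scheme, order=2)
        assert np.allclose(p1, p2, atol=1e-12)

    def test_order1_tracks_empirical_at_low_rates(self, three_state):
        from vjump import draw_stationary_increments, empirical_density

        scheme = ObservationScheme(1.0, 0.05)
        low = validate_model(
            VelocityJumpModel(
                three_state.velocities,
                three_state.rates * 0.1,
                three_state.transition_probs,
            )
        )
        dy, _ = draw_stationary_increments(low, scheme, 200_000, seed=22)
        centers, dens = empirical_density(dy, bins=100, grid_range=(-1.3, 1.3))
        p1 = marginal_density(centers, low, scheme, order=1)
        width = 2.6 / 100
        assert np.sum(np.abs(p1 - dens)) * width < 0.05
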