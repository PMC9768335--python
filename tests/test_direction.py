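import numpy as np
import pytest

from ddtg.direction import (
    decide_direction,
    taylor_regression,
    wildtype_stationarity_check,
)
from ddtg.dream_io import ExpressionPanel


def pinv_fit(x, y, z, x0, y0, z0):
    """Independent minimum-norm normal-equations oracle."""
    design = np.column_stack(((x - x0) ** 2, y - y0))
    return np.linalg.pinv(design) @ (z - z0)


class TestTaylorRegression:
    def test_exact_recovery_of_coefficients(self):
        rng = np.random.default_rng(0)
        x0, y0, z0 = 2.0, 1.0, 3.0
        x = x0 + rng.uniform(-1, 1, 30)
        y = y0 + rng.normal(size=30)
        z = z0 + 3.0 * (x - x0) ** 2 + 2.0 * (y - y0)
        a, b, degenerate = taylor_regression(x, y, z, x0, y0, z0)
        assert a == pytest.approx(3.0, abs=1e-10)
        assert b == pytest.approx(2.0, abs=1e-10)
        assert not degenerate

    def test_constant_y_gives_zero_coefficient_and_flag(self):
        rng = np.random.default_rng(1)
        x = 2.0 + rng.uniform(-1, 1, 20)
        y = np.full(20, 5.0)
        z = 3.0 + 1.5 * (x - 2.0) ** 2
        a, b, degenerate = taylor_regression(x, y, z, 2.0, 5.0, 3.0)
        assert degenerate
        assert b == pytest.approx(0.0, abs=1e-10)
        assert a == pytest.approx(1.5, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x0, y0, z0 = rng.uniform(1, 5, 3)
            x = x0 + rng.uniform(-1, 1, 25)
            y = y0 + rng.normal(size=25)
            z = z0 + rng.normal(size=25)
            a, b, _ = taylor_regression(x, y, z, x0, y0, z0)
            oracle = pinv_fit(x, y, z, x0, y0, z0)
            np.testing.assert_allclose([a, b], oracle, atol=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            taylor_regression(np.ones(4), np.ones(5), np.ones(4), 0, 0, 0)


class TestDecideDirection:
    def test_collinear_construction_oriented_forward(self):
        # Y = (X-X0)^2 exactly and Z = 2Y: both designs are rank deficient;
        # the minimum-norm fits still order the cross-gains correctly
        rng = np.random.default_rng(3)
        x0 = 2.0
        x = x0 + rng.uniform(-1, 1, 30)
        y = (x - x0) ** 2
        z = 2.0 * y
        v = decide_direction(x, y, z, x0, 0.0, 0.0)
        assert v.winner == "forward"
        assert v.degenerate
        # frozen oracle values: min-norm splits z=2q over two identical
        # regressors (1, 1); reverse fit spreads y=q over (q, 2q) -> (0.2, 0.4)
        assert v.forward_coef == pytest.approx(1.0, abs=1e-9)
        assert v.reverse_coef == pytest.approx(0.4, abs=1e-9)
        oracle_f = pinv_fit(x, y, z, x0, 0.0, 0.0)
        oracle_r = pinv_fit(x, z, y, x0, 0.0, 0.0)
        assert v.forward_coef == pytest.approx(oracle_f[1], abs=1e-12)
        assert v.reverse_coef == pytest.approx(oracle_r[1], abs=1e-12)

    def test_swapped_roles_flip_verdict(self):
        rng = np.random.default_rng(4)
        x0, y0, z0 = 2.0, 1.0, 1.0
        x = x0 + rng.uniform(-1, 1, 40)
        y = y0 + 1.2 * (x - x0) ** 2 + 0.02 * rng.normal(size=40)
        z = z0 + 0.8 * (x - x0) ** 2 + 2.0 * (y - y0) + 0.02 * rng.normal(size=40)
        assert decide_direction(x, y, z, x0, y0, z0).winner == "forward"
        assert decide_direction(x, z, y, x0, z0, y0).winner == "reverse"

    def test_antisymmetry_on_random_data(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            x0, y0, z0 = rng.uniform(1, 4, 3)
            x = x0 + rng.uniform(-1, 1, 20)
            y = y0 + rng.normal(size=20)
            z = z0 + rng.normal(size=20)
            fwd = decide_direction(x, y, z, x0, y0, z0, y_index=0, z_index=1)
            rev = decide_direction(x, z, y, x0, z0, y0, y_index=1, z_index=0)
            ordered = {
                "forward": (fwd.y, fwd.z),
                "reverse": (fwd.z, fwd.y),
                "tie": None,
            }[fwd.winner]
            ordered_rev = {
                "forward": (rev.y, rev.z),
                "reverse": (rev.z, rev.y),
                "tie": None,
            }[rev.winner]
            assert ordered == ordered_rev

    def test_tie_on_symmetric_construction(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])
        v = decide_direction(x, y, y, 2.0, 0.0, 0.0)
        assert v.winner == "tie"


class TestStationarityCheck:
    def make_panel(self, response):
        # gene G6 varies across knockouts; G1 responds via `response`
        x_col = np.array([1.5, 0.5, 1.8, 0.8, 1.2, 0.0])
        wild = np.ones(6)
        ko = np.tile(wild, (6, 1))
        np.fill_diagonal(ko, 0.0)
        ko[:, 5] = x_col
        ko[:, 0] = 1.0 + response(x_col - 1.0)
        ko[0, 0] = 0.0
        return ExpressionPanel(tuple(f"G{i+1}" for i in range(6)), wild, ko)

    def test_pure_quadratic_response_flags_nothing(self):
        panel = self.make_panel(lambda dx: dx**2)
        diag = wildtype_stationarity_check(panel)
        assert diag[0] == pytest.approx(0.0, abs=1e-8)

    def test_dominant_linear_response_flagged(self, caplog):
        panel = self.make_panel(lambda dx: 0.5 * dx)
        diag = wildtype_stationarity_check(panel)
        assert diag[0] > 1.0
        assert any("linear response" in r.message for r in caplog.records)

    def test_finite_on_simulated_panel(self):
        from ddtg.simulate import SyntheticSpec, sample_network, simulate_panel

        spec = SyntheticSpec(seed=2)
        panel, _ = simulate_panel(sample_network(spec), spec)
        diag = wildtype_stationarity_check(panel)
        assert np.all(np.isfinite(diag))
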