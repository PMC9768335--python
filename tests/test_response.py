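import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import random_panel
from ddtg.response import (
    ResponseConfig,
    change_matrix,
    relative_change,
    response_matrix,
    response_strength,
    select_targets,
    sigmoid_weight,
)


class TestChangeMatrix:
    def test_hand_computed_example(self, tiny_panel):
        expected = np.array(
            [
                [-1.0, 0.0, 0.0],
                [0.0, -2.0, 3.0],
                [0.0, 2.0, -3.0],
            ]
        )
        np.testing.assert_array_equal(change_matrix(tiny_panel), expected)

    def test_null_perturbation_gives_zero_row(self, single_edge_panel):
        delta = change_matrix(single_edge_panel)
        # knockout of G3 leaves every other gene at wild type
        assert np.all(delta[2, [0, 1, 3]] == 0)


class TestRelativeChange:
    def test_identical_changes_normalise_to_one(self):
        delta = np.full((4, 1), 2.5)
        rel, denom = relative_change(delta)
        np.testing.assert_allclose(rel, 1.0)
        assert denom[0] == 2.5

    def test_hand_computed_column(self):
        # single column (0, 3, -2): signed mean 1/3 -> (0, 9, -6)
        rel, denom = relative_change(np.array([[0.0], [3.0], [-2.0]]))
        np.testing.assert_allclose(denom, [1.0 / 3.0])
        np.testing.assert_allclose(rel[:, 0], [0.0, 9.0, -6.0])

    def test_zero_mean_guard_yields_finite_output(self, caplog):
        rel, _ = relative_change(np.array([[1.0], [-1.0]]))
        assert np.all(np.isfinite(rel))
        assert any("floor" in r.message for r in caplog.records)

    def test_abs_mean_mode(self):
        rel, denom = relative_change(
            np.array([[2.0], [-2.0]]), denom_mode="abs-mean"
        )
        np.testing.assert_allclose(denom, [2.0])
        np.testing.assert_allclose(rel[:, 0], [1.0, -1.0])

    def test_square_input_excludes_self_knockout_from_mean(self):
        # 3x3 change matrix: column means over the off-diagonal rows only
        delta = np.array(
            [
                [-5.0, 1.0, 2.0],
                [0.0, -5.0, 4.0],
                [2.0, 3.0, -5.0],
            ]
        )
        _, denom = relative_change(delta)
        np.testing.assert_allclose(denom, [1.0, 2.0, 3.0])


class TestSigmoidWeight:
    def test_midpoint_is_half(self):
        assert sigmoid_weight(0.5, r=-10, u=0.5) == pytest.approx(0.5)

    def test_closed_form_value(self):
        # w = 1 / (1 + e^{-1})
        assert sigmoid_weight(0.6, r=-10, u=0.5) == pytest.approx(
            0.7310585786300049, abs=1e-12
        )

    def test_weak_response_below_half(self):
        assert sigmoid_weight(0.0, r=-10, u=0.5) < 0.5

    @given(
        b1=st.floats(0.0, 2.0),
        b2=st.floats(0.0, 2.0),
        r=st.integers(-12, -1),
        u=st.floats(0.05, 0.95),
    )
    def test_strictly_increasing_and_bounded(self, b1, b2, r, u):
        w1, w2 = sigmoid_weight(b1, r, u), sigmoid_weight(b2, r, u)
        assert 0.0 < w1 < 1.0
        if b2 - b1 > 1e-3:
            assert w1 < w2


class TestResponseStrength:
    def test_excludes_self_knockout_row(self, single_edge_panel):
        b = response_strength(single_edge_panel)
        # G2's only off-diagonal response is the drop from 4 to 2 -> 0.5
        assert b[1] == pytest.approx(0.5)
        # G3 responds to nothing but its own deletion
        assert b[2] == 0.0

    def test_signed_mode_takes_largest_signed_ratio(self, single_edge_panel):
        # G2 only drops (to half) -> the signed maximum over the zero
        # responses is 0: a pure repression scores nothing in signed mode,
        # which is why absolute mode is the default
        b = response_strength(single_edge_panel, b_mode="signed")
        assert b[1] == pytest.approx(0.0)
        # a rising response keeps its positive ratio
        ko = single_edge_panel.knockout.copy()
        ko[0, 2] = 9.0  # G3 rises from 6 to 9 when G1 is deleted
        from ddtg.dream_io import ExpressionPanel

        panel = ExpressionPanel(
            single_edge_panel.gene_names, single_edge_panel.wild_type, ko
        )
        assert response_strength(panel, b_mode="signed")[2] == pytest.approx(0.5)


class TestResponseMatrix:
    def test_composes_stages(self, tiny_panel):
        cfg = ResponseConfig()
        rm = response_matrix(tiny_panel, cfg)
        delta = tiny_panel.knockout - tiny_panel.wild_type
        # independent step-by-step recomputation
        mask = ~np.eye(3, dtype=bool)
        denom = np.where(
            np.abs((delta * mask).sum(0) / 2) < cfg.eps,
            cfg.eps,
            (delta * mask).sum(0) / 2,
        )
        b = np.max(np.abs(delta / tiny_panel.wild_type) * mask, axis=0)
        w = 1.0 / (1.0 + np.exp(cfg.r * (b - cfg.u)))
        np.testing.assert_allclose(rm.b, b)
        np.testing.assert_allclose(rm.w, w)
        np.testing.assert_allclose(rm.S, delta / denom * w, atol=1e-12)

    def test_unperturbing_regulator_has_no_targets(self, single_edge_panel):
        rm = response_matrix(single_edge_panel)
        for i in (1, 2, 3):  # only G1's knockout changes anything
            assert select_targets(rm, i, 1.0) == []

    def test_scale_equivariance(self):
        # scaling a gene's column and wild type together leaves S unchanged
        rng = np.random.default_rng(11)
        panel = random_panel(rng, n=5)
        rm = response_matrix(panel)
        c = 7.3
        wild = panel.wild_type.copy()
        ko = panel.knockout.copy()
        wild[2] *= c
        ko[:, 2] *= c
        scaled = type(panel)(panel.gene_names, wild, ko)
        rm2 = response_matrix(scaled)
        np.testing.assert_allclose(rm2.S, rm.S, rtol=1e-9)
        np.testing.assert_allclose(rm2.b, rm.b, rtol=1e-9)


class TestSelectTargets:
    def test_ordered_by_absolute_response(self):
        from ddtg.response import ResponseMatrix

        S = np.array(
            [
                [9.0, 2.0, -3.0, 0.5],
                [0.0, 9.0, 0.0, 0.0],
                [0.0, 0.0, 9.0, 0.0],
                [0.0, 0.0, 0.0, 9.0],
            ]
        )
        rm = ResponseMatrix(
            gene_names=("G1", "G2", "G3", "G4"),
            S=S,
            delta=S,
            mean_change=np.ones(4),
            b=np.ones(4),
            w=np.ones(4) * 0.5,
        )
        assert select_targets(rm, 0, 1.0) == [2, 1]
        assert select_targets(rm, 0, 5.0) == []
        assert select_targets(rm, 0, 0.0) == [2, 1, 3]

    def test_monotone_shrinking_in_threshold(self):
        rng = np.random.default_rng(3)
        panel = random_panel(rng, n=6)
        rm = response_matrix(panel)
        prev = None
        for theta in (0.0, 0.5, 1.0, 2.0, 5.0):
            cur = set(select_targets(rm, 0, theta))
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_out_of_range_regulator(self, tiny_panel):
        rm = response_matrix(tiny_panel)
        with pytest.raises(IndexError):
            select_targets(rm, 5, 1.0)


class TestResponseConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"r": 1.0},
            {"u": 1.5},
            {"theta0": -0.1},
            {"denom_mode": "median"},
            {"b_mode": "rms"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ResponseConfig(**kwargs)
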