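"""Projection, Z-scores, bins, weighted sub-scores and the 1-10 scale."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from skiscore.errors import (
    DegenerateModelError,
    DimensionError,
    MissingCellError,
    ValidationError,
)
from skiscore.scoring import (
    bin_z,
    pc_contributions,
    project,
    scale_score,
    score_run,
    score_turn,
    turn_percentage,
    variable_subscore,
    zscore,
)
from skiscore.evaluation import skewness
from skiscore.synthetic import generate_cohort
from skiscore.types import EnrichedTurn, SyntheticParams, VariableModel, VARIABLES


@pytest.fixture
def vm(rng):
    q, _ = np.linalg.qr(rng.normal(size=(101, 3)))
    return VariableModel(mean_curve=rng.normal(size=101), loadings=q.T,
                         varfrac=np.array([0.7, 0.22, 0.05]),
                         score_sd=np.array([2.0, 1.0, 0.5]), n_ref=50)


def _mean_turn(model, cell_style, size, style=None, **kw):
    return EnrichedTurn(
        edge_angle=model.cells[(cell_style, size, "edge_angle")].mean_curve,
        symmetry=model.cells[(cell_style, size, "symmetry")].mean_curve,
        radial_force=model.cells[(cell_style, size, "radial_force")].mean_curve,
        speed=np.maximum(model.cells[(cell_style, size, "speed")].mean_curve, 0),
        style=style or cell_style, size=size, **kw)


class TestProject:
    def test_mean_curve_projects_to_zero(self, vm):
        np.testing.assert_allclose(project(vm.mean_curve, vm), 0.0, atol=1e-12)

    def test_offset_along_loading_recovered(self, vm):
        scores = project(vm.mean_curve + 2.0 * vm.loadings[0], vm)
        np.testing.assert_allclose(scores, [2.0, 0.0, 0.0], atol=1e-10)

    def test_matches_dot_product_oracle(self, vm, rng):
        x = rng.normal(size=101)
        oracle = [float(np.dot(x - vm.mean_curve, vm.loadings[k]))
                  for k in range(3)]
        np.testing.assert_allclose(project(x, vm), oracle, atol=1e-12)

    def test_wrong_length_rejected(self, vm):
        with pytest.raises(DimensionError):
            project(np.zeros(100), vm)


class TestZscore:
    def test_zero_scores(self, vm):
        np.testing.assert_allclose(zscore(np.zeros(3), vm), 0.0)

    def test_absolute_scaling(self, vm):
        z = zscore(np.array([3.0, -1.5, 0.25]), vm)
        np.testing.assert_allclose(z, [1.5, 1.5, 0.5])

    def test_zero_varfrac_component_gets_zero_z(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(101, 3)))
        vm = VariableModel(mean_curve=np.zeros(101), loadings=q.T,
                           varfrac=np.array([0.9, 0.0, 0.0]),
                           score_sd=np.array([1.0, 1.0, 1.0]),
                           n_ref=20, n_effective=1)
        np.testing.assert_allclose(zscore(np.array([1.0, 5.0, 5.0]), vm),
                                   [1.0, 0.0, 0.0])


class TestBinZ:
    @pytest.mark.parametrize("z,expected", [
        (0.0, 4), (0.5, 4), (0.749, 4),
        (0.75, 3), (1.0, 3), (1.49, 3),
        (1.5, 2), (2.9, 2),
        (3.0, 1), (3.5, 1), (100.0, 1)])
    def test_bin_rule(self, z, expected):
        assert bin_z(z) == expected

    def test_negative_z_rejected(self):
        with pytest.raises(ValidationError):
            bin_z(-0.1)

    @given(st.floats(min_value=0, max_value=10),
           st.floats(min_value=0, max_value=10))
    @settings(max_examples=100, deadline=None)
    def test_monotone_non_increasing(self, a, b):
        lo, hi = sorted((a, b))
        assert bin_z(lo) >= bin_z(hi)


class TestVariableSubscore:
    def test_worked_example_perfect_bins(self):
        """Perfect bin 4 on PCs explaining 70/22/5 % of variance."""
        contrib = pc_contributions([4, 4, 4], [0.70, 0.22, 0.05])
        assert contrib[1] == pytest.approx(0.88, abs=1e-12)
        assert variable_subscore([4, 4, 4], [0.70, 0.22, 0.05]) == \
            pytest.approx(2.8 + 0.88 + 0.2, abs=1e-12)

    def test_full_varfrac_maximum_is_four(self):
        assert variable_subscore([4, 4, 4], [0.6, 0.3, 0.1]) == \
            pytest.approx(4.0)

    def test_minimum_bins(self):
        assert variable_subscore([1, 1, 1], [0.5, 0.3, 0.2]) == \
            pytest.approx(1.0)

    def test_invalid_bins_rejected(self):
        with pytest.raises(ValidationError):
            variable_subscore([0, 4, 4], [0.5, 0.3, 0.2])


class TestTurnPercentage:
    @staticmethod
    def _uniform(bins_value, varfrac=(0.7, 0.2, 0.05)):
        subs = {v: variable_subscore([bins_value] * 3, varfrac)
                for v in VARIABLES}
        fracs = {v: np.array(varfrac) for v in VARIABLES}
        return turn_percentage(subs, fracs)

    def test_all_bins_four_is_hundred(self):
        assert self._uniform(4) == pytest.approx(100.0)

    def test_all_bins_one_is_twenty_five(self):
        assert self._uniform(1) == pytest.approx(25.0)

    def test_mixed_case_matches_hand_computation(self):
        varfrac = np.array([0.6, 0.25, 0.1])
        subs, fracs = {}, {}
        bins = {"edge_angle": [4, 3, 2], "symmetry": [3, 3, 3],
                "radial_force": [4, 4, 1], "speed": [2, 1, 4]}
        for v in VARIABLES:
            subs[v] = variable_subscore(bins[v], varfrac)
            fracs[v] = varfrac
        total = sum(np.dot(bins[v], varfrac) for v in VARIABLES)
        expected = 100.0 * total / (4 * 4 * varfrac.sum())
        assert turn_percentage(subs, fracs) == pytest.approx(expected,
                                                             abs=1e-12)

    def test_missing_variable_named(self):
        subs = {v: 1.0 for v in VARIABLES if v != "speed"}
        fracs = {v: np.array([0.7, 0.2, 0.1]) for v in VARIABLES}
        with pytest.raises(ValidationError, match="speed"):
            turn_percentage(subs, fracs)


class TestScaleScore:
    @pytest.mark.parametrize("pct,style,expected", [
        (100.0, "carving", 10.0), (0.0, "carving", 7.0),
        (100.0, "drifting", 6.0), (0.0, "drifting", 3.0),
        (50.0, "carving", 8.5)])
    def test_band_mapping(self, pct, style, expected):
        score, flags = scale_score(pct, style)
        assert score == pytest.approx(expected)
        assert flags == ()

    def test_snowplow_constants(self):
        assert scale_score(0.0, "snowplow")[0] == 1.0
        assert scale_score(100.0, "snowplow_steering")[0] == 2.0

    def test_non_parallel_uses_drifting_band_with_flag(self):
        score, flags = scale_score(50.0, "non_parallel")
        assert score == pytest.approx(4.5)
        assert "non_parallel_scored_as_drifting" in flags

    def test_unknown_style_rejected(self):
        with pytest.raises(ValidationError):
            scale_score(50.0, "freestyle")

    @given(st.floats(min_value=25, max_value=100))
    @settings(max_examples=50, deadline=None)
    def test_band_containment(self, pct):
        assert 7.75 <= scale_score(pct, "carving")[0] <= 10.0
        assert 3.75 <= scale_score(pct, "drifting")[0] <= 6.0


class TestScoreTurn:
    def test_reference_mean_turn_scores_ten(self, reference_model):
        turn = _mean_turn(reference_model, "carving", "medium")
        ts = score_turn(turn, reference_model)
        assert ts.final_score == pytest.approx(10.0)
        assert ts.percentage == pytest.approx(100.0)
        for var in VARIABLES:
            np.testing.assert_allclose(ts.z[var], 0.0, atol=1e-9)
            assert list(ts.bins[var]) == [4, 4, 4]

    def test_mean_turn_labelled_drifting_scores_six(self, reference_model):
        turn = _mean_turn(reference_model, "drifting", "medium")
        assert score_turn(turn, reference_model).final_score == \
            pytest.approx(6.0)

    def test_snowplow_constant_score(self, reference_model):
        turn = _mean_turn(reference_model, "carving", "medium",
                          style="snowplow")
        ts = score_turn(turn, reference_model)
        assert ts.final_score == 1.0 and ts.percentage is None

    def test_known_offsets_match_hand_composed_oracle(self, reference_model):
        """Push the edge angle 2 SD out on PC1: hand-compose the result."""
        style, size = "carving", "medium"
        vm = reference_model.cells[(style, size, "edge_angle")]
        turn = _mean_turn(reference_model, style, size)
        turn.edge_angle = vm.mean_curve + 2.0 * vm.score_sd[0] * vm.loadings[0]
        ts = score_turn(turn, reference_model)
        np.testing.assert_allclose(ts.z["edge_angle"], [2.0, 0, 0], atol=1e-8)
        assert list(ts.bins["edge_angle"]) == [2, 4, 4]
        sub = 2 * vm.varfrac[0] + 4 * (vm.varfrac[1] + vm.varfrac[2])
        assert ts.subscores["edge_angle"] == pytest.approx(sub)
        maximum = sum(4 * reference_model.cells[(style, size, v)].varfrac.sum()
                      for v in VARIABLES)
        others = sum(4 * reference_model.cells[(style, size, v)].varfrac.sum()
                     for v in VARIABLES if v != "edge_angle")
        expect_pct = 100 * (sub + others) / maximum
        assert ts.percentage == pytest.approx(expect_pct)
        assert ts.final_score == pytest.approx(7 + 3 * expect_pct / 100)

    def test_opposite_deviations_score_identically(self, reference_model):
        """+delta and -delta along a loading are equally far from the reference."""
        vm = reference_model.cells[("carving", "medium", "radial_force")]
        up = _mean_turn(reference_model, "carving", "medium")
        dn = _mean_turn(reference_model, "carving", "medium")
        delta = 1.3 * vm.score_sd[1] * vm.loadings[1]
        up.radial_force = vm.mean_curve + delta
        dn.radial_force = vm.mean_curve - delta
        assert score_turn(up, reference_model).final_score == \
            pytest.approx(score_turn(dn, reference_model).final_score)

    def test_increasing_one_z_never_raises_score(self, reference_model):
        vm = reference_model.cells[("carving", "medium", "speed")]
        finals = []
        for z in (0.0, 0.5, 1.0, 2.0, 3.5):
            turn = _mean_turn(reference_model, "carving", "medium")
            turn.speed = np.maximum(
                vm.mean_curve + z * vm.score_sd[0] * vm.loadings[0], 0)
            finals.append(score_turn(turn, reference_model).final_score)
        assert all(a >= b for a, b in zip(finals, finals[1:]))

    def test_missing_cell_strict_raises_batch_reports(self, reference_model):
        turn = _mean_turn(reference_model, "carving", "medium")
        turn.size = "large"
        with pytest.raises(MissingCellError):
            score_turn(turn, reference_model)
        ts = score_turn(turn, reference_model, strict=False)
        assert not ts.scorable and "large" in ts.reason

    def test_degenerate_model_rejected(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(101, 3)))
        with pytest.raises(DegenerateModelError):
            vm = VariableModel.__new__(VariableModel)
            vm.mean_curve = np.zeros(101)
            vm.loadings = q.T
            vm.varfrac = np.array([0.9, 0.05, 0.01])
            vm.score_sd = np.array([1.0, 0.0, 1.0])
            zscore(np.ones(3), vm)


class TestScoreRun:
    def test_identical_perfect_turns(self, reference_model):
        turns = [_mean_turn(reference_model, "carving", "medium")
                 for _ in range(5)]
        scores, summary = score_run(turns, reference_model)
        assert summary["mean_score"] == pytest.approx(10.0)
        assert summary["median_score"] == pytest.approx(10.0)
        assert summary["n_scored"] == 5

    def test_mixed_styles_summarised_over_final_scores(self, reference_model):
        turns = [_mean_turn(reference_model, "carving", "medium"),
                 _mean_turn(reference_model, "drifting", "medium"),
                 _mean_turn(reference_model, "carving", "medium",
                            style="snowplow")]
        _, summary = score_run(turns, reference_model)
        assert summary["mean_score"] == pytest.approx((10 + 6 + 1) / 3)
        assert summary["median_score"] == pytest.approx(6.0)

    def test_no_scorable_turns_reports_reasons(self, reference_model):
        turn = _mean_turn(reference_model, "carving", "medium")
        turn.size = "small"
        scores, summary = score_run([turn], reference_model)
        assert summary["n_scored"] == 0
        assert summary["mean_score"] is None
        assert summary["reasons"]

    def test_reference_cohort_scores_skew_to_band_top(self, default_params,
                                                      reference_model):
        turns, _ = generate_cohort(default_params, 200,
                                   [("carving", "medium")], seed=99)
        scores, _ = score_run(turns, reference_model)
        finals = [s.final_score for s in scores]
        assert np.mean(finals) > 9.0
        assert skewness(finals) < 0  # piled against the top of the band
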