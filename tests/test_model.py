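"""Unit tests for the closed-form resistance model."""

import math

import pytest

from preresist import (
    ModelParameters,
    ParameterError,
    TumorGeometry,
    combine_lesion_probabilities,
    diameter_for_probability,
    effective_division_factor,
    estimate_for_diameter,
    expected_resistant_fraction,
    prob_double_resistance,
    prob_preexisting_resistance,
    stem_cells,
    total_cells,
)


class TestCellCounts:
    @pytest.mark.parametrize(
        "diameter, expected",
        [
            (2.0, (math.pi / 6) * 8 * 5e8),     # 2.0944e9
            (0.0, 0.0),
            (6.0, (math.pi / 6) * 216 * 5e8),   # 5.6549e10
        ],
    )
    def test_total_cells_sphere(self, diameter, expected, geometry_template):
        assert total_cells(geometry_template.with_diameter(diameter)) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "diameter, expected",
        [(2.0, 1.2985250e7), (6.0, 3.5060174e8)],
    )
    def test_stem_cells_defaults(self, diameter, expected, geometry_template):
        assert stem_cells(geometry_template.with_diameter(diameter)) == pytest.approx(expected, rel=1e-6)

    def test_stem_fraction_one_is_identity(self):
        geo = TumorGeometry(diameter_cm=3.0, stem_fraction=1.0)
        assert stem_cells(geo) == total_cells(geo)

    def test_negative_diameter_rejected(self):
        with pytest.raises(ParameterError, match="diameter"):
            TumorGeometry(diameter_cm=-1.0)


class TestDivisionFactor:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(a=0.0, b=0.0, d=0.0, l=1.0), 1.0),
            (dict(a=0.0, b=0.0, d=0.5, l=1.0), 2.0 * math.log(2.0)),
            (dict(a=0.5, b=0.0, d=0.0, l=1.0), 1.5),  # analytic limit (1-a/2)/(1-a)
        ],
    )
    def test_known_values(self, kwargs, expected):
        assert effective_division_factor(ModelParameters(**kwargs)) == pytest.approx(expected, rel=1e-12)

    def test_limit_continuous_at_switch(self):
        """The d -> 0 analytic limit matches the raw expression just above the
        switch threshold."""
        below = effective_division_factor(ModelParameters(a=0.3, d=1e-13))
        above = effective_division_factor(ModelParameters(a=0.3, d=1e-9))
        assert below == pytest.approx(above, rel=1e-6)

    def test_rate_scale_invariance(self):
        """F depends on rates only through d/l."""
        f1 = effective_division_factor(ModelParameters(l=1.0, d=0.25, b=0.1))
        f2 = effective_division_factor(ModelParameters(l=7.0, d=1.75, b=0.1))
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_subcritical_rejected_naming_constraint(self):
        with pytest.raises(ParameterError, match="supercritical"):
            ModelParameters(d=1.5, l=1.0)
        with pytest.raises(ParameterError, match="a \\+ 2b"):
            ModelParameters(a=0.5, b=0.3)


class TestProbability:
    @pytest.mark.parametrize(
        "u, n_stem, expected, tol",
        [
            (1e-8, 1.2985250e7, 0.1217750, 1e-5),  # 2 cm worked example
            (1e-8, 3.5060174e8, 0.9699838, 1e-5),  # 6 cm worked example
            (0.0, 1e12, 0.0, 0.0),
        ],
    )
    def test_prob_preexisting(self, u, n_stem, expected, tol):
        p = prob_preexisting_resistance(ModelParameters(u=u), n_stem)
        assert p == pytest.approx(expected, abs=tol)

    def test_published_anchor_rounding(self, default_params, geometry_template):
        p2 = estimate_for_diameter(default_params, geometry_template.with_diameter(2.0)).p_resistance
        p6 = estimate_for_diameter(default_params, geometry_template.with_diameter(6.0)).p_resistance
        assert round(p2, 2) == 0.12
        assert round(p6, 2) == 0.97

    def test_negative_stem_count_rejected(self, default_params):
        with pytest.raises(ParameterError):
            prob_preexisting_resistance(default_params, -1.0)


class TestEstimateRecord:
    def test_record_internally_consistent(self, default_params, geometry_template):
        est = estimate_for_diameter(default_params, geometry_template.with_diameter(7.0))
        assert est.p_resistance == pytest.approx(-math.expm1(-est.expected_resistant_lineages), rel=1e-15)
        assert est.stem_cells == pytest.approx(est.total_cells * 6.2e-3, rel=1e-12)
        assert est.p_resistance == pytest.approx(0.99618, abs=5e-5)

    def test_zero_diameter_record(self, default_params, geometry_template):
        est = estimate_for_diameter(default_params, geometry_template.with_diameter(0.0))
        assert est.total_cells == est.stem_cells == est.expected_resistant_lineages == 0.0
        assert est.p_resistance == 0.0

    def test_to_dict_headers(self, default_params, geometry_template):
        d = estimate_for_diameter(default_params, geometry_template.with_diameter(2.0)).to_dict()
        assert list(d) == ["diameter_cm", "total_cells", "stem_cells",
                           "division_factor", "lambda", "p_resistance", "resistant_fraction"]


class TestResistantFraction:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(u=1e-8), 1e-8),                                   # 1 per 1e8 cells
            (dict(u=0.0), 0.0),
            (dict(u=1e-8, d=0.5, l=1.0), 2e-8 * math.log(2.0)),     # u * 2 ln 2
        ],
    )
    def test_fraction_is_u_times_factor(self, kwargs, expected):
        assert expected_resistant_fraction(ModelParameters(**kwargs)) == pytest.approx(expected, rel=1e-12)


class TestDoubleResistance:
    def test_large_tumor_value(self, default_params, geometry_template):
        n_stem = stem_cells(geometry_template.with_diameter(40.0))
        p = prob_double_resistance(default_params, 1e-8, n_stem)
        assert p == pytest.approx(1.03881e-5, rel=1e-4)

    def test_zero_second_rate(self, default_params):
        assert prob_double_resistance(default_params, 0.0, 1e12) == 0.0

    def test_bounded_by_single_drug_probability(self, geometry_template):
        for d_cm in (1.0, 5.0, 20.0, 40.0):
            n_stem = stem_cells(geometry_template.with_diameter(d_cm))
            for u, u2 in [(1e-8, 1e-8), (1e-7, 1e-9), (1e-6, 1e-8)]:
                params = ModelParameters(u=u)
                p_both = prob_double_resistance(params, u2, n_stem)
                p_min = prob_preexisting_resistance(ModelParameters(u=min(u, u2)), n_stem)
                assert p_both <= p_min


class TestInverseDiameter:
    def test_half_probability_diameter(self, default_params, geometry_template):
        d = diameter_for_probability(default_params, geometry_template, 0.5)
        assert d == pytest.approx(3.4953316, rel=1e-6)

    def test_zero_target(self, default_params, geometry_template):
        assert diameter_for_probability(default_params, geometry_template, 0.0) == 0.0

    def test_round_trip_of_worked_example(self, default_params, geometry_template):
        p2 = estimate_for_diameter(default_params, geometry_template.with_diameter(2.0)).p_resistance
        assert diameter_for_probability(default_params, geometry_template, p2) == pytest.approx(2.0, rel=1e-9)

    def test_bisection_agrees_with_closed_form(self, geometry_template):
        params = ModelParameters(u=3e-8, d=0.4, b=0.05, a=0.1)
        for p in (0.05, 0.5, 0.99):
            d_b = diameter_for_probability(params, geometry_template, p, method="bisect")
            d_c = diameter_for_probability(params, geometry_template, p, method="closed_form")
            assert d_b == pytest.approx(d_c, rel=1e-9)

    def test_unreachable_target_rejected(self, default_params, geometry_template):
        with pytest.raises(ParameterError, match="unreachable"):
            diameter_for_probability(default_params, geometry_template, 1.0)
        with pytest.raises(ParameterError, match="unreachable"):
            diameter_for_probability(ModelParameters(u=0.0), geometry_template, 0.5)


class TestMultiLesion:
    def test_combination_rule(self):
        ps = [0.1, 0.2, 0.5]
        expected = 1 - (0.9 * 0.8 * 0.5)
        assert combine_lesion_probabilities(ps) == pytest.approx(expected, rel=1e-12)

    def test_single_lesion_identity_and_certainty(self):
        assert combine_lesion_probabilities([0.37]) == pytest.approx(0.37)
        assert combine_lesion_probabilities([0.2, 1.0]) == 1.0


@pytest.mark.parametrize(
    "kwargs",
    [dict(u=-0.1), dict(u=1.0), dict(l=0.0), dict(d=-0.1),
     dict(a=-0.1), dict(b=0.5), dict(limit_threshold=0.0)],
)
def test_invalid_parameters_rejected(kwargs):
    with pytest.raises(ParameterError):
        ModelParameters(**kwargs)
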