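import numpy as np
import pytest

from iodose import (
    ThyroidCoefficients,
    build_icrp_iodine_model,
    riu,
    tiac,
    tiac_by_quadrature,
    whole_body_decays,
)
from iodose.compartments import Compartment, CompartmentModel, INTRAVENOUS
from iodose.errors import ConfigurationError, ValidationError
from iodose.kinetics import assemble_matrix, solve_activities
from iodose.nuclides import build_decay_chain, get_nuclide
from iodose.units import LN2

from conftest import random_linear_model, rk4


def single_compartment_model():
    return CompartmentModel(
        name="single",
        compartments=(Compartment("pool", "other", True),),
        transfers={},
        route_entry={INTRAVENOUS: "pool"},
    )


def two_compartment_chain_model(k):
    return CompartmentModel(
        name="ab",
        compartments=(
            Compartment("a", "other", True),
            Compartment("b", "other", True),
        ),
        transfers={("a", "b"): k},
        route_entry={INTRAVENOUS: "a"},
    )


class TestAssembly:
    def test_dimensions_single_member(self):
        model = two_compartment_chain_model(1.0)
        chain = build_decay_chain("I-131")[:1]
        state = assemble_matrix(model, chain, "intravenous")
        assert state.matrix.shape == (2, 2)

    def test_dimensions_with_progeny_blocks(self, normal_model):
        chain = build_decay_chain("I-131")
        state = assemble_matrix(normal_model, chain, "intravenous")
        assert len(chain) == 2
        assert state.matrix.shape == (60, 60)
        # ingrowth couples the parent block into the progeny block
        n = normal_model.n_compartments
        ingrowth = state.matrix[n:, :n]
        lam = get_nuclide("I-131").decay_constant
        np.testing.assert_allclose(ingrowth, 0.0118 * lam * np.eye(n), rtol=1e-12)

    def test_unsupported_route_is_a_configuration_error(self):
        model = two_compartment_chain_model(1.0)
        with pytest.raises(ConfigurationError, match="oral"):
            assemble_matrix(model, build_decay_chain("I-131")[:1], "oral")


class TestClosedForms:
    def test_decay_only_exponential(self):
        chain = build_decay_chain("I-131")[:1]
        lam = chain[0][0].decay_constant
        state = assemble_matrix(single_compartment_model(), chain, "intravenous")
        t_h = np.array([0.0, 12.0, 24.0, 96.0, 192.0])
        got = solve_activities(state, t_h).fraction("pool")
        np.testing.assert_allclose(got, np.exp(-lam * t_h / 24.0), rtol=1e-12)

    def test_transfer_fills_downstream_compartment(self):
        k = 0.7
        state = assemble_matrix(
            two_compartment_chain_model(k),
            build_decay_chain("I-131")[:1],
            "intravenous",
            include_decay=False,
        )
        t_h = np.array([6.0, 24.0, 120.0])
        got = solve_activities(state, t_h).fraction("b")
        np.testing.assert_allclose(got, 1.0 - np.exp(-k * t_h / 24.0), rtol=1e-10)


class TestSolverProperties:
    def test_matches_rk4_oracle_on_random_models(self):
        rng = np.random.default_rng(1234)
        chain = build_decay_chain("I-131")[:1]
        for _ in range(5):
            model = random_linear_model(rng)
            state = assemble_matrix(model, chain, "intravenous")
            t_end_d = 2.0
            expected = rk4(state.matrix, state.y0, t_end_d, dt=0.001)
            got = solve_activities(state, [t_end_d * 24.0]).activities[0, :, 0]
            np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_conservation_without_decay(self, normal_model):
        chain = build_decay_chain("I-131")[:1]
        for route in ("oral", "intravenous"):
            state = assemble_matrix(normal_model, chain, route, include_decay=False)
            curves = solve_activities(state, [0.0, 1.0, 24.0, 240.0, 2400.0])
            np.testing.assert_allclose(curves.total_everywhere(), 1.0, atol=1e-9)

    def test_activities_are_nonnegative(self, patient1_model):
        chain = build_decay_chain("I-131")
        state = assemble_matrix(patient1_model, chain, "oral")
        curves = solve_activities(state, np.linspace(0.0, 480.0, 97))
        assert np.all(curves.activities >= 0.0)

    def test_times_must_be_sorted(self, normal_model):
        chain = build_decay_chain("I-131")[:1]
        state = assemble_matrix(normal_model, chain, "oral")
        with pytest.raises(ValidationError):
            solve_activities(state, [24.0, 5.0])


class TestRIU:
    def test_starts_at_zero_for_both_routes(self, normal_model):
        for route in ("oral", "intravenous"):
            assert riu(normal_model, "I-131", route, [0.0])[0] == pytest.approx(0.0)

    def test_24h_normal_uptake_around_quarter(self, normal_model):
        value = riu(normal_model, "I-131", "oral", [24.0])[0]
        assert value == pytest.approx(0.26, abs=0.02)

    def test_blocked_equals_inorganic_compartment_alone(self):
        blocked = build_icrp_iodine_model("blocked")
        chain = build_decay_chain("I-131")[:1]
        state = assemble_matrix(blocked, chain, "oral")
        t_h = [6.0, 24.0, 96.0]
        curves = solve_activities(state, t_h)
        np.testing.assert_allclose(
            riu(blocked, "I-131", "oral", t_h),
            curves.fraction("thyroid_iodide"),
            atol=1e-12,
        )
        assert np.all(curves.fraction("thyroid_organic") == 0.0)

    def test_riu_bounded_by_decay_free_retention(self, normal_model):
        t_h = [6.0, 24.0, 120.0]
        with_decay = riu(normal_model, "I-131", "oral", t_h)
        chain = build_decay_chain("I-131")[:1]
        state = assemble_matrix(normal_model, chain, "oral", include_decay=False)
        without = solve_activities(state, t_h).region_fraction("thyroid")
        assert np.all(with_decay <= without + 1e-12)

    def test_24h_riu_monotone_in_blood_to_thyroid(self, normal_model):
        values = []
        for k in (2.0, 7.3, 20.0, 60.0):
            coeffs = ThyroidCoefficients(k, 36.0, 95.0, 0.0077)
            model = normal_model.with_thyroid_coefficients(coeffs)
            values.append(riu(model, "I-131", "oral", [24.0])[0])
        assert np.all(np.diff(values) >= 0)


class TestTIAC:
    def test_single_compartment_integral_is_inverse_decay_constant(self):
        model = single_compartment_model()
        table = tiac(model, "I-125", "intravenous")
        lam_per_hour = LN2 / (59.4 * 24.0)
        assert table.region_hours("other") == pytest.approx(1.0 / lam_per_hour, rel=1e-10)

    def test_analytic_matches_quadrature(self, patient1_model):
        analytic = tiac(patient1_model, "I-131", "oral").thyroid_h
        quad = tiac_by_quadrature(patient1_model, "I-131", "oral")
        assert quad == pytest.approx(analytic, rel=1e-4)

    def test_decay_off_closed_loop_raises_diagnostic(self):
        model = CompartmentModel(
            name="loop",
            compartments=(
                Compartment("a", "other", True),
                Compartment("b", "other", True),
            ),
            transfers={("a", "b"): 1.0, ("b", "a"): 1.0},
            route_entry={INTRAVENOUS: "a"},
        )
        chain = build_decay_chain("I-131")[:1]
        state = assemble_matrix(model, chain, "intravenous", include_decay=False)
        from iodose.kinetics import _integrated_nuclei

        with pytest.raises(ValidationError, match="decay"):
            _integrated_nuclei(state)

    def test_total_decays_bounded_by_physical_maximum(self, normal_model):
        table = tiac(normal_model, "I-131", "oral")
        lam_per_hour = get_nuclide("I-131").decay_constant / 24.0
        total = table.table["I-131"].sum()
        assert 0.0 < total <= 1.0 / lam_per_hour + 1e-6

    def test_progeny_decays_bounded_by_branching(self, normal_model):
        chain = build_decay_chain("I-131")
        state = assemble_matrix(normal_model, chain, "oral")
        from iodose.kinetics import _integrated_nuclei

        x = _integrated_nuclei(state)
        n = normal_model.n_compartments
        lam_parent = chain[0][0].decay_constant
        lam_xe = chain[1][0].decay_constant
        parent_decays = lam_parent * x[:n].sum()
        xe_decays = lam_xe * x[n:].sum()
        assert xe_decays <= 0.0118 * parent_decays + 1e-9


class TestWholeBodyDecays:
    def test_no_excretion_means_every_decay_in_body(self):
        model = CompartmentModel(
            name="closed",
            compartments=(
                Compartment("a", "other", True),
                Compartment("b", "other", True),
            ),
            transfers={("a", "b"): 0.5},
            route_entry={INTRAVENOUS: "a"},
        )
        assert whole_body_decays(model, "I-131", "intravenous") == pytest.approx(1.0)

    def test_instant_excretion_limit_approaches_zero(self):
        model = CompartmentModel(
            name="flush",
            compartments=(
                Compartment("a", "other", True),
                Compartment("urine", "urine", False),
            ),
            transfers={("a", "urine"): 1e6},
            route_entry={INTRAVENOUS: "a"},
        )
        assert whole_body_decays(model, "I-131", "intravenous") < 1e-4
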