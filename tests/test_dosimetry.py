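from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iodose import (
    PlanInputs,
    SAFTable,
    absorbed_dose,
    administered_activity,
    compose_s_value,
    default_svalue_table,
    effective_dose,
    mass_correct_self_dose,
    scale_to_administration,
    tiac,
)
from iodose.dosimetry import (
    DEFAULT_WEIGHTS,
    REFERENCE_THYROID_MASS_KG,
    SValueTable,
    mean_energy_per_decay_j,
)
from iodose.errors import ValidationError
from iodose.nuclides import EmissionSpectrum, Transition
from iodose.units import MEV_TO_J


def toy_saf():
    rows = []
    for rclass, phis in (("photon", [0.02, 0.010, 0.004]),
                         ("electron", [40.0, 42.0, 45.0])):
        for e, phi in zip([0.01, 0.1, 1.0], phis):
            rows.append(("thyroid", "thyroid", rclass, e, phi))
    return SAFTable(pd.DataFrame(
        rows, columns=["source", "target", "radiation_class", "energy_mev", "phi_per_kg"],
    ))


class TestComposeSValue:
    def test_hand_summed_three_transition_fixture(self):
        spectrum = EmissionSpectrum((
            Transition("photon", 0.1, 0.8),
            Transition("photon", 1.0, 0.1),
            Transition("electron", 0.1, 1.0),
        ))
        row = compose_s_value(spectrum, toy_saf(), "thyroid", "thyroid")
        to_mgy = 3.6e9 * 1e3
        expected_photon = (0.1 * 0.8 * 0.010 + 1.0 * 0.1 * 0.004) * MEV_TO_J * to_mgy
        expected_electron = (0.1 * 1.0 * 42.0) * MEV_TO_J * to_mgy
        assert row["s_photon"] == pytest.approx(expected_photon, rel=1e-12)
        assert row["s_particle"] == pytest.approx(expected_electron, rel=1e-12)

    def test_additive_over_spectrum_partition(self):
        a = EmissionSpectrum((Transition("photon", 0.05, 0.5),))
        b = EmissionSpectrum((Transition("electron", 0.5, 0.9),))
        both = EmissionSpectrum(a.transitions + b.transitions)
        saf = toy_saf()
        ra = compose_s_value(a, saf, "thyroid", "thyroid")
        rb = compose_s_value(b, saf, "thyroid", "thyroid")
        rab = compose_s_value(both, saf, "thyroid", "thyroid")
        assert rab["s_photon"] == pytest.approx(ra["s_photon"] + rb["s_photon"])
        assert rab["s_particle"] == pytest.approx(ra["s_particle"] + rb["s_particle"])

    def test_energy_outside_grid_raises_not_clamps(self):
        spectrum = EmissionSpectrum((Transition("photon", 2.0, 0.5),))
        with pytest.raises(ValidationError, match="outside SAF grid"):
            compose_s_value(spectrum, toy_saf(), "thyroid", "thyroid")


class TestMassCorrection:
    ROW = {
        "nuclide": "I-131", "source": "thyroid", "target": "thyroid",
        "sex": "female", "s_photon": 0.3, "s_particle": 6.0,
    }

    def test_reference_mass_is_identity(self):
        out = mass_correct_self_dose(self.ROW, REFERENCE_THYROID_MASS_KG["female"])
        assert out["s_photon"] == pytest.approx(0.3, rel=1e-12)
        assert out["s_particle"] == pytest.approx(6.0, rel=1e-12)

    def test_doubling_mass_scales_components(self):
        m = REFERENCE_THYROID_MASS_KG["female"]
        out = mass_correct_self_dose(self.ROW, 2.0 * m)
        assert out["s_particle"] == pytest.approx(6.0 * 0.5, rel=1e-12)
        assert out["s_photon"] == pytest.approx(0.3 * 0.5 ** (2.0 / 3.0), rel=1e-12)

    def test_monotone_decrease_with_patient_mass(self):
        masses = [0.01, 0.02, 0.04, 0.08]
        photon = [mass_correct_self_dose(self.ROW, m)["s_photon"] for m in masses]
        particle = [mass_correct_self_dose(self.ROW, m)["s_particle"] for m in masses]
        assert np.all(np.diff(photon) < 0)
        assert np.all(np.diff(particle) < 0)

    @settings(derandomize=True, max_examples=50)
    @given(
        m_a=st.floats(min_value=0.005, max_value=0.2),
        m_b=st.floats(min_value=0.005, max_value=0.2),
    )
    def test_correction_preserves_component_ordering(self, m_a, m_b):
        """A larger thyroid receives smaller self-dose S values, and beyond
        the reference mass the particle term falls faster than the photon
        term (full mass scaling vs the two-thirds power)."""
        small, large = sorted((m_a, m_b))
        s_small = mass_correct_self_dose(self.ROW, small)
        s_large = mass_correct_self_dose(self.ROW, large)
        assert s_large["s_photon"] <= s_small["s_photon"] + 1e-12
        assert s_large["s_particle"] <= s_small["s_particle"] + 1e-12
        rel_particle = s_large["s_particle"] / s_small["s_particle"]
        rel_photon = s_large["s_photon"] / s_small["s_photon"]
        assert rel_particle <= rel_photon + 1e-12

    def test_cross_dose_row_is_a_usage_error(self):
        row = dict(self.ROW, source="blood")
        with pytest.raises(ValidationError, match="self-irradiation"):
            mass_correct_self_dose(row, 0.02)


class TestAbsorbedDose:
    def test_single_source_single_row_is_tiac_times_s(self, normal_model):
        tiacs = tiac(normal_model, "I-131", "oral")
        tau = tiacs.region_hours("thyroid")
        table = SValueTable(pd.DataFrame(
            [("I-131", "thyroid", "thyroid", "female", 0.3, 6.0)],
            columns=["nuclide", "source", "target", "sex", "s_photon", "s_particle"],
        ))
        result = absorbed_dose(tiacs, table, sexes=("female",))
        assert result.organ_doses("female")["thyroid"] == pytest.approx(tau * 6.3)

    def test_linear_in_tiacs(self, normal_model):
        tiacs = tiac(normal_model, "I-131", "oral")
        doubled = replace(
            tiacs, table=tiacs.table * 2.0, by_compartment=tiacs.by_compartment * 2.0
        )
        table = default_svalue_table()
        d1 = absorbed_dose(tiacs, table).organ_doses("female")
        d2 = absorbed_dose(doubled, table).organ_doses("female")
        pd.testing.assert_series_equal(d2, 2.0 * d1)

    def test_progeny_contribution_is_negligible_for_i131(self, patient1_model):
        tiacs = tiac(patient1_model, "I-131", "oral")
        table = default_svalue_table()
        full = absorbed_dose(tiacs, table)
        no_xe = SValueTable(table.frame[table.frame["nuclide"] != "Xe-131m"])
        parent_only = absorbed_dose(tiacs, no_xe)
        thyroid_full = full.organ_doses("female")["thyroid"]
        thyroid_parent = parent_only.organ_doses("female")["thyroid"]
        rel = (thyroid_full - thyroid_parent) / thyroid_full
        assert 0.0 <= rel < 0.01


class TestEffectiveDose:
    def test_uniform_dose_gives_that_dose(self):
        organs = list(DEFAULT_WEIGHTS.w_t) + ["kidneys", "uterus"]
        organs.remove("remainder")
        uniform = pd.Series(2.0, index=organs)
        assert effective_dose(uniform, uniform) == pytest.approx(2.0)

    def test_zero_thyroid_weight_removes_thyroid_only_dose(self):
        only_thyroid = pd.Series({"thyroid": 100.0})
        assert effective_dose(only_thyroid, only_thyroid, zero_thyroid=True) == 0.0

    def test_thyroid_term_identity(self, normal_model):
        tiacs = tiac(normal_model, "I-131", "oral")
        result = absorbed_dose(tiacs, default_svalue_table())
        male, female = result.organ_doses("male"), result.organ_doses("female")
        e = effective_dose(male, female)
        e0 = effective_dose(male, female, zero_thyroid=True)
        w_thyroid = DEFAULT_WEIGHTS.w_t["thyroid"]
        avg_thyroid = 0.5 * (male["thyroid"] + female["thyroid"])
        assert e0 == pytest.approx(e - w_thyroid * avg_thyroid, rel=1e-12)
        assert e0 <= e


class TestPlanning:
    def test_unit_identity_one_becquerel(self):
        # 1 Gy to 1 kg with 1 J per decay and a 1-second RIU integral -> 1 Bq
        plan = PlanInputs(1.0, 1.0, 1.0, 1.0 / 3600.0)
        assert administered_activity(plan) == pytest.approx(1e-6, rel=1e-12)

    def test_linear_in_prescribed_dose_and_inverse_in_integral(self):
        base = PlanInputs(150.0, 0.03, mean_energy_per_decay_j(), 100.0)
        a = administered_activity(base)
        assert administered_activity(replace(base, prescribed_dose_gy=300.0)) == pytest.approx(2 * a)
        assert administered_activity(replace(base, riu_integral_h=200.0)) == pytest.approx(a / 2)

    @settings(derandomize=True, max_examples=50)
    @given(
        scale=st.floats(min_value=0.1, max_value=10.0),
        dose=st.floats(min_value=1.0, max_value=500.0),
        integral=st.floats(min_value=10.0, max_value=300.0),
    )
    def test_joint_scaling_invariance(self, scale, dose, integral):
        """Scaling the prescription and the uptake integral by the same
        factor leaves the prescribed activity unchanged."""
        e = mean_energy_per_decay_j()
        a = administered_activity(PlanInputs(dose, 0.03, e, integral))
        b = administered_activity(PlanInputs(dose * scale, 0.03, e, integral * scale))
        assert b == pytest.approx(a, rel=1e-12)

    def test_nonpositive_integral_rejected(self):
        with pytest.raises(ValidationError):
            PlanInputs(150.0, 0.03, 3e-14, 0.0)

    def test_scale_to_administration(self):
        coeffs = pd.Series({"kidneys": 0.77, "stomach_wall": 0.38})
        scaled = scale_to_administration(coeffs, 300.0)
        assert scaled["kidneys"] == pytest.approx(231.0)
        assert scale_to_administration(0.5, 0.0) == 0.0


class TestSValueTableIO:
    def test_missing_units_header_rejected(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("nuclide,source,target,sex,s_photon,s_particle\n"
                        "I-131,thyroid,thyroid,female,0.3,6.0\n")
        with pytest.raises(ValidationError, match="units"):
            SValueTable.from_csv(path)

    def test_duplicate_key_rejected(self):
        frame = pd.DataFrame(
            [("I-131", "thyroid", "thyroid", "female", 0.3, 6.0)] * 2,
            columns=["nuclide", "source", "target", "sex", "s_photon", "s_particle"],
        )
        with pytest.raises(ValidationError, match="duplicate"):
            SValueTable(frame)
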