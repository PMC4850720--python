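"""Unit tests for compounds, pathway modes, genotype gating and flux audits."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fermsplit.stoich_model import (
    COMPOUNDS,
    DOWNSTREAM_REACTIONS,
    PATHWAY_MODES,
    STRAIN_PRESETS,
    FluxDomainError,
    FluxVector,
    Genotype,
    InfeasibleModelError,
    InvalidModeError,
    ModelOptions,
    build_model,
    mode_coefficients,
    strict_anaerobe_model,
    validate_flux,
)
from fermsplit.yield_scenarios import scenario_yields


class TestCompounds:
    @pytest.mark.parametrize(
        "name, carbons, gamma",
        [
            ("glucose", 6, 24),
            ("gluconate", 6, 22),
            ("glycerol", 3, 14),
            ("pyruvate", 3, 10),
            ("ethanol", 2, 12),
            ("acetate", 2, 8),
            ("formate", 1, 2),
            ("h2", 0, 2),
            ("co2", 1, 0),
        ],
    )
    def test_degree_of_reduction_from_formula(self, name, carbons, gamma):
        cpd = COMPOUNDS[name]
        assert cpd.carbons == carbons
        assert cpd.gamma == 4 * cpd.c + cpd.h - 2 * cpd.o == gamma

    def test_heating_values_consistent(self):
        # HHV - LHV equals the condensation enthalpy of product water
        for name, n_water in [("h2", 1), ("ethanol", 3), ("glucose", 6), ("glycerol", 4)]:
            cpd = COMPOUNDS[name]
            assert cpd.hhv - cpd.lhv == pytest.approx(44.0 * n_water, abs=0.5)


class TestPathwayModes:
    @pytest.mark.parametrize("mode", PATHWAY_MODES.values(), ids=lambda m: m.id)
    def test_carbon_and_electron_closure_exact(self, mode):
        assert mode.carbon_closure_gap() == 0
        assert mode.electron_closure_gap() == 0

    @pytest.mark.parametrize(
        "mode_id, substrate, pyr, nadh, nadph, co2, atp",
        [
            ("EMP", "glucose", 2, 2, 0, 0, 2),
            ("PP_SINGLE_PASS", "glucose", Fraction(5, 3), Fraction(5, 3), 2, 1, Fraction(5, 3)),
            ("PP_CYCLIC", "glucose", 1, 1, 6, 3, 1),
            ("ED", "glucose", 2, 1, 1, 0, 1),
            ("GNT_GND", "gluconate", Fraction(5, 3), Fraction(5, 3), 1, 1, Fraction(5, 3)),
            ("GNT_ED", "gluconate", 2, 1, 0, 0, 1),
            ("GLYCEROL", "glycerol", 1, 2, 0, 0, 1),
        ],
    )
    def test_coefficients(self, mode_id, substrate, pyr, nadh, nadph, co2, atp):
        m = mode_coefficients(mode_id, substrate)
        assert (m.pyr, m.nadh, m.nadph, m.co2_gly, m.atp) == (pyr, nadh, nadph, co2, atp)

    @pytest.mark.parametrize(
        "mode_id, substrate",
        [("EMP", "gluconate"), ("GNT_GND", "glucose"), ("GLYCEROL", "glucose"),
         ("NOPE", "glucose")],
    )
    def test_invalid_pairings_rejected(self, mode_id, substrate):
        with pytest.raises(InvalidModeError):
            mode_coefficients(mode_id, substrate)


class TestDownstreamReactions:
    @pytest.mark.parametrize("name", DOWNSTREAM_REACTIONS)
    def test_electron_conservation(self, name):
        e_in, e_out = DOWNSTREAM_REACTIONS[name]
        assert e_in == e_out


class TestBuildModel:
    def test_sh9_star_full_mode_set(self):
        m = build_model(STRAIN_PRESETS["SH9*"], "glucose")
        assert set(m.mode_ids) == {"EMP", "PP_SINGLE_PASS", "PP_CYCLIC", "ED"}
        assert {"PFL", "FHL", "ADH_ACCOA", "PTA_ACKA", "PYR_EXCRETION"} <= m.reactions

    def test_sh8_star_lacks_acetate_branch(self):
        m = build_model(STRAIN_PRESETS["SH8*_ZG"], "glucose")
        assert "PTA_ACKA" not in m.reactions
        assert set(m.mode_ids) == {"EMP", "PP_SINGLE_PASS", "PP_CYCLIC", "ED"}

    def test_ed_deletion_excludes_ed_modes(self):
        m = build_model(STRAIN_PRESETS["SH10_ZG"], "glucose")
        assert "ED" not in m.mode_ids
        g = build_model(STRAIN_PRESETS["SH10_ZG"], "gluconate")
        assert g.mode_ids == ("GNT_GND",)

    def test_gluconate_without_any_entry_is_infeasible(self):
        genotype = Genotype(edd_eda=True, gnd=True)
        with pytest.raises(InfeasibleModelError):
            build_model(genotype, "gluconate")

    def test_optional_reactions_gated_by_options(self):
        m = build_model(STRAIN_PRESETS["SH9*_ZG"], "glucose",
                        ModelOptions(pdc_route=True, nadh_h2=True))
        assert {"PDC_ROUTE", "NADH_H2"} <= m.reactions

    def test_strict_anaerobe_model_is_emp_only_with_nadh_h2(self):
        m = strict_anaerobe_model()
        assert m.mode_ids == ("EMP",)
        assert "NADH_H2" in m.reactions


class TestValidateFlux:
    def test_emp_redox_neutral_vector_closes_everything(self, glucose_model):
        flux = FluxVector(fractions={"EMP": 1.0}, pfl=2.0, fhl=2.0, adh=1.0, ack=1.0)
        r = validate_flux(flux, glucose_model)
        assert r.carbon == pytest.approx(0, abs=1e-12)
        assert r.electron == pytest.approx(0, abs=1e-12)
        assert r.nadph == pytest.approx(0, abs=1e-12)
        assert r.feasible(closed_redox=True)

    def test_pp_all_ethanol_has_one_third_surplus(self, glucose_model):
        f = 5.0 / 3.0
        flux = FluxVector(fractions={"PP_SINGLE_PASS": 1.0}, pfl=f, fhl=f, adh=f)
        r = validate_flux(flux, glucose_model)
        assert r.carbon == pytest.approx(0, abs=1e-9)
        assert r.electron == pytest.approx(0, abs=1e-9)
        assert r.nadph == pytest.approx(1.0 / 3.0, abs=1e-9)
        assert r.feasible() and not r.feasible(closed_redox=True)

    def test_negative_component_rejected(self, glucose_model):
        flux = FluxVector(fractions={"EMP": 1.0}, pfl=2.0, fhl=2.0, adh=-1.0)
        with pytest.raises(FluxDomainError):
            validate_flux(flux, glucose_model)

    def test_bad_simplex_rejected(self, glucose_model):
        with pytest.raises(FluxDomainError):
            validate_flux(FluxVector(fractions={"EMP": 0.7}, slack=0.5), glucose_model)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        f_emp=st.floats(0, 1),
        f_pp=st.floats(0, 1),
        slack=st.floats(0, 0.3),
    )
    def test_random_redox_closed_vectors_close_carbon(self, glucose_model, f_emp, f_pp, slack):
        """Substrate carbon x (1 - slack) lands entirely in the products."""
        total = f_emp + f_pp + slack
        if total == 0:
            return
        # normalize onto the simplex
        f_emp, f_pp, slack = f_emp / total, f_pp / total, slack / total
        res = scenario_yields({"EMP": f_emp, "PP_SINGLE_PASS": f_pp}, glucose_model)
        if not res.feasible:
            return
        r = validate_flux(res.flux, glucose_model)
        assert abs(r.carbon) < 1e-9
        assert abs(r.electron) < 1e-9
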