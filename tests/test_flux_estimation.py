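"""Flux-split estimation: round trips, oracle agreement, identifiability."""

import numpy as np
import pytest

from fermsplit.balance_audit import YieldMeasurement
from fermsplit.flux_estimation import (
    default_mode_basis,
    estimate_splits,
    grid_oracle,
    profile_residual,
)
from fermsplit.stoich_model import STRAIN_PRESETS, build_model
from fermsplit.synthetic_data import SimConfig, simulate_yields


@pytest.fixture(scope="module")
def roundtrip_sample(glucose_model):
    cfg = SimConfig(splits={"EMP": 0.4, "PP_SINGLE_PASS": 0.6}, noise_cv=0.0, seed=0)
    return simulate_yields(cfg, glucose_model)[0]


class TestRoundTrip:
    @pytest.mark.parametrize("loss", ["balance", "yield"])
    def test_noiseless_recovery_is_exact(self, glucose_model, roundtrip_sample, loss):
        r = estimate_splits(roundtrip_sample, glucose_model, loss=loss)
        assert r.splits["PP_SINGLE_PASS"] == pytest.approx(0.600, abs=1e-6)
        assert r.splits["EMP"] == pytest.approx(0.400, abs=1e-6)
        assert r.ssr == pytest.approx(0.0, abs=1e-10)
        assert r.identifiable

    def test_slack_absorbs_unmodeled_substrate(self, glucose_model):
        cfg = SimConfig(splits={"EMP": 0.2, "PP_SINGLE_PASS": 0.7}, noise_cv=0.0, seed=0)
        s = simulate_yields(cfg, glucose_model)[0]
        r = estimate_splits(s, glucose_model)
        assert r.slack == pytest.approx(0.1, abs=1e-6)


class TestPanelEstimates:
    def test_host_strain_pp_fraction_near_zero(self, glucose_model, panel):
        # the NAD(P)H balance forces f_PP down when ethanol ~ acetate
        r = estimate_splits(panel["SH9*/glucose"], glucose_model, co2_policy="omit")
        assert r.f_pp <= 0.05

    @pytest.mark.parametrize("co2_policy", ["omit", "infer"])
    @pytest.mark.parametrize("loss", ["balance", "yield"])
    def test_zwf_gnd_overexpression_raises_f_pp(self, glucose_model, panel, co2_policy, loss):
        host = estimate_splits(panel["SH9*/glucose"], glucose_model,
                               co2_policy=co2_policy, loss=loss)
        over = estimate_splits(panel["SH9*_ZG/glucose"], glucose_model,
                               co2_policy=co2_policy, loss=loss)
        assert over.f_pp > host.f_pp + 0.2

    def test_inferred_co2_pulls_f_pp_up(self, glucose_model, panel):
        omit = estimate_splits(panel["SH9*_ZG/glucose"], glucose_model, co2_policy="omit")
        infer = estimate_splits(panel["SH9*_ZG/glucose"], glucose_model, co2_policy="infer")
        assert infer.f_pp > omit.f_pp


class TestGridOracle:
    @pytest.mark.parametrize("sid", ["SH9*/glucose", "SH9*_ZG/glucose", "SH8*_ZG/glucose"])
    @pytest.mark.parametrize("co2_policy", ["omit", "infer"])
    def test_oracle_equivalence_on_panel(self, panel, sid, co2_policy):
        model = build_model(
            STRAIN_PRESETS[sid.split("/")[0]], "glucose"
        )
        step = 0.01
        a = estimate_splits(panel[sid], model, co2_policy=co2_policy)
        b = grid_oracle(panel[sid], model, co2_policy=co2_policy, step=step)
        assert a.f_pp == pytest.approx(b.f_pp, abs=2 * step)
        assert a.ssr <= b.ssr + 1e-9

    def test_oracle_equivalence_gluconate(self, gluconate_model, panel):
        a = estimate_splits(panel["SH9*/gluconate"], gluconate_model)
        b = grid_oracle(panel["SH9*/gluconate"], gluconate_model, step=0.01)
        assert a.f_pp == pytest.approx(b.f_pp, abs=0.02)

    def test_step_domain(self, glucose_model, panel):
        with pytest.raises(ValueError):
            grid_oracle(panel["SH9*/glucose"], glucose_model, step=0.0)
        with pytest.raises(ValueError):
            grid_oracle(panel["SH9*/glucose"], glucose_model, step=0.2)

    def test_too_many_dimensions_refused(self, panel):
        model = build_model(STRAIN_PRESETS["SH9*"], "glucose")
        with pytest.raises(ValueError):
            grid_oracle(panel["SH9*/glucose"], model, step=0.05,
                        modes=["EMP", "PP_SINGLE_PASS", "PP_CYCLIC", "ED"])

    def test_single_mode_model_trivial(self):
        model = build_model(STRAIN_PRESETS["SH9*"], "glycerol")
        m = YieldMeasurement("g", "glycerol", y_h2=0.9, y_etoh=0.9)
        r = grid_oracle(m, model, step=0.01)
        assert r.splits["GLYCEROL"] == pytest.approx(0.9, abs=0.02)


class TestProfileAndIdentifiability:
    def test_noiseless_profile_has_unique_zero_minimum(self, glucose_model, roundtrip_sample):
        grid = np.linspace(0, 1, 21)
        prof = profile_residual(roundtrip_sample, glucose_model, "PP_SINGLE_PASS", grid)
        i = int(np.argmin(prof))
        assert grid[i] == pytest.approx(0.6, abs=0.05)
        assert prof[i] == pytest.approx(0.0, abs=1e-8)
        # monotone away from the minimum
        assert np.all(np.diff(prof[: i + 1]) <= 1e-9)
        assert np.all(np.diff(prof[i:]) >= -1e-9)

    def test_h2_only_measurement_is_non_identifiable(self, glucose_model):
        # zero weight on every equation carrying ethanol/acetate information
        m = YieldMeasurement("h2only", "glucose", y_h2=1.8)
        w = np.array([1.0, 0.0, 1.0, 0.0])  # pyruvate + formate rows only
        r = estimate_splits(m, glucose_model, weights=w)
        assert not r.identifiable
        prof = profile_residual(m, glucose_model, "PP_SINGLE_PASS",
                                np.linspace(0, 0.5, 6), weights=w)
        assert np.ptp(prof) < 1e-8

    def test_profile_grid_domain(self, glucose_model, roundtrip_sample):
        with pytest.raises(ValueError):
            profile_residual(roundtrip_sample, glucose_model, "EMP", [-0.1, 0.5])

    def test_all_absent_yields_rejected(self, glucose_model):
        with pytest.raises(ValueError):
            estimate_splits(YieldMeasurement("empty", "glucose"), glucose_model)


class TestMonotonicity:
    def test_more_ethanol_never_lowers_f_pp(self, glucose_model):
        """More ethanol means more NAD(P)H demand, hence more PP flux."""
        prev = -1.0
        for y_etoh in np.linspace(0.8, 1.6, 9):
            m = YieldMeasurement("mono", "glucose", y_h2=1.8, y_etoh=float(y_etoh), y_ace=0.2)
            f_pp = estimate_splits(m, glucose_model).f_pp
            assert f_pp >= prev - 1e-6
            prev = f_pp


class TestBasis:
    def test_default_basis_glucose(self, glucose_model):
        assert default_mode_basis(glucose_model) == ("EMP", "PP_SINGLE_PASS")

    def test_explicit_basis_must_be_admissible(self):
        model = build_model(STRAIN_PRESETS["SH10_ZG"], "glucose")
        with pytest.raises(Exception):
            default_mode_basis(model, ["ED"])
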