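"""Assay mathematics: viability, 4PL, permeability, HPLC, logBB."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cns_screen.assays import (
    CalibrationCurve, DoseResponseDataset, FourPLRegressor, LinearCalibration,
    PermeabilityRecord, fit_4pl, four_pl, log_bb, normalize_by_teer,
    normalize_viability, permeability, quantify, tissue_concentration,
)
from cns_screen.registry import get_compound


class TestNormalizeViability:
    def test_vehicle_mean_maps_to_hundred(self):
        raw = np.array([0.8, 0.9, 1.0, 0.4])
        out = normalize_viability(raw, vehicle_wells=[0, 1, 2])
        assert out[:3].mean() == pytest.approx(100.0)

    def test_zero_absorbance_is_zero_percent(self):
        out = normalize_viability(np.array([1.0, 0.0]), vehicle_wells=[0])
        assert out[1] == 0.0

    def test_half_vehicle_is_fifty_percent(self):
        out = normalize_viability(np.array([1.0, 1.0, 0.5]), vehicle_wells=[0, 1])
        assert out[2] == pytest.approx(50.0)

    def test_nonpositive_vehicle_mean_rejected(self):
        with pytest.raises(ValueError):
            normalize_viability(np.array([0.0, 1.0]), vehicle_wells=[0])


class TestFourPL:
    def test_noiseless_recovery_to_1e6_relative(self):
        doses = 1.17 * 10.0 ** np.linspace(-1.5, 1.5, 8)
        resp = four_pl(doses, ic50=1.17, hill=1.5, top=100.0, bottom=5.0)
        reg = FourPLRegressor().fit(doses, resp)
        assert reg.ic50_ == pytest.approx(1.17, rel=1e-6)
        assert reg.hill_ == pytest.approx(1.5, rel=1e-6)
        assert reg.top_ == pytest.approx(100.0, rel=1e-6)
        assert reg.bottom_ == pytest.approx(5.0, rel=1e-6)

    def test_dose_unit_rescaling_equivariance(self):
        doses = 0.59 * 10.0 ** np.linspace(-1.5, 1.5, 8)
        resp = four_pl(doses, ic50=0.59, hill=1.2, top=100.0, bottom=0.0)
        a = FourPLRegressor().fit(doses, resp)
        b = FourPLRegressor().fit(doses * 1000.0, resp)
        assert b.ic50_ == pytest.approx(a.ic50_ * 1000.0, rel=1e-6)
        assert b.hill_ == pytest.approx(a.hill_, rel=1e-6)

    def test_flat_response_not_identifiable(self):
        doses = np.array([0.1, 1.0, 10.0, 100.0])
        with pytest.raises(ValueError, match="flat"):
            FourPLRegressor().fit(doses, np.full(4, 50.0))

    def test_too_few_distinct_doses_rejected(self):
        with pytest.raises(ValueError):
            FourPLRegressor().fit([1, 1, 2, 2], [90, 91, 10, 11])

    def test_predict_reproduces_curve(self):
        doses = 10.0 ** np.linspace(-2, 2, 9)
        resp = four_pl(doses, 1.0, 1.0, 100.0, 0.0)
        reg = FourPLRegressor().fit(doses, resp)
        assert np.allclose(reg.predict(doses), resp, atol=1e-5)

    def test_dataset_wrapper_returns_fit_record(self):
        doses = np.repeat(10.0 ** np.linspace(-1.5, 1.5, 8), 3)
        resp = four_pl(doses, 2.0, 1.0, 100.0, 10.0)
        d = DoseResponseDataset("HR68", doses, resp)
        fit = fit_4pl(d)
        assert fit.converged
        assert fit.ic50 == pytest.approx(2.0, rel=1e-6)
        assert fit.bottom <= fit.top

    def test_noisy_median_ic50_error_under_ten_percent(self):
        # sigma = 5% multiplicative, n = 3 per dose, 200 seeds
        from cns_screen.simulate import GeneratorConfig, gen_dose_response
        errors = []
        for seed in range(200):
            cfg = GeneratorConfig(seed=seed, n=3, noise_sd=0.05,
                                  truth={"ic50": 1.17, "hill": 1.5,
                                         "top": 100.0, "bottom": 5.0})
            df = gen_dose_response(cfg)
            reg = FourPLRegressor().fit(df["dose_uM"], df["response_pct"])
            errors.append(abs(reg.ic50_ - 1.17) / 1.17)
        assert np.median(errors) < 0.10


class TestPermeability:
    def test_zero_acceptor_concentration_gives_zero(self):
        r = PermeabilityRecord(v_a=0.5, c_a=0.0, t=10800, s=0.33, c_l=25)
        assert permeability(r) == 0.0

    def test_direct_arithmetic_example(self):
        r = PermeabilityRecord(v_a=0.5, c_a=5.0, t=10800, s=0.33, c_l=25)
        assert permeability(r) == pytest.approx(2.806e-5, rel=1e-3)

    def test_linearity_in_acceptor_concentration(self):
        r1 = PermeabilityRecord(v_a=0.5, c_a=5.0, t=10800, s=0.33, c_l=25)
        r2 = PermeabilityRecord(v_a=0.5, c_a=10.0, t=10800, s=0.33, c_l=25)
        assert permeability(r2) == pytest.approx(2 * permeability(r1), rel=1e-12)

    @pytest.mark.parametrize("field", ["t", "s", "c_l", "v_a"])
    def test_nonpositive_geometry_rejected(self, field):
        kwargs = dict(v_a=0.5, c_a=5.0, t=10800, s=0.33, c_l=25)
        kwargs[field] = 0.0
        with pytest.raises(ValueError):
            PermeabilityRecord(**kwargs)


class TestTeerNormalization:
    def test_batch_mean_insert_unchanged(self):
        assert normalize_by_teer(2e-5, 150.0, 150.0) == 2e-5

    def test_double_teer_doubles_p(self):
        assert normalize_by_teer(2e-5, 300.0, 150.0) == pytest.approx(4e-5)

    def test_identical_batch_is_noop(self):
        ps = [normalize_by_teer(p, 120.0, 120.0) for p in (1e-6, 2e-5)]
        assert ps == [1e-6, 2e-5]

    def test_nonpositive_teer_rejected(self):
        with pytest.raises(ValueError):
            normalize_by_teer(1e-5, 0.0, 150.0)


class TestQuantify:
    def test_area_equal_intercept_is_zero(self):
        curve = CalibrationCurve(slope=1000.0, intercept=50.0, r2=1.0,
                                 conc_min=0.0, conc_max=25.0)
        out = quantify([50.0], curve)
        assert out.loc[0, "conc_uM"] == 0.0

    def test_perfect_standards_round_trip(self):
        conc = np.array([0.0, 1.0, 2.0, 5.0, 10.0])
        area = 800.0 * conc + 30.0
        cal = LinearCalibration().fit(conc, area)
        out = cal.quantify(area)
        assert np.allclose(out["conc_uM"], conc, atol=1e-9)
        assert cal.curve_.r2 == pytest.approx(1.0)

    def test_noisy_standards_recover_within_three_sigma(self):
        rng = np.random.default_rng(17)
        conc = np.array([0.0, 0.78125, 1.5625, 3.125, 6.25, 12.5, 25.0])
        sigma = 40.0
        area = 1000.0 * conc + 50.0 + rng.normal(0, sigma, conc.size)
        cal = LinearCalibration().fit(conc, area)
        out = cal.quantify(1000.0 * np.array([5.0]) + 50.0)
        assert abs(out.loc[0, "conc_uM"] - 5.0) < 3 * sigma / 1000.0

    def test_extrapolation_flagged(self):
        curve = CalibrationCurve(slope=100.0, intercept=0.0, r2=1.0,
                                 conc_min=0.0, conc_max=10.0)
        out = quantify([100.0 * 50.0], curve)
        assert bool(out.loc[0, "extrapolated"])

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            CalibrationCurve(slope=-1.0, intercept=0.0, r2=1.0,
                             conc_min=0.0, conc_max=1.0)


class TestLogBB:
    def test_equal_concentrations_give_zero(self):
        assert log_bb(5.0, 5.0) == 0.0

    def test_twenty_percent_penetration_is_minus_point_seven(self):
        # the temozolomide benchmark: 20% of plasma levels in the CNS
        assert round(log_bb(0.20, 1.0), 1) == -0.7

    def test_tenfold_ratio_is_one(self):
        assert log_bb(10.0, 1.0) == pytest.approx(1.0)

    @given(x=st.floats(1e-6, 1e6), y=st.floats(1e-6, 1e6))
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry(self, x, y):
        assert log_bb(x, y) == pytest.approx(-log_bb(y, x), abs=1e-12)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            log_bb(0.0, 1.0)


class TestTissueConcentration:
    def test_zero_amount_is_zero(self, hr67):
        assert tissue_concentration(0.0, hr67) == 0.0

    def test_unit_identity(self, hr67):
        # amount equal to the molar mass in ng/g is exactly 1 uM
        assert tissue_concentration(hr67.molar_mass, hr67) == pytest.approx(1.0)

    def test_brain_tumor_level_arithmetic(self, hr67):
        # 1461 ng/g of a ~395 g/mol compound is ~3.7 uM
        assert tissue_concentration(1461.0, hr67) == pytest.approx(3.70, abs=0.01)
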