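"""Normalization, kcat, dose-response, fold change and FP binding fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from allostat.enzymology import (
    KineticResult,
    bound_fraction,
    cpm_to_product,
    fit_dose_response,
    fit_fp_binding,
    fit_kcat,
    fold_change,
    four_pl,
    normalize_activity,
)
from allostat.errors import ComparisonError, DegenerateWindowError, ValidationError


def well_table(sample_cpm, control_cpm=(2000.0,), background_cpm=(50.0,),
               dataset="d1", conc=10.0):
    rows = []
    for i, c in enumerate(sample_cpm):
        rows.append((dataset, "sample", c, conc, 20.0, "peptide", 1.0, i))
    for i, c in enumerate(control_cpm):
        rows.append((dataset, "no_compound_control", c, 0.0, 20.0, "peptide", 1.0, i))
    for i, c in enumerate(background_cpm):
        rows.append((dataset, "no_enzyme_background", c, 0.0, 0.0, "peptide", 1.0, i))
    return pd.DataFrame(rows, columns=[
        "dataset", "role", "cpm", "compound_conc_uM", "enzyme_conc_nM",
        "substrate", "time_h", "replicate"])


class TestNormalization:
    def test_control_background_and_midpoint(self):
        df, prov = normalize_activity(well_table([2000.0, 50.0, 1025.0]))
        pct = df[df.role == "sample"]["percent_activity"].to_numpy()
        assert np.allclose(pct, [100.0, 0.0, 50.0])
        assert prov["d1"] == (2000.0, 50.0)

    def test_controls_average_to_100_and_0(self):
        df, _ = normalize_activity(well_table([500.0], control_cpm=(1900.0, 2100.0),
                                              background_cpm=(40.0, 60.0)))
        assert np.isclose(
            df[df.role == "no_compound_control"]["percent_activity"].mean(), 100.0)
        assert np.isclose(
            df[df.role == "no_enzyme_background"]["percent_activity"].mean(), 0.0)

    @given(st.floats(0.1, 10.0), st.floats(0.0, 500.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariant_under_joint_affine_cpm_change(self, scale, offset):
        base = well_table([1500.0, 300.0])
        shifted = base.copy()
        shifted["cpm"] = shifted["cpm"] * scale + offset
        p1, _ = normalize_activity(base)
        p2, _ = normalize_activity(shifted)
        assert np.allclose(p1["percent_activity"], p2["percent_activity"], atol=1e-9)

    def test_missing_controls_rejected(self):
        df = well_table([100.0]).query("role != 'no_enzyme_background'")
        with pytest.raises(ValidationError, match="d1"):
            normalize_activity(df)

    def test_degenerate_window_rejected(self):
        with pytest.raises(DegenerateWindowError):
            normalize_activity(well_table([100.0], control_cpm=(40.0,),
                                          background_cpm=(50.0,)))


class TestCpmConversion:
    def test_zero_and_unit_arithmetic(self):
        assert cpm_to_product(0.0, 100.0, 10.0) == 0.0
        assert np.isclose(cpm_to_product(1000.0, 100.0, 10.0), 1000.0)

    def test_round_trip_with_generator_conversion(self):
        product_nM = 480.0
        cpm = product_nM * 10.0 * 100.0 / 1000.0
        assert np.isclose(cpm_to_product(cpm, 100.0, 10.0), product_nM)

    def test_bad_conversion_rejected(self):
        with pytest.raises(ValueError):
            cpm_to_product(10.0, 0.0, 10.0)


class TestKcat:
    def test_single_endpoint_through_origin(self):
        """120 nM product at 1 h from 20 nM enzyme -> kcat 6 /h."""
        res = fit_kcat([1.0], [120.0], 20.0)
        assert np.isclose(res.kcat, 6.0)
        assert res.flag == "single_point"

    def test_zero_product(self):
        assert fit_kcat([0.5, 1.0], [0.0, 0.0], 20.0).kcat == 0.0

    def test_noiseless_slope_oracle(self):
        t = np.array([0.25, 0.5, 0.75, 1.0])
        res = fit_kcat(t, 480.0 * t, 20.0)
        assert abs(res.kcat - 24.0) < 1e-9

    def test_linearity_in_product_and_enzyme(self, rng):
        t = np.linspace(0.1, 1.0, 6)
        p = 200.0 * t + rng.normal(0, 5, 6)
        k1 = fit_kcat(t, p, 20.0).kcat
        assert np.isclose(fit_kcat(t, 2 * p, 20.0).kcat, 2 * k1)
        assert np.isclose(fit_kcat(t, p, 40.0).kcat, k1 / 2)

    def test_negative_slope_clipped_and_flagged(self):
        res = fit_kcat([0.25, 0.5, 1.0], [300.0, 200.0, 100.0], 20.0)
        assert res.kcat == 0.0
        assert res.flag == "non_positive_slope"


class TestFoldChange:
    def test_printed_kcat_pairs(self):
        """Activation ratios from the turnover table: 20/9 and 1.5/0.7."""
        mk = lambda k, s: KineticResult(k, s, "peptide", "I363M")
        assert np.isclose(fold_change(mk(20, 1), mk(9, 1)).ratio, 20 / 9)
        mkn = lambda k, s: KineticResult(k, s, "nucleosome", "I363M")
        assert np.isclose(fold_change(mkn(1.5, 0.02), mkn(0.7, 0.04)).ratio, 1.5 / 0.7)

    def test_self_ratio_is_one(self):
        a = KineticResult(9.0, 1.0, "peptide", "I363M")
        assert fold_change(a, a).ratio == 1.0

    def test_error_propagation(self):
        a = KineticResult(20.0, 1.0, "peptide", "I363M")
        b = KineticResult(10.0, 0.5, "peptide", "I363M")
        fc = fold_change(a, b)
        assert np.isclose(fc.sd, 2.0 * np.sqrt(0.05**2 + 0.05**2))

    def test_substrate_mismatch_rejected(self):
        a = KineticResult(20.0, 1.0, "peptide", "I363M")
        b = KineticResult(10.0, 0.5, "nucleosome", "I363M")
        with pytest.raises(ComparisonError):
            fold_change(a, b)


class TestDoseResponse:
    def fourpl_points(self, ec50=2.3, bottom=100.0, top=240.0, hill=1.0, reps=3):
        conc = np.repeat(np.geomspace(0.0316, 100.0, 8), reps)
        return conc, four_pl(conc, bottom, top, ec50, hill)

    def test_noiseless_recovery(self):
        conc, pct = self.fourpl_points()
        fit = fit_dose_response(conc, pct)
        assert abs(fit.ec50 - 2.3) < 1e-6
        assert fit.direction == "activation"

    def test_midpoint_identity(self):
        conc, pct = self.fourpl_points()
        fit = fit_dose_response(conc, pct)
        mid = fit.predict(fit.ec50)
        assert np.isclose(mid, (fit.top + fit.bottom) / 2, atol=1e-6)

    def test_inhibition_direction(self):
        conc, pct = self.fourpl_points(bottom=100.0, top=10.0)
        assert fit_dose_response(conc, pct).direction == "inhibition"

    def test_gridsearch_oracle_on_noisy_fixture(self, rng):
        conc, pct = self.fourpl_points()
        noisy = pct * (1 + 0.03 * rng.standard_normal(pct.size))
        fit = fit_dose_response(conc, noisy)

        # coarse exhaustive minimization over (ec50, hill), plateaus by lsq
        def sse(ec50, hill):
            x = 1.0 / (1.0 + (ec50 / conc) ** hill)
            a = np.vstack([np.ones_like(x), x]).T
            coef, res, *_ = np.linalg.lstsq(a, noisy, rcond=None)
            return np.sum((a @ coef - noisy) ** 2)

        grid_e = np.geomspace(0.5, 10, 200)
        grid_h = np.linspace(0.5, 2.0, 60)
        sses = [[sse(e, h) for h in grid_h] for e in grid_e]
        best_e = grid_e[np.unravel_index(np.argmin(sses), (200, 60))[0]]
        assert abs(fit.ec50 - best_e) / best_e < 0.05

    def test_parameter_recovery_ensemble(self, rng):
        """200 simulated noisy datasets: median EC50 within 10%, SD on the
        same scale as the reported ±0.4 µM uncertainty."""
        fits = []
        for _ in range(200):
            conc, pct = self.fourpl_points()
            noisy = pct * (1 + 0.03 * rng.standard_normal(pct.size))
            fits.append(fit_dose_response(conc, noisy).ec50)
        fits = np.array(fits)
        assert abs(np.median(fits) - 2.3) / 2.3 < 0.10
        assert 0.05 < fits.std() < 0.8

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            fit_dose_response([1.0, 2.0, 4.0, 8.0], [10, 20, 40, 60])


class TestFpBinding:
    def test_quadratic_matches_root_finder(self):
        """P=100, L=40, Kd=50 (nM): closed form vs brentq on mass action."""
        p_tot, l_tot, kd = 100.0, 40.0, 50.0
        fb = float(bound_fraction(p_tot, l_tot, kd))

        def mass_action(pl):
            return (p_tot - pl) * (l_tot - pl) - kd * pl

        pl_root = optimize.brentq(mass_action, 0.0, min(p_tot, l_tot))
        assert np.isclose(fb, pl_root / l_tot, atol=1e-10)

    def test_hyperbolic_limit_half_saturation_at_kd(self):
        kd = 200.0
        fb = bound_fraction(kd, 1e-6, kd)
        assert np.isclose(fb, 0.5, atol=1e-6)

    def test_reduces_to_hyperbola_for_trace_tracer(self):
        kd = 200.0
        p = np.geomspace(10, 2000, 8)
        fb = bound_fraction(p, kd / 100.0, kd)
        hyp = p / (p + kd)
        assert np.abs(fb / hyp - 1).max() < 0.01

    def test_noiseless_kd_recovery(self):
        kd, tracer = 156.0, 40.0
        p = 2000.0 / 2 ** np.arange(12)
        fp = 50.0 + 200.0 * bound_fraction(p, tracer, kd)
        fit = fit_fp_binding(p, fp, tracer)
        assert abs(fit.kd - kd) / kd < 1e-3
        assert np.isclose(fit.fp_min, 50.0, atol=1e-6)

    def test_fitted_curve_nondecreasing(self):
        p = 2000.0 / 2 ** np.arange(12)
        fp = 50.0 + 200.0 * bound_fraction(p, 40.0, 156.0)
        fit = fit_fp_binding(p, fp, 40.0)
        pred = fit.predict(np.sort(p))
        assert np.all(np.diff(pred) >= -1e-9)

    def test_unsaturated_titration_flagged(self):
        kd = 50000.0  # far above the top of the titration
        p = 2000.0 / 2 ** np.arange(12)
        fp = 50.0 + 200.0 * bound_fraction(p, 40.0, kd)
        fit = fit_fp_binding(p, fp, 40.0)
        assert fit.flag == "wide_interval"
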