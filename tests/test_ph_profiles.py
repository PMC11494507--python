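"""Activity-pH models, apparent-pKa fits, rate tables, computed profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ribomech.lfer_thermo import ThermoContext, relative_rate_from_barriers
from ribomech.ph_profiles import (
    ActivityProfile,
    MechanismModel,
    PHRateDataset,
    build_computed_profile,
    fit_ph_profile,
    k_int_from_point,
    model_double_pka,
    model_single_pka,
    normalize_profiles,
    relative_rate_table,
    round_sig,
)
from ribomech.synthetic_data import gen_ph_rate_data

PH_GRID = np.arange(5.5, 8.51, 0.5)


class TestSinglePkaModel:
    def test_half_protonation_at_pka(self):
        assert model_single_pka(6.4, 1.0, 6.4) == pytest.approx(0.5, rel=1e-12)

    def test_low_ph_limit(self):
        assert model_single_pka(3.4, 1.0, 6.4) == pytest.approx(1.0, abs=1e-3)

    def test_curve_passes_through_measured_rate(self):
        # intrinsic rate back-solved so pKa 6.4 reproduces 0.60 /min at pH 6
        k_int = k_int_from_point(0.60, 6.0, 6.4)
        assert model_single_pka(6.0, k_int, 6.4) == pytest.approx(0.60, rel=1e-12)
        assert k_int == pytest.approx(0.839, abs=0.001)

    @given(st.floats(0.0, 14.0), st.floats(0.0, 14.0))
    def test_monotone_non_increasing(self, p1, p2):
        lo, hi = sorted((p1, p2))
        assert model_single_pka(hi, 1.0, 6.4) <= model_single_pka(lo, 1.0, 6.4)

    @given(st.floats(3.0, 11.0))
    def test_never_exceeds_intrinsic_rate(self, ph):
        assert model_single_pka(ph, 0.84, 6.4) <= 0.84


class TestDoublePkaModel:
    def test_reduces_to_single_when_nucleophile_always_ionized(self):
        ph = PH_GRID
        double = model_double_pka(ph, 1.0, 6.4, -20.0)
        single = model_single_pka(ph, 1.0, 6.4)
        np.testing.assert_allclose(double, single, atol=1e-8)

    def test_half_suppression_at_nucleophile_pka(self):
        v = model_double_pka(3.0, 1.0, 6.4, 3.0)
        assert v == pytest.approx(0.5 * model_single_pka(3.0, 1.0, 6.4), rel=1e-12)

    def test_bell_maximum_between_the_two_pkas(self):
        # symmetric factors peak midway; verified against a dense grid
        pka_acid, pka_nuc = 7.0, 3.0
        ph = np.linspace(0.0, 14.0, 14001)
        v = model_double_pka(ph, 1.0, pka_acid, pka_nuc)
        assert ph[np.argmax(v)] == pytest.approx((pka_acid + pka_nuc) / 2, abs=2e-3)

    def test_warns_when_pkas_inverted(self):
        with pytest.warns(UserWarning, match="pKa_nuc"):
            model_double_pka(6.0, 1.0, 4.0, 7.0)

    def test_unimodality(self):
        v = model_double_pka(np.linspace(1, 13, 1201), 1.0, 7.5, 3.5)
        d = np.diff(v)
        sign_changes = np.sum(np.diff(np.sign(d[np.abs(d) > 1e-15])) != 0)
        assert sign_changes <= 1


class TestFitPhProfile:
    @pytest.mark.parametrize("pka_true", [6.4, 6.5])
    def test_noise_free_recovery(self, pka_true):
        ds = gen_ph_rate_data(0.84, pka_true, PH_GRID, cv=0.0, n_reps=1, seed=0)
        fit = fit_ph_profile(ds, "single_pka")
        assert fit.converged and not fit.ph_independent
        assert fit.pka_acid == pytest.approx(pka_true, abs=1e-4)
        assert fit.k_int == pytest.approx(0.84, rel=1e-4)

    def test_flat_data_flagged_unidentifiable(self):
        # pH-independent rates: no ionization in the measured window
        ds = gen_ph_rate_data(4.4e-5, 20.0, PH_GRID, cv=0.1, n_reps=3, seed=5)
        fit = fit_ph_profile(ds, "single_pka")
        assert fit.ph_independent

    def test_all_equal_rates_flagged(self):
        df = pd.DataFrame({"pH": PH_GRID, "k_obs": 0.5, "replicate": 0})
        fit = fit_ph_profile(PHRateDataset("flat", df))
        assert fit.ph_independent and not fit.converged

    def test_recovery_within_three_se(self):
        hits = 0
        for seed in range(1, 26):
            ds = gen_ph_rate_data(0.84, 6.4, PH_GRID, cv=0.1, n_reps=3, seed=seed)
            fit = fit_ph_profile(ds)
            if abs(fit.pka_acid - 6.4) < 3 * fit.se_pka_acid:
                hits += 1
        assert hits >= 23  # ~99.7% expected; allow slack at n=25

    def test_double_pka_fit_recovers_both(self):
        ds = gen_ph_rate_data(1.0, 7.0, np.arange(3.0, 10.51, 0.5),
                              cv=0.0, n_reps=1, seed=0, pka_nuc=4.0)
        fit = fit_ph_profile(ds, "double_pka")
        assert fit.pka_acid == pytest.approx(7.0, abs=1e-3)
        assert fit.pka_nuc == pytest.approx(4.0, abs=1e-3)

    def test_too_few_ph_values_rejected(self):
        df = pd.DataFrame({"pH": [6.0, 6.5, 7.0], "k_obs": [0.5, 0.3, 0.2],
                           "replicate": 0})
        with pytest.raises(ValueError, match="distinct pH"):
            fit_ph_profile(PHRateDataset("x", df))


class TestRelativeRateTable:
    @pytest.fixture()
    def rates(self):
        return pd.DataFrame({
            "variant": ["C10/A63", "C10/A63", "A63 n7c", "C10 n1c"],
            "pH": [6.0, 7.5, 6.0, 6.0],
            "k_mean": [0.6, 0.019, 5.1, 4.4e-5],
        })

    def test_printed_cells(self, rates):
        out = relative_rate_table(rates, ("C10/A63", 6.0))
        by = out.set_index(["variant", "pH"])["rel_rate_display"]
        assert by[("C10/A63", 6.0)] == 1.0
        assert by[("A63 n7c", 6.0)] == 8.5
        assert by[("C10 n1c", 6.0)] == pytest.approx(7.3e-5, rel=1e-12)
        assert by[("C10/A63", 7.5)] == pytest.approx(0.032, rel=1e-12)

    def test_unit_invariance(self, rates):
        out1 = relative_rate_table(rates, ("C10/A63", 6.0))
        scaled = rates.assign(k_mean=rates["k_mean"] * 1e3)  # /min -> /s-ish
        out2 = relative_rate_table(scaled, ("C10/A63", 6.0))
        np.testing.assert_allclose(out1["rel_rate"], out2["rel_rate"], rtol=1e-12)

    def test_missing_reference_errors(self, rates):
        with pytest.raises(ValueError, match="reference"):
            relative_rate_table(rates, ("missing", 6.0))

    def test_round_sig(self):
        assert round_sig(0.86666, 2) == 0.87
        assert round_sig(8.4999, 2) == 8.5
        assert round_sig(7.33e-5, 2) == pytest.approx(7.3e-5, rel=1e-12)


class TestMechanismModel:
    @pytest.mark.parametrize("soln, shift, expected", [
        (4.2, 2.1, 6.3), (11.4, 5.2, 16.6), (3.7, 2.9, 6.6), (4.2, 2.1, 6.3),
    ])
    def test_pka_chain_by_construction(self, soln, shift, expected):
        mm = MechanismModel("v", 16.0, 1.0, 1.0, soln, shift)
        assert mm.pka_ribozyme == pytest.approx(expected, abs=1e-12)


class TestComputedProfiles:
    def test_half_maximum_at_ribozyme_pka(self):
        from ribomech.lfer_thermo import eyring_rate
        mm = MechanismModel("MTR1", 16.3, 1.0, 1.0, 4.2, 2.1)
        curve = build_computed_profile(mm, ph_grid=np.arange(4.0, 9.001, 0.001))
        # at pH = ribozyme pKa (6.3) the rate is exactly half the intrinsic rate
        k_int = eyring_rate(16.3, ThermoContext())
        at_pka = curve.rate[np.argmin(np.abs(curve.ph - 6.3))]
        assert at_pka == pytest.approx(k_int / 2, rel=1e-9)

    def test_equal_parameters_identical_curves(self):
        a = build_computed_profile(MechanismModel("a", 16.0, 1, 1, 4.0, 2.0))
        b = build_computed_profile(MechanismModel("b", 16.0, 1, 1, 4.0, 2.0))
        np.testing.assert_array_equal(a.rate, b.rate)

    def test_low_ph_ratio_matches_barrier_ratio(self):
        # internal consistency with the TST conversion
        mtr1 = build_computed_profile(MechanismModel("MTR1", 16.3, 1, 1, 4.2, 2.1),
                                      ph_grid=[4.0])
        var = build_computed_profile(MechanismModel("c5n", 15.7, 1, 1, 3.7, 2.9),
                                     ph_grid=[4.0])
        ratio = var.rate[0] / mtr1.rate[0]
        expected = relative_rate_from_barriers(16.3, 15.7, ThermoContext())
        # protonation factors at pH 4 differ slightly (pKa 6.3 vs 6.6)
        f1 = 1 / (1 + 10 ** (4.0 - 6.3))
        f2 = 1 / (1 + 10 ** (4.0 - 6.6))
        assert ratio == pytest.approx(expected * f2 / f1, rel=1e-10)

    def test_normalization_scalar(self):
        ph = np.arange(5.0, 9.01, 0.1)
        expt = ActivityProfile(ph, model_single_pka(ph, 0.6, 6.4))
        comp = ActivityProfile(ph, 2.0 * model_single_pka(ph, 0.6, 6.4))
        scaled, scalar = normalize_profiles(comp, expt)
        assert scalar == pytest.approx(0.5, rel=1e-12)
        np.testing.assert_allclose(scaled.rate, expt.rate, rtol=1e-12)

    def test_identical_curves_scalar_one(self):
        ph = np.arange(5.0, 9.01, 0.1)
        c = ActivityProfile(ph, model_single_pka(ph, 0.6, 6.4))
        _, scalar = normalize_profiles(c, c)
        assert scalar == 1.0

    def test_reference_scalar_applied_to_other_variant(self):
        # the scalar from the reference variant, not the variant's own,
        # rescales a second computed curve — rate ratios are preserved
        ph = np.arange(5.0, 9.01, 0.1)
        expt = ActivityProfile(ph, model_single_pka(ph, 0.6, 6.4))
        comp_ref = ActivityProfile(ph, 4.0 * model_single_pka(ph, 0.6, 6.4))
        comp_var = ActivityProfile(ph, 4.0 * model_single_pka(ph, 1.2, 6.6))
        _, scalar = normalize_profiles(comp_ref, expt)
        var_scaled = ActivityProfile(comp_var.ph, comp_var.rate * scalar)
        assert var_scaled.max() == pytest.approx(comp_var.max() / comp_ref.max()
                                                 * expt.max(), rel=1e-12)

    def test_zero_maximum_rejected(self):
        ph = np.arange(5.0, 6.01, 0.5)
        with pytest.raises(ValueError, match="zero maximum"):
            normalize_profiles(ActivityProfile(ph, np.zeros_like(ph)),
                               ActivityProfile(ph, np.ones_like(ph)))


def test_dataset_validation():
    with pytest.raises(ValueError, match="positive"):
        PHRateDataset("x", pd.DataFrame(
            {"pH": [6.0], "k_obs": [-0.1], "replicate": [0]}))
    with pytest.raises(ValueError, match="pH"):
        PHRateDataset("x", pd.DataFrame(
            {"pH": [15.0], "k_obs": [0.1], "replicate": [0]}))
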