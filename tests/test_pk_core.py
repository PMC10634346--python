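"""One-compartment infusion model, pooled fitting and unit conversions."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad, solve_ivp

from cdk9pkpd import (
    BindingConstants,
    ConcentrationProfile,
    DoseEvent,
    OneCompartmentParams,
    SyntheticConfig,
    concentration_at,
    fit_one_compartment,
    generate_pk_profiles,
    mass_to_molar,
    molar_to_mass,
    round_sig,
    to_unbound,
)


class TestConcentrationAt:
    def test_zero_before_and_at_infusion_start(self, reference_params, clinical_dose):
        assert concentration_at(reference_params, clinical_dose, 0.0) == 0.0

    def test_steady_state_plateau_for_long_infusion(self, reference_params):
        # with Tinf -> infinity the plateau is R0/CL
        dose = DoseEvent(dose_mg=30.0, infusion_h=10_000.0)
        c = concentration_at(reference_params, dose, 10_000.0)
        assert c == pytest.approx(dose.rate_ug_per_h / reference_params.clearance, rel=1e-6)

    def test_matches_ode_integration(self, reference_params, clinical_dose):
        """Closed form vs numerical integration of dA/dt = R0·1(t<=Tinf) − kA."""
        k = reference_params.elimination_rate
        r0 = clinical_dose.rate_ug_per_h
        tinf = clinical_dose.infusion_h

        def rhs(t, y):
            return [(r0 if t <= tinf else 0.0) - k * y[0]]

        t_grid = np.linspace(0.01, 24.0, 120)
        sol = solve_ivp(rhs, (0.0, 24.0), [0.0], t_eval=t_grid, rtol=1e-10,
                        atol=1e-12, max_step=0.25)
        oracle = sol.y[0] / reference_params.volume
        ours = concentration_at(reference_params, clinical_dose, t_grid)
        assert np.allclose(ours, oracle, rtol=1e-6)

    def test_continuous_at_end_of_infusion(self, reference_params, clinical_dose):
        tinf = clinical_dose.infusion_h
        eps = 1e-9
        left = concentration_at(reference_params, clinical_dose, tinf - eps)
        right = concentration_at(reference_params, clinical_dose, tinf + eps)
        assert left == pytest.approx(right, rel=1e-6)

    def test_superposition_doubling_dose_doubles_concentration(self, reference_params):
        t = np.linspace(0.0, 24.0, 50)
        c1 = concentration_at(reference_params, DoseEvent(30.0, 0.5), t)
        c2 = concentration_at(reference_params, DoseEvent(60.0, 0.5), t)
        assert np.allclose(c2, 2.0 * c1, rtol=1e-12)

    def test_auc_infinity_equals_dose_over_clearance(self, reference_params, clinical_dose):
        # 200 h is ~58 half-lives here; the truncated tail is negligible
        auc, _ = quad(
            lambda t: concentration_at(reference_params, clinical_dose, t),
            0.0, 200.0, points=[clinical_dose.infusion_h], limit=200,
        )
        expected = clinical_dose.dose_ug / reference_params.clearance
        assert auc == pytest.approx(expected, rel=1e-3)

    def test_negative_time_rejected(self, reference_params, clinical_dose):
        with pytest.raises(ValueError):
            concentration_at(reference_params, clinical_dose, -1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            OneCompartmentParams(clearance=-1.0, volume=50.0)
        with pytest.raises(ValueError):
            OneCompartmentParams(clearance=10.0, volume=0.0)
        with pytest.raises(ValueError):
            DoseEvent(dose_mg=30.0, infusion_h=0.0)


class TestFitOneCompartment:
    def test_noise_free_fit_is_exact_fixed_point(self, clinical_dose):
        truth = OneCompartmentParams(clearance=10.3, volume=30.0)
        times = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0])
        profiles = [
            ConcentrationProfile(f"s{i}", clinical_dose, times,
                                 concentration_at(truth, clinical_dose, times))
            for i in range(3)
        ]
        for weighting in ("uniform", "proportional"):
            res = fit_one_compartment(profiles, weighting=weighting)
            assert res.converged
            assert res.params.clearance == pytest.approx(10.3, rel=1e-6)
            assert res.params.volume == pytest.approx(30.0, rel=1e-6)

    def test_noisy_pooled_fit_recovers_clearance(self):
        """15 subjects, 20% proportional noise: CL back within 10% of truth."""
        cfg = SyntheticConfig(seed=42, n_subjects=15, pk_bsv_cv=(0.0, 0.0))
        profiles, _ = generate_pk_profiles(cfg)
        res = fit_one_compartment(profiles)
        assert res.converged
        assert res.params.clearance == pytest.approx(cfg.pk_truth.clearance, rel=0.10)

    def test_optimizer_beats_coarse_grid_search(self, clinical_dose):
        """Brute-force (CL, V) grid never undercuts the optimizer's objective."""
        cfg = SyntheticConfig(seed=7, n_subjects=4)
        profiles, _ = generate_pk_profiles(cfg)
        res = fit_one_compartment(profiles, weighting="uniform")

        t = np.concatenate([p.times for p in profiles])
        y = np.concatenate([p.concentrations for p in profiles])
        mask = t > 0
        t, y = t[mask], y[mask]

        def objective(cl, v):
            pred = concentration_at(OneCompartmentParams(cl, v), clinical_dose, t)
            return float(np.sum((y - pred) ** 2))

        grid_best = min(
            objective(cl, v)
            for cl, v in itertools.product(np.linspace(4, 25, 40), np.linspace(20, 150, 40))
        )
        assert res.objective <= grid_best + 1e-9

    def test_reports_cv_percent_for_both_parameters(self):
        cfg = SyntheticConfig(seed=5, n_subjects=10)
        profiles, _ = generate_pk_profiles(cfg)
        res = fit_one_compartment(profiles)
        assert set(res.cv_percent) == {"clearance", "volume"}
        assert all(np.isfinite(v) and v > 0 for v in res.cv_percent.values())

    def test_degenerate_single_time_design_rejected(self, clinical_dose):
        prof = ConcentrationProfile("s", clinical_dose, np.array([1.0]), np.array([100.0]))
        with pytest.raises(ValueError, match="degenerate"):
            fit_one_compartment([prof])


class TestConversions:
    def test_media_unbound_concentration_matches_reported_arithmetic(self):
        # 250 nmol/L at 66.6 % unbound in media -> 166.5, reported rounded 167
        raw = to_unbound(250.0, 0.666)
        assert raw == pytest.approx(166.5)
        assert round_sig(raw, 3) == 167.0

    def test_plasma_unbound_cmax_raw_product(self):
        # 1750 nmol/L at fu 6.65 % -> 116.375 (displayed as 117)
        assert to_unbound(1750.0, 0.0665) == pytest.approx(116.375)

    def test_fu_of_one_is_identity(self):
        assert to_unbound(123.4, 1.0) == pytest.approx(123.4)

    def test_fu_out_of_range_rejected(self):
        for fu in (0.0, -0.1, 1.2):
            with pytest.raises(ValueError):
                to_unbound(100.0, fu)

    def test_mass_molar_unit_identity(self):
        assert mass_to_molar(0.0, 404.4) == 0.0
        assert mass_to_molar(404.4, 404.4) == pytest.approx(1000.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        conc=st.floats(min_value=1e-6, max_value=1e6),
        mw=st.floats(min_value=50.0, max_value=2000.0),
    )
    def test_mass_molar_round_trip(self, conc, mw):
        assert molar_to_mass(mass_to_molar(conc, mw), mw) == pytest.approx(conc, rel=1e-12)

    def test_nonpositive_molecular_weight_rejected(self):
        with pytest.raises(ValueError):
            mass_to_molar(1.0, 0.0)
        with pytest.raises(ValueError):
            BindingConstants(molecular_weight=-1.0)

    @pytest.mark.parametrize(
        "x,sig,expected",
        [(708.4667, 3, 708.0), (5.6864, 3, 5.69), (2965.0, 4, 2965.0),
         (0.5204, 3, 0.52), (116.375, 3, 116.0), (166.5, 3, 167.0)],
    )
    def test_half_up_significant_figure_rounding(self, x, sig, expected):
        assert round_sig(x, sig) == expected


class TestProfileValidation:
    def test_unsorted_times_rejected(self, clinical_dose):
        with pytest.raises(ValueError):
            ConcentrationProfile("s", clinical_dose, np.array([0.0, 2.0, 1.0]),
                                 np.array([0.0, 1.0, 2.0]))

    def test_negative_concentration_rejected(self, clinical_dose):
        with pytest.raises(ValueError):
            ConcentrationProfile("s", clinical_dose, np.array([0.0, 1.0]),
                                 np.array([0.0, -5.0]))

    def test_length_mismatch_rejected(self, clinical_dose):
        with pytest.raises(ValueError):
            ConcentrationProfile("s", clinical_dose, np.array([0.0, 1.0]),
                                 np.array([1.0]))


class TestConcentrationCsvRoundTrip:
    def test_write_then_read_preserves_profiles(self, tmp_path, clinical_dose):
        from cdk9pkpd import read_concentration_csv, write_concentration_csv

        cfg = SyntheticConfig(seed=11, n_subjects=3)
        profiles, _ = generate_pk_profiles(cfg)
        path = tmp_path / "conc.csv"
        write_concentration_csv(profiles, path)
        back = read_concentration_csv(path)
        assert [p.subject_id for p in back] == [p.subject_id for p in profiles]
        for a, b in zip(profiles, back):
            assert np.allclose(a.times, b.times)
            assert np.allclose(a.concentrations, b.concentrations)
            assert a.dose == b.dose
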