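"""Two-site ThT equilibrium solver and titration fits."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amyloidvs import (BindingParams, displacement_fraction,
                       fit_competition_titration, fit_dilution,
                       fit_direct_titration, fit_global, fit_replicates,
                       fit_two_phase, one_site_bound, predict_intensity,
                       simulate_intensities, solve_equilibrium, synth_titration)
from amyloidvs.synthetic_data import default_truth_params


def _params(**kw):
    base = dict(eps_f_phi_f=1.0, eps_b_phi_b=10.0, kd_tht=1e-6, kd_l=1e-7,
                s1_tot=0.5e-6, s2_tot=0.0)
    base.update(kw)
    return BindingParams(**base)


class TestSolveEquilibrium:
    def test_matches_single_site_quadratic(self):
        st_ = solve_equilibrium(1e-6, 0.0, _params())
        assert st_.tht_s1 * 1e6 == pytest.approx(0.21922, abs=5e-6)
        assert st_.tht_s1 == pytest.approx(one_site_bound(1e-6, 0.5e-6, 1e-6), abs=1e-16)

    def test_no_tht_decouples_to_competitor_quadratic(self):
        p = _params(s1_tot=1e-6)
        st_ = solve_equilibrium(0.0, 2e-6, p)
        assert st_.tht_free == st_.tht_s1 == st_.tht_s2 == 0.0
        assert st_.l_s1 == pytest.approx(one_site_bound(2e-6, 1e-6, p.kd_l), rel=1e-12)

    def test_tight_competitor_displaces_completely(self):
        p = _params(kd_l=1e-15, s2_tot=0.0)
        st_ = solve_equilibrium(1e-6, 1e-6, p)  # l_tot >= s1_tot
        assert st_.tht_s1 < 1e-8 * p.s1_tot

    def test_conservation_on_random_draws(self, rng):
        for _ in range(200):
            p = _params(kd_tht=10 ** rng.uniform(-8, -4),
                        kd_l=10 ** rng.uniform(-9, -5),
                        s1_tot=10 ** rng.uniform(-8, -5),
                        s2_tot=10 ** rng.uniform(-8, -5))
            st_ = solve_equilibrium(10 ** rng.uniform(-8, -4),
                                    10 ** rng.uniform(-9, -4), p)
            assert max(st_.residuals.values()) < 1e-12
            assert min(st_.tht_free, st_.l_free, st_.s1_free, st_.s2_free,
                       st_.tht_s1, st_.tht_s2, st_.l_s1) >= 0.0

    def test_bound_tht_monotone_in_competitor(self):
        p = _params(s2_tot=0.3e-6)
        prev = math.inf
        for l_tot in np.linspace(0.0, 5e-6, 30):
            b = solve_equilibrium(1e-6, l_tot, p).tht_s1
            assert b <= prev + 1e-18
            prev = b

    def test_intensity_monotone_in_tht_when_bound_brighter(self):
        p = _params()
        vals = [predict_intensity(solve_equilibrium(t, 1e-7, p), p)
                for t in np.linspace(0.0, 5e-6, 25)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_negative_totals_rejected(self):
        with pytest.raises(ValueError):
            solve_equilibrium(-1e-9, 0.0, _params())


class TestPredictIntensity:
    def test_no_tht_gives_zero(self):
        st_ = solve_equilibrium(0.0, 1e-6, _params())
        assert predict_intensity(st_, _params()) == 0.0

    def test_equal_responses_conserve_total(self):
        p = _params(eps_f_phi_f=3.0, eps_b_phi_b=3.0)
        st_ = solve_equilibrium(1e-6, 0.0, p)
        assert predict_intensity(st_, p) == pytest.approx(3.0 * 1e-6, rel=1e-12)

    def test_closed_form_example(self):
        p = _params(eps_f_phi_f=1e6, eps_b_phi_b=1e7)  # 1 and 10 AU/uM
        st_ = solve_equilibrium(1e-6, 0.0, p)
        assert predict_intensity(st_, p) == pytest.approx(2.97302, abs=5e-5)

    def test_symmetric_competition_splits_site1_evenly(self):
        p = _params(kd_l=1e-6, s2_tot=0.0)  # kd_l == kd_tht
        st_ = solve_equilibrium(1e-6, 1e-6, p)
        assert st_.tht_s1 == pytest.approx(st_.l_s1, rel=1e-10)


class TestDilutionFit:
    def test_two_point_slope(self):
        pts = pd.DataFrame({"phase": ["dilution"] * 2, "tht_tot_M": [0.0, 1e-6],
                            "intensity_au": [0.0, 2.0]})
        assert fit_dilution(pts) == pytest.approx(2e6)

    def test_exact_linear_recovered_to_machine_precision(self):
        t = np.linspace(0, 2e-6, 8)
        pts = pd.DataFrame({"phase": "dilution", "tht_tot_M": t,
                            "intensity_au": 5e9 * t})
        assert fit_dilution(pts) == pytest.approx(5e9, rel=1e-12)

    def test_noisy_slope_within_three_percent(self, rng):
        t = np.linspace(0, 2e-6, 20)
        i = 5e9 * t + rng.normal(0, 0.01 * 5e9 * 2e-6, size=t.size)
        pts = pd.DataFrame({"phase": "dilution", "tht_tot_M": t, "intensity_au": i})
        assert fit_dilution(pts) == pytest.approx(5e9, rel=0.03)

    def test_singular_design_rejected(self):
        pts = pd.DataFrame({"phase": ["dilution"] * 3, "tht_tot_M": [0.0] * 3,
                            "intensity_au": [0.0] * 3})
        with pytest.raises(ValueError):
            fit_dilution(pts)


class TestTitrationFits:
    def test_noiseless_direct_recovers_kd_tht(self, truth_params, noiseless_titration):
        fit = fit_direct_titration(noiseless_titration, truth_params.eps_f_phi_f)
        assert fit.converged
        assert fit.fitted["log10_kd_tht"] == pytest.approx(-6.7, abs=0.01)
        assert fit.fitted["s_tot"] == pytest.approx(5e-7, rel=0.01)

    def test_noiseless_competition_recovers_kd_l(self, truth_params, noiseless_titration):
        fit = fit_competition_titration(noiseless_titration, truth_params)
        assert fit.fitted["log10_kd_l"] == pytest.approx(-7.6, abs=0.01)
        assert not fit.flags

    def test_two_phase_pipeline_noiseless(self, noiseless_titration):
        fit = fit_two_phase(noiseless_titration)
        assert fit.fitted["log10_kd_tht"] == pytest.approx(-6.7, abs=0.01)
        assert fit.fitted["log10_kd_l"] == pytest.approx(-7.6, abs=0.01)

    def test_competition_identifies_absent_second_site(self):
        # truth has every site competed away: plateau at zero bound signal
        truth = BindingParams(5e9, 1e12, 10 ** -6.7, 10 ** -7.6, 5e-7, 0.0)
        df = synth_titration(truth, noise_sd=0.0, seed=0)
        seq = fit_two_phase(df, float_split=True)
        assert seq.params.s2_tot == pytest.approx(0.0, abs=0.02 * 5e-7)

    def test_all_zero_intensities_flagged_degenerate(self):
        df = pd.DataFrame({
            "phase": ["dilution"] * 3 + ["direct"] * 5,
            "tht_tot_M": [0, 1e-6, 2e-6] + list(np.linspace(0, 3e-6, 5)),
            "l_tot_M": 0.0, "intensity_au": 0.0})
        fit = fit_direct_titration(df, eps_f_phi_f=0.0)
        assert any("degenerate" in f for f in fit.flags)
        assert fit.params.eps_b_phi_b == 0.0

    def test_flat_competition_response_flagged_unidentifiable(self, truth_params):
        # competitor far too weak to displace anything over the schedule
        weak = BindingParams(truth_params.eps_f_phi_f, truth_params.eps_b_phi_b,
                             truth_params.kd_tht, 1e-1, truth_params.s1_tot,
                             truth_params.s2_tot)
        df = synth_titration(weak, noise_sd=0.0, seed=0)
        fit = fit_competition_titration(df, weak)
        assert any("unidentifiable" in f for f in fit.flags)

    def test_replicate_dispersion_ci(self, truth_params):
        dfs = [synth_titration(truth_params, noise_sd=0.02, seed=100 + k,
                               replicate_id=f"r{k}") for k in range(3)]
        fit = fit_replicates(pd.concat(dfs, ignore_index=True))
        assert fit.uncertainty_kind == "replicate-dispersion"
        lo, hi = fit.ci95["log10_kd_l"]
        assert lo <= fit.fitted["log10_kd_l"] <= hi
        assert len(fit.replicate_fits) == 3

    def test_global_fit_round_trip_reproduces_curve(self, truth_params):
        df = synth_titration(truth_params, noise_sd=0.02, seed=42)
        fit = fit_global(df)
        resim = synth_titration(fit.params, noise_sd=0.0, seed=0)
        mask = df["phase"] != "dilution"
        scale = df["intensity_au"].max()
        resid = (df.loc[mask, "intensity_au"].to_numpy()
                 - resim.loc[mask, "intensity_au"].to_numpy())
        # residuals at the injected-noise floor (2% of range), not above ~3x
        assert np.abs(resid).max() < 0.06 * scale


class TestDisplacementFraction:
    def test_single_site_fully_displaced(self):
        assert displacement_fraction(_params(s2_tot=0.0), 1e-6) == pytest.approx(1.0)

    def test_equal_dilute_sites_half_displaced(self):
        p = _params(s1_tot=1e-9, s2_tot=1e-9)
        assert displacement_fraction(p, 1e-6) == pytest.approx(0.5, abs=1e-3)

    def test_matches_brute_force_large_competitor(self, rng):
        for _ in range(20):
            p = _params(kd_tht=10 ** rng.uniform(-7.5, -5.5),
                        kd_l=10 ** rng.uniform(-9, -6),
                        s1_tot=10 ** rng.uniform(-8, -6),
                        s2_tot=10 ** rng.uniform(-8, -6))
            tht_tot = 10 ** rng.uniform(-7, -5.5)
            base = solve_equilibrium(tht_tot, 0.0, p).tht_bound
            brute = solve_equilibrium(tht_tot, 1e6 * p.kd_l, p).tht_bound
            assert displacement_fraction(p, tht_tot) == pytest.approx(
                1.0 - brute / base, abs=1e-4)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(tht=st.floats(min_value=0, max_value=1e-4),
       l=st.floats(min_value=0, max_value=1e-4),
       kt=st.floats(min_value=-8, max_value=-4),
       kl=st.floats(min_value=-9, max_value=-4),
       s1=st.floats(min_value=0, max_value=1e-5),
       s2=st.floats(min_value=0, max_value=1e-5))
def test_solver_conservation_property(tht, l, kt, kl, s1, s2):
    p = BindingParams(1.0, 10.0, 10 ** kt, 10 ** kl, s1, s2)
    state = solve_equilibrium(tht, l, p)
    assert max(state.residuals.values()) < 1e-12
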