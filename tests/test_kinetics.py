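import numpy as np
import pytest
from oracles import grid_search_progress, ols_line

from serpinkit import (
    KineticScenario,
    correct_association_constant,
    fit_kobs_vs_inhibitor,
    fit_progress_curve,
    run_association_pipeline,
    simulate_progress_curves,
)
from serpinkit.errors import DegenerateDataError, DomainError, InputError
from serpinkit.kinetics import irreversible_progress

from conftest import make_curve


class TestFitProgressCurve:
    def test_recovers_generating_parameters_noiseless(self, noiseless_curve):
        fit = fit_progress_curve(noiseless_curve)
        assert fit.converged
        assert fit.v0 == pytest.approx(1e-3, rel=1e-6)
        assert fit.kobs == pytest.approx(5e-3, rel=1e-6)

    def test_linear_limit_gives_zero_kobs(self):
        t = np.linspace(0, 1200, 61)
        curve = make_curve("line", t, 1e-3 * t)
        fit = fit_progress_curve(curve)
        assert fit.kobs <= 1e-6
        assert fit.v0 == pytest.approx(1e-3, rel=1e-4)

    def test_matches_grid_search_oracle_on_noisy_curve(self):
        # seeded noisy curve; oracle = dense RSS grid computed independently
        v0_true, kobs_true = 1e-3, 4e-3
        t = np.linspace(0, 1200, 61)
        plateau = v0_true / kobs_true
        rng = np.random.default_rng(7)
        y = (v0_true / kobs_true) * (1 - np.exp(-kobs_true * t)) + rng.normal(
            0, 0.02 * plateau, t.size
        )
        curve = make_curve("noisy", t, y)
        fit = fit_progress_curve(curve, fit_baseline=False)

        v0_grid = np.linspace(0.8e-3, 1.2e-3, 241)
        kobs_grid = np.linspace(3e-3, 5e-3, 241)
        v0_star, kobs_star = grid_search_progress(t, y, v0_grid, kobs_grid)
        assert abs(fit.v0 - v0_star) <= v0_grid[1] - v0_grid[0]
        assert abs(fit.kobs - kobs_star) <= kobs_grid[1] - kobs_grid[0]

    def test_baseline_offset_estimated_and_recovered(self):
        t = np.linspace(0, 1200, 61)
        clean = 0.3 + (1e-3 / 5e-3) * (1 - np.exp(-5e-3 * t))
        fit = fit_progress_curve(make_curve("offset", t, clean))
        assert fit.baseline == pytest.approx(0.3, abs=1e-6)
        assert fit.kobs == pytest.approx(5e-3, rel=1e-5)

    def test_too_few_points(self):
        with pytest.raises(InputError):
            fit_progress_curve(make_curve("short", [0, 1, 2, 3], [0, 1, 2, 3]))

    def test_constant_signal_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_progress_curve(make_curve("flat", [0, 1, 2, 3, 4], [1, 1, 1, 1, 1]))

    def test_model_limits(self, noiseless_curve):
        # P(inf) = v0/kobs and dP/dt|0 = v0 for any returned fit
        fit = fit_progress_curve(noiseless_curve)
        big_t = 1e9
        assert irreversible_progress(big_t, fit.v0, fit.kobs) == pytest.approx(
            fit.plateau, rel=1e-9
        )
        eps = 1e-6
        slope0 = irreversible_progress(eps, fit.v0, fit.kobs) / eps
        assert slope0 == pytest.approx(fit.v0, rel=1e-6)


class TestKobsRegression:
    def test_exact_line_through_origin(self):
        conc = [1e-7, 2e-7, 5e-7, 1e-6]
        pts = [(c, 2.0e4 * c) for c in conc]
        slope, intercept, r2 = fit_kobs_vs_inhibitor(pts)
        assert slope == pytest.approx(2.0e4)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_affine_shift_preserves_slope(self):
        conc = [1e-7, 2e-7, 5e-7, 1e-6]
        pts = [(c, 2.0e4 * c + 1e-4) for c in conc]
        slope, intercept, _ = fit_kobs_vs_inhibitor(pts)
        assert slope == pytest.approx(2.0e4)
        assert intercept == pytest.approx(1e-4)

    def test_matches_closed_form_ols_oracle(self):
        rng = np.random.default_rng(21)
        conc = np.linspace(1e-7, 1e-6, 8)
        kobs = 3.0e4 * conc + rng.normal(0, 1e-4, conc.size)
        slope, intercept, _ = fit_kobs_vs_inhibitor(list(zip(conc, kobs)))
        o_slope, o_intercept = ols_line(conc, kobs)
        assert slope == pytest.approx(o_slope, rel=1e-12)
        assert intercept == pytest.approx(o_intercept, rel=1e-9)

    def test_insufficient_points(self):
        with pytest.raises(InputError):
            fit_kobs_vs_inhibitor([(1e-7, 1e-3), (2e-7, 2e-3)])
        with pytest.raises(InputError):
            fit_kobs_vs_inhibitor([(1e-7, 1e-3)] * 5)


class TestCompetitionCorrection:
    def test_paper_scale_arithmetic(self):
        # inverting ka = k'app*(1+[S]/Km) at [S]=200 µM, Km=114 µM
        assert correct_association_constant(3.0497e4, 200e-6, 114e-6) == pytest.approx(
            8.4e4, rel=1e-3
        )

    def test_no_substrate_means_no_correction(self):
        assert correct_association_constant(5.0e4, 0.0, 114e-6) == 5.0e4

    def test_substrate_at_km_doubles(self):
        assert correct_association_constant(5.0e4, 114e-6, 114e-6) == pytest.approx(1.0e5)

    def test_km_must_be_positive(self):
        with pytest.raises(DomainError):
            correct_association_constant(1e4, 1e-4, 0.0)

    @pytest.mark.parametrize("km", [50e-6, 114e-6, 270e-6])
    def test_strictly_increasing_in_substrate(self, km):
        subs = np.linspace(0, 1e-3, 25)
        vals = [correct_association_constant(1e4, s, km) for s in subs]
        assert np.all(np.diff(vals) > 0)

    def test_strictly_decreasing_in_km(self):
        kms = np.linspace(10e-6, 1e-3, 25)
        vals = [correct_association_constant(1e4, 200e-6, k) for k in kms]
        assert np.all(np.diff(vals) < 0)


class TestPipeline:
    def test_noiseless_exact_recovery(self, hne_scenario):
        curves = simulate_progress_curves(hne_scenario)
        fit = run_association_pipeline(curves, km=hne_scenario.km)
        assert fit.ka == pytest.approx(hne_scenario.ka_true, rel=1e-4)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert len(fit.curve_fits) == 6

    def test_noisy_recovery_within_5pct(self, hne_scenario):
        import dataclasses

        s = dataclasses.replace(hne_scenario, noise_sd_frac=0.02, seed=11)
        fit = run_association_pipeline(simulate_progress_curves(s), km=s.km)
        assert fit.ka == pytest.approx(s.ka_true, rel=0.05)

    def test_ka_invariant_holds(self, hne_scenario):
        fit = run_association_pipeline(simulate_progress_curves(hne_scenario), km=hne_scenario.km)
        assert fit.ka == fit.kapp_prime * (1 + fit.substrate_conc / fit.km)

    def test_single_concentration_rejected(self, hne_scenario):
        curves = simulate_progress_curves(hne_scenario)[:1]
        with pytest.raises(InputError):
            run_association_pipeline(curves, km=hne_scenario.km)

    def test_mixed_substrate_rejected(self, hne_scenario):
        curves = simulate_progress_curves(hne_scenario)
        curves[0].substrate_conc = 100.0
        with pytest.raises(InputError):
            run_association_pipeline(curves, km=hne_scenario.km)

    def test_substoichiometric_inhibitor_warns(self, hne_scenario):
        import dataclasses

        s = dataclasses.replace(
            hne_scenario,
            inhibitor_concs=[5e-8, 4e-7, 8e-7, 1.2e-6],
        )
        with pytest.warns(UserWarning, match="pseudo-first-order"):
            run_association_pipeline(simulate_progress_curves(s), km=s.km)

    def test_zero_inhibitor_curves_excluded(self, hne_scenario):
        curves = simulate_progress_curves(hne_scenario)
        t = curves[0].times
        curves.append(make_curve("uninhibited", t, 1e-3 * t, inhibitor_uM=0.0))
        fit = run_association_pipeline(curves, km=hne_scenario.km)
        assert len(fit.points) == 6


@pytest.mark.parametrize("ka_true", [1e3, 1e4, 1e5, 1e6, 1e7])
def test_parameter_recovery_across_log_grid(ka_true):
    """Noiseless pipeline recovers any generating ka in [1e3, 1e7]."""
    enzyme = 2e-7
    km, sub = 114e-6, 200e-6
    comp = 1 + sub / km
    kobs_min = ka_true * enzyme / comp
    s = KineticScenario(
        ka_true=ka_true,
        km=km,
        substrate_conc=sub,
        enzyme_conc=enzyme,
        inhibitor_concs=[enzyme * m for m in (1, 2, 4, 6, 8, 10)],
        duration=6.0 / kobs_min,
        n_timepoints=301,
        noise_sd_frac=0.0,
        seed=0,
    )
    fit = run_association_pipeline(simulate_progress_curves(s), km=km)
    assert fit.ka == pytest.approx(ka_true, rel=1e-4)
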