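"""Tests for CRM/EWOC dose-selection rules, scheme constraints, and the
trial engine."""

import math

import numpy as np
import pytest

from dosegrid.designs import (
    DoseScheme,
    FeasibilitySchedule,
    STUDY_SCHEMES,
    apply_scheme_constraints,
    crm_next_dose,
    ewoc_next_dose,
    get_scheme,
    next_alpha,
    run_trial,
)
from dosegrid.model import (
    ModelParams,
    ModelSpace,
    PriorSpec,
    TrialHistory,
    canonical_from_reparam,
    link_cdf,
    posterior_update,
)
from dosegrid.truth import calibrate_truth

RES = (64, 64)


class TestSchemes:
    def test_study_scheme_sizes(self):
        sizes = {name: s.size for name, s in STUDY_SCHEMES.items() if s.mode == "discrete"}
        assert sizes == {"d0.05": 21, "d0.10": 11, "d0.125": 9, "d0.20": 6, "d0.25": 5}

    def test_schemes_span_the_dose_interval(self):
        for name, s in STUDY_SCHEMES.items():
            if s.mode == "discrete":
                assert s.doses[0] == 0.0 and s.doses[-1] == 1.0
                assert np.all(np.diff(s.doses) > 0)

    def test_rounding_nearest(self):
        d = get_scheme("d0.10")
        assert d.round_dose(0.37) == pytest.approx(0.40)
        assert d.round_dose(0.05) == pytest.approx(0.0)  # exact tie goes down
        assert d.round_dose(-0.3) == 0.0
        assert d.round_dose(1.7) == 1.0

    def test_rounding_down(self):
        d = DoseScheme.equally_spaced(0.10, rounding="down")
        assert d.round_dose(0.37) == pytest.approx(0.30)
        assert d.round_dose(0.30) == pytest.approx(0.30)

    def test_unknown_scheme_name(self):
        with pytest.raises(ValueError):
            get_scheme("d0.33")


class TestSchemeConstraints:
    def test_rounding_then_no_skip_cap(self):
        scheme = get_scheme("d0.10")
        history = TrialHistory([(0.0, 0), (0.1, 0), (0.2, 0)])
        # candidate 0.50 rounds onto the grid but exceeds highest + 1
        assert apply_scheme_constraints(0.50, scheme, history) == pytest.approx(0.30)

    def test_first_patient_capped_at_lowest_dose(self):
        scheme = get_scheme("d0.10")
        assert apply_scheme_constraints(0.8, scheme, TrialHistory()) == 0.0

    def test_de_escalation_unrestricted(self):
        scheme = get_scheme("d0.10")
        history = TrialHistory([(0.0, 0), (0.1, 0), (0.2, 1), (0.3, 1)])
        assert apply_scheme_constraints(0.0, scheme, history) == 0.0

    def test_continuous_passthrough(self):
        scheme = DoseScheme.continuous()
        assert apply_scheme_constraints(0.4321, scheme, TrialHistory()) == 0.4321

    def test_no_skip_off(self):
        scheme = DoseScheme.equally_spaced(0.10, no_skip=False)
        history = TrialHistory([(0.0, 0)])
        assert apply_scheme_constraints(0.50, scheme, history) == pytest.approx(0.50)


class TestFeasibilitySchedule:
    def test_advance_on_no_dlt(self):
        sched = FeasibilitySchedule(0.05, 0.05)
        assert next_alpha(sched, 0.05, 0) == pytest.approx(0.10)

    def test_hold_on_dlt(self):
        sched = FeasibilitySchedule(0.05, 0.05)
        assert next_alpha(sched, 0.10, 1) == pytest.approx(0.10)

    def test_cap(self):
        sched = FeasibilitySchedule(0.05, 0.05, cap=0.5)
        assert next_alpha(sched, 0.50, 0) == pytest.approx(0.50)

    def test_full_no_dlt_sequence(self):
        sched = FeasibilitySchedule(0.05, 0.05, cap=0.5)
        alphas = [0.05]
        for _ in range(12):
            alphas.append(next_alpha(sched, alphas[-1], 0))
        expected = [0.05 + 0.05 * k for k in range(10)] + [0.5, 0.5, 0.5]
        assert np.allclose(alphas, expected)

    def test_unconditional_variant_advances_on_dlt(self):
        sched = FeasibilitySchedule(0.25, 0.05, conditional=False)
        assert next_alpha(sched, 0.25, 1) == pytest.approx(0.30)


def concentrated_grid(space, rho0, gamma, resolution=RES):
    """Posterior sharply concentrated near (rho0, gamma): many DLT-free
    and DLT observations pin the curve only approximately, so build the
    grid directly with near-delta weights at the closest node."""
    prior = PriorSpec()
    grid = posterior_update(prior, TrialHistory(), space, resolution)
    i = int(np.argmin(np.abs(grid.rho0_nodes - rho0)))
    j = int(np.argmin(np.abs(grid.gamma_nodes - gamma)))
    w = np.zeros_like(grid.weights)
    w[i, j] = 1.0
    from dosegrid.model import PosteriorGrid

    return PosteriorGrid(
        rho0_nodes=grid.rho0_nodes, gamma_nodes=grid.gamma_nodes, weights=w, space=space
    )


class TestCrmNextDose:
    def test_continuous_returns_gamma_estimate(self, space):
        grid = concentrated_grid(space, 0.10, 0.42, resolution=(64, 250))
        dose = crm_next_dose(grid, DoseScheme.continuous(), space)
        assert dose == pytest.approx(0.42, abs=1 / 250)

    def test_discrete_brute_force_objective(self, space):
        # plug-in estimates (0.1, 0.42) scanned over D0.20 by |theta - F|
        rho0_hat, gamma_hat = 0.1, 0.42
        coef = canonical_from_reparam(ModelParams(rho0_hat, gamma_hat), space)
        doses = np.array(STUDY_SCHEMES["d0.20"].doses)
        brute = doses[np.argmin(np.abs(0.33 - link_cdf(coef.beta0 + coef.beta1 * doses)))]
        assert brute == pytest.approx(0.40)
        grid = concentrated_grid(space, 0.10, 0.42, resolution=(64, 250))
        assert crm_next_dose(grid, STUDY_SCHEMES["d0.20"], space) == pytest.approx(0.40)

    def test_clipping_at_x_max(self, space, uniform_prior):
        # history of all-safe outcomes at the top dose pushes the
        # estimate toward x_max; recommendation must stay in bounds
        h = TrialHistory([(1.0, 0)] * 10)
        grid = posterior_update(uniform_prior, h, space, RES)
        dose = crm_next_dose(grid, DoseScheme.continuous(), space)
        assert dose <= space.x_max


class TestEwocNextDose:
    def test_uniform_prior_first_quantile(self, space, uniform_prior):
        grid = posterior_update(uniform_prior, TrialHistory(), space, RES)
        assert ewoc_next_dose(grid, 0.05, DoseScheme.continuous()) == pytest.approx(
            0.05, abs=1e-9
        )

    def test_discrete_rounding_of_quantile(self, space, uniform_prior):
        grid = posterior_update(uniform_prior, TrialHistory(), space, RES)
        # quantile 0.05 sits exactly midway on D0.10; the tie goes down
        assert ewoc_next_dose(grid, 0.05, get_scheme("d0.10")) == pytest.approx(0.0)
        assert ewoc_next_dose(grid, 0.06, get_scheme("d0.10")) == pytest.approx(0.10)

    def test_nondecreasing_in_alpha(self, space, uniform_prior):
        h = TrialHistory([(0.2, 0), (0.4, 1)])
        grid = posterior_update(uniform_prior, h, space, RES)
        for scheme in (DoseScheme.continuous(), get_scheme("d0.10")):
            doses = [ewoc_next_dose(grid, a, scheme) for a in np.linspace(0.05, 0.95, 19)]
            assert np.all(np.diff(doses) >= 0)


class TestRunTrial:
    def test_first_dose_is_x_min(self, space, rng):
        truth = calibrate_truth("logistic", 0.1, 0.4, space)
        for design in ("crm", "ewoc"):
            result = run_trial(design, truth, DoseScheme.continuous(), 1, rng,
                               resolution=RES)
            assert len(result.history) == 1
            assert result.history.doses[0] == space.x_min

    def test_all_dlt_truth_freezes_alpha(self, rng, space):
        class AlwaysToxic:
            x_min, x_max = 0.0, 1.0
            theta = 0.33
            def prob(self, x):
                return 1.0
        result = run_trial("ewoc", AlwaysToxic(), DoseScheme.continuous(), 8, rng,
                           resolution=RES)
        assert all(a == pytest.approx(0.05) for a in result.alphas)
        assert result.history.dlts.sum() == 8

    def test_administered_doses_belong_to_scheme(self, space, rng):
        truth = calibrate_truth("logistic", 0.1, 0.6, space)
        scheme = get_scheme("d0.125")
        result = run_trial("ewoc", truth, scheme, 25, rng, resolution=RES)
        for d in result.history.doses:
            assert any(abs(d - s) < 1e-12 for s in scheme.doses)

    @pytest.mark.parametrize("design", ["crm", "ewoc"])
    def test_no_skip_escalation_steps(self, space, design):
        truth = calibrate_truth("logistic", 0.1, 0.8, space)
        scheme = get_scheme("d0.10")
        rng = np.random.default_rng(11)
        result = run_trial(design, truth, scheme, 30, rng, resolution=RES)
        idx = [scheme.index_of(d) for d in result.history.doses]
        assert max(np.diff(idx)) <= 1

    def test_reproducible_from_seed(self, space):
        truth = calibrate_truth("normal", 0.05, 0.4, space)
        r1 = run_trial("ewoc", truth, get_scheme("d0.05"), 15,
                       np.random.default_rng(5), resolution=RES)
        r2 = run_trial("ewoc", truth, get_scheme("d0.05"), 15,
                       np.random.default_rng(5), resolution=RES)
        assert r1.history.records == r2.history.records
        assert r1.mtd_estimate == r2.mtd_estimate

    def test_overdose_control_ordering(self, space):
        # EWOC with a small feasibility bound administers lower doses on
        # average than the same trials run at a fixed alpha = 0.5
        truth = calibrate_truth("logistic", 0.1, 0.4, space)
        scheme = DoseScheme.continuous()
        cautious = FeasibilitySchedule(0.05, 0.05)
        median_rule = FeasibilitySchedule(0.5, 0.0, cap=0.5)
        mean_dose = {}
        for name, sched in (("c05", cautious), ("fixed50", median_rule)):
            doses = []
            for rep in range(120):
                rng = np.random.default_rng(np.random.SeedSequence([9, rep]))
                r = run_trial("ewoc", truth, scheme, 20, rng, schedule=sched,
                              resolution=RES)
                doses.append(r.history.doses.mean())
            mean_dose[name] = np.mean(doses)
        assert mean_dose["c05"] <= mean_dose["fixed50"]

    def test_posterior_concentration_recommends_truth(self, space):
        # long trial under a known curve: final estimate near the MTD
        truth = calibrate_truth("logistic", 0.1, 0.4, space)
        rng = np.random.default_rng(2)
        r = run_trial("crm", truth, DoseScheme.continuous(), 60, rng,
                      resolution=(64, 128))
        assert abs(r.mtd_estimate - 0.4) < 0.15

    def test_cohort_size_groups_doses(self, space, rng):
        truth = calibrate_truth("logistic", 0.1, 0.4, space)
        r = run_trial("ewoc", truth, get_scheme("d0.10"), 9, rng,
                      resolution=RES, cohort_size=3)
        doses = r.history.doses
        for start in range(0, 9, 3):
            assert len(set(doses[start:start + 3])) == 1

    def test_invalid_inputs(self, space, rng):
        truth = calibrate_truth("logistic", 0.1, 0.4, space)
        with pytest.raises(ValueError):
            run_trial("boin", truth, DoseScheme.continuous(), 5, rng, resolution=RES)
        with pytest.raises(ValueError):
            run_trial("crm", truth, DoseScheme.continuous(), 0, rng, resolution=RES)
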