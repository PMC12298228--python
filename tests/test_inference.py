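"""Fitting machinery, identifiability profiles and sensitivity coefficients."""

import numpy as np
import pytest

from losartan_pkpd import (
    AnalysisError,
    ConcentrationSeries,
    DoseRegimen,
    FitProblem,
    ObservationDesign,
    fit_parameters,
    identifiability_profile,
    model_sensitivity,
    objective,
    recovery_harness,
    sensitivity_ss,
    simulate,
    two_stage_fit,
)


def toy_problem(model_fn, observed_by_label, bounds, shared=(), local=(), seed=0):
    datasets = [
        (label, ConcentrationSeries(times=t, C_p=cp, C_m=cm))
        for label, (t, cp, cm) in observed_by_label.items()
    ]
    return FitProblem(
        datasets=datasets,
        base_params={label: {} for label, _ in datasets},
        dose=DoseRegimen(dose_mg=50.0),
        bounds=bounds,
        shared_parameters=tuple(shared),
        local_parameters=tuple(local),
        seed=seed,
        model_fn=model_fn,
    )


def linear_model(params, times):
    """C_p = p * t, C_m = q * t — a cheap stand-in for the simulator."""
    t = np.asarray(times, float)
    return params["p"] * t, params["q"] * t


class TestObjective:
    def test_zero_loss_on_noise_free_data(self, gg_params, dose50, fast_solver):
        times = np.array([0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0])
        truth = simulate(gg_params, dose50, t_end=12.0, t_eval=times, **fast_solver)
        problem = FitProblem(
            datasets=[("d", truth)],
            base_params={"d": gg_params},
            dose=dose50,
            bounds={"k_m": (0.01, 30.0)},
            local_parameters=("k_m",),
            solver_kwargs=fast_solver,
        )
        assert objective(problem, {"k_m[d]": gg_params.k_m}) < 1e-10

    def test_invariant_to_dataset_order(self):
        t = np.array([1.0, 2.0, 3.0])
        obs = {
            "a": (t, 2.0 * t, 3.0 * t),
            "b": (t, 1.0 * t, 5.0 * t),
        }
        bounds = {"p": (0.1, 10.0), "q": (0.1, 10.0)}
        values = {"p": 1.5, "q": 2.5}
        p1 = toy_problem(linear_model, obs, bounds, shared=("p", "q"))
        p2 = toy_problem(linear_model, dict(reversed(obs.items())), bounds, shared=("p", "q"))
        assert objective(p1, values) == objective(p2, values)

    def test_matches_hand_summed_residuals(self):
        t = np.array([1.0, 2.0, 3.0])
        obs = {"d": (t, np.array([2.0, 3.0, 7.0]), np.array([1.0, 1.0, 1.0]))}
        problem = toy_problem(
            linear_model, obs, {"p": (0.1, 10.0), "q": (0.1, 10.0)}, shared=("p", "q")
        )
        values = {"p": 2.0, "q": 0.5}
        # C_p residuals: (2-2, 4-3, 6-7); C_m residuals: (0.5-1, 1-1, 1.5-1)
        expected = (0.0 + 1.0 + 1.0) + (0.25 + 0.0 + 0.25)
        assert objective(problem, values) == pytest.approx(expected, rel=1e-12)


class TestFit:
    def _quadratic_problem(self, seed=0):
        t = np.array([1.0, 2.0, 4.0, 8.0])
        truth = {"p": 2.5, "q": 0.8}
        cp, cm = linear_model(truth, t)
        return toy_problem(
            linear_model,
            {"d": (t, cp, cm)},
            {"p": (0.01, 100.0), "q": (0.01, 100.0)},
            shared=("p", "q"),
            seed=seed,
        ), truth

    def test_recovers_toy_truth(self):
        problem, truth = self._quadratic_problem()
        res = fit_parameters(problem, maxiter=60, popsize=10)
        assert res.values["p"] == pytest.approx(truth["p"], rel=1e-4)
        assert res.values["q"] == pytest.approx(truth["q"], rel=1e-4)

    def test_deterministic_under_seed(self):
        p1, _ = self._quadratic_problem(seed=42)
        p2, _ = self._quadratic_problem(seed=42)
        r1 = fit_parameters(p1, maxiter=20, popsize=8)
        r2 = fit_parameters(p2, maxiter=20, popsize=8)
        assert r1.values == r2.values and r1.loss == r2.loss

    def test_bounds_respected_for_every_candidate(self):
        seen = []

        def recording_model(params, times):
            seen.append((params["p"], params["q"]))
            return linear_model(params, times)

        t = np.array([1.0, 2.0, 3.0])
        cp, cm = linear_model({"p": 2.0, "q": 1.0}, t)
        problem = toy_problem(
            recording_model,
            {"d": (t, cp, cm)},
            {"p": (0.5, 4.0), "q": (0.2, 2.0)},
            shared=("p", "q"),
        )
        fit_parameters(problem, maxiter=15, popsize=6)
        arr = np.array(seen)
        assert arr[:, 0].min() >= 0.5 - 1e-9 and arr[:, 0].max() <= 4.0 + 1e-9
        assert arr[:, 1].min() >= 0.2 - 1e-9 and arr[:, 1].max() <= 2.0 + 1e-9


class TestTwoStage:
    def test_stage_two_builds_on_stage_one(self):
        """Stage 1 pins the first rate with the second fixed; stage 2 fixes
        the stage-1 estimate and recovers the second."""
        t = np.array([1.0, 2.0, 4.0])
        truth = {"p": 2.5, "q": 0.8}
        cp, cm = linear_model(truth, t)
        obs = ConcentrationSeries(times=t, C_p=cp, C_m=cm)

        def problem(fit_names, base):
            return FitProblem(
                datasets=[("d", obs)],
                base_params={"d": base},
                dose=DoseRegimen(dose_mg=50.0),
                bounds={n: (0.01, 100.0) for n in fit_names},
                shared_parameters=tuple(fit_names),
                seed=0,
                model_fn=linear_model,
            )

        stage1 = problem(("p",), {"q": truth["q"]})
        res1, res2 = two_stage_fit(
            stage1,
            lambda r: problem(("q",), {"p": r.values["p"]}),
            maxiter=40, popsize=8,
        )
        assert res1.values["p"] == pytest.approx(truth["p"], rel=1e-3)
        assert res2.values["q"] == pytest.approx(truth["q"], rel=1e-3)


class TestIdentifiability:
    def test_product_parameters_are_unidentifiable(self):
        # observations depend only on the product p*q: profiles stay flat
        def product_model(params, times):
            t = np.asarray(times, float)
            c = params["p"] * params["q"] * t
            return c, c

        t = np.array([1.0, 2.0, 4.0])
        cp, cm = product_model({"p": 2.0, "q": 3.0}, t)
        problem = toy_problem(
            product_model,
            {"d": (t, cp, cm)},
            {"p": (0.05, 200.0), "q": (0.05, 200.0)},
            shared=("p", "q"),
        )
        fitted = {"p": 2.0, "q": 3.0}
        for name in ("p", "q"):
            prof = identifiability_profile(
                problem, fitted, name, np.geomspace(0.2, 60.0, 9), abs_threshold=1e-6
            )
            assert prof.classification == "unidentifiable"

    def test_saturating_parameter_is_partially_identifiable(self):
        # output saturates in x: loss rises only below the plateau
        def sat_model(params, times):
            t = np.asarray(times, float)
            c = 10.0 * t * params["x"] / (1.0 + params["x"])
            return c, c

        t = np.array([1.0, 2.0, 3.0])
        cp, cm = sat_model({"x": 1e4}, t)
        problem = toy_problem(
            sat_model, {"d": (t, cp, cm)}, {"x": (1e-3, 1e7)}, shared=("x",)
        )
        prof = identifiability_profile(
            problem, {"x": 1e4}, "x", np.geomspace(0.01, 1e6, 11), abs_threshold=1e-3
        )
        assert prof.classification == "partially identifiable"

    def test_conversion_rate_identifiable_from_rich_data(self, gg_params, dose50, fast_solver):
        times = np.array([0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0])
        truth = simulate(gg_params, dose50, t_end=12.0, t_eval=times, **fast_solver)
        problem = FitProblem(
            datasets=[("d", truth)],
            base_params={"d": gg_params},
            dose=dose50,
            bounds={"k_m": (0.01, 30.0)},
            local_parameters=("k_m",),
            solver_kwargs=fast_solver,
        )
        fitted = {"k_m[d]": gg_params.k_m}
        prof = identifiability_profile(
            problem, fitted, "k_m[d]", np.geomspace(0.5, 15.0, 7), abs_threshold=1.0
        )
        assert prof.classification == "identifiable"
        # profile at the optimum equals the fitted loss
        assert prof.fitted_loss == pytest.approx(objective(problem, fitted), rel=1e-12)

    def test_grid_must_bracket_the_optimum(self):
        problem = toy_problem(
            linear_model,
            {"d": (np.array([1.0]), np.array([2.0]), np.array([1.0]))},
            {"p": (0.1, 10.0), "q": (0.1, 10.0)},
            shared=("p", "q"),
        )
        with pytest.raises(AnalysisError):
            identifiability_profile(problem, {"p": 2.0, "q": 1.0}, "p", [3.0, 4.0, 5.0])


class TestSensitivity:
    def test_independent_output_has_zero_elasticity(self):
        res = sensitivity_ss(lambda v: 42.0, {"x": 3.0}, "x")
        assert res.ss == 0.0

    def test_unit_elasticity_for_linear_output(self):
        res = sensitivity_ss(lambda v: v["x"], {"x": 3.0}, "x", delta=1e-6)
        assert res.ss == pytest.approx(1.0, abs=1e-4)

    def test_quadratic_output_has_elasticity_two(self):
        res = sensitivity_ss(lambda v: v["x"] ** 2, {"x": 3.0}, "x", delta=1e-6)
        assert res.ss == pytest.approx(2.0, abs=1e-3)

    def test_zero_baseline_rejected(self):
        with pytest.raises(AnalysisError):
            sensitivity_ss(lambda v: 0.0, {"x": 1.0}, "x")

    def test_relative_mode_is_flagged(self, gg_params, dose50):
        res = model_sensitivity(
            gg_params, dose50, "CL_m", "AUC0inf_E3174", delta=1e-4, relative=True,
            horizon=24.0, rtol=1e-8, atol=1e-10,
        )
        assert res.relative_perturbation and res.delta == pytest.approx(1e-4 * gg_params.CL_m)
        # E-3174 clearance up -> metabolite exposure down, about unit elasticity
        assert res.ss == pytest.approx(-1.0, abs=0.15)


class TestRecovery:
    def test_noise_free_recovery_of_genotype_rates(self, dose50, gg_params):
        """Noise-free curves from two CYP2C9 genotypes pin down k_m tightly."""
        from losartan_pkpd import genotype_parameters

        truth = {
            "*1/*1": gg_params,
            "*3/*3": genotype_parameters("CYP2C9*3/CYP2C9*3", "GG/CC"),
        }
        design = ObservationDesign(
            sample_times=(0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 12.0),
            cv=0.0,
            n_subjects_per_genotype=1,
            seed=11,
        )
        report = recovery_harness(
            truth, dose50, design, local_parameters=("k_m",), seed=5,
            maxiter=25, popsize=8,
        )
        errs = report.rows.set_index("parameter")["rel_error"]
        assert (errs < 0.05).all()
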