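"""Baseline calibration and segment-wise trajectory estimation."""

import numpy as np
import pytest

from pyadapt import (AdaptSolution, GeneCouplingMap, LongitudinalDataset,
                     MetabolicModel, SolverSettings, build_ensemble,
                     calibrate_baseline, estimate_segment, fit_spline,
                     run_adapt)
from pyadapt.data import SdInterpolant


class TestCalibrateBaseline:
    def test_recovers_truth_from_noisefree_data(
            self, scenario_a_noisefree, baseline_fits_noisefree, p_true):
        best = baseline_fits_noisefree[0]
        assert best.sse < 1e-6
        assert np.all(np.abs(best.parameters - p_true) / p_true < 0.01)

    def test_keep_fraction_controls_local_run_count(
            self, scenario_a_noisefree, noisefree_data):
        fits = calibrate_baseline(scenario_a_noisefree.model, noisefree_data,
                                  n_scatter=100, keep_fraction=0.1,
                                  rng_seed=0)
        assert len(fits) <= 10
        assert len({f.start_index for f in fits}) == len(fits)

    def test_seeded_determinism(self, scenario_a_noisefree, noisefree_data):
        kw = dict(n_scatter=300, keep_fraction=0.1)
        a = calibrate_baseline(scenario_a_noisefree.model, noisefree_data,
                               rng_seed=5, **kw)
        b = calibrate_baseline(scenario_a_noisefree.model, noisefree_data,
                               rng_seed=5, **kw)
        assert [f.start_index for f in a] == [f.start_index for f in b]
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.parameters, fb.parameters)

    def test_results_sorted_by_sse(self, baseline_fits_noisefree):
        sses = [f.sse for f in baseline_fits_noisefree]
        assert sses == sorted(sses)


def one_state_decay_setup(rate=2.0):
    """Model dx/dt = -p x with data spline d(t) = e^{-rate t}."""
    model = MetabolicModel(
        state_names=["a"], parameter_names=["p1"],
        stoichiometry=[[-1]],
        fluxes=[{"name": "f1", "parameter": "p1", "substrates": ["a"]}],
        outputs=[{"name": "y_a", "expr": "a"}],
        parameter_bounds=[[0.0, 50.0]])
    t = np.linspace(0, 2, 25)
    spline = {"y_a": fit_spline(t, np.exp(-rate * t))}
    sigma = {"y_a": SdInterpolant(t, np.full(t.size, 0.05))}
    return model, spline, sigma


class TestEstimateSegment:
    def test_stationary_point_returns_initialization(
            self, scenario_a_noisefree, noisefree_data,
            baseline_fits_noisefree):
        model = scenario_a_noisefree.model
        p0 = baseline_fits_noisefree[0].parameters
        ens = build_ensemble(noisefree_data, 1, 0)
        sigma = {o: noisefree_data.sd_function(o)
                 for o in noisefree_data.observables
                 if o in model.output_names}
        x0 = model.initial_state(p0)
        p_hat, _, _, _, bd, ok = estimate_segment(
            model, x0, p0, p0[:, None], ens.splines[0], sigma,
            GeneCouplingMap([]), {}, (0.0, 0.0), 1, 0.42, p0)
        assert ok
        assert np.allclose(p_hat, p0, rtol=1e-6)
        assert bd.chi_d2 < 1e-10

    def test_recovers_decay_rate_each_segment(self):
        model, spline, sigma = one_state_decay_setup(rate=2.0)
        x = np.array([1.0])
        p = np.array([1.0])  # deliberately off-truth initialization
        dt = 0.2
        prefix = p[:, None]
        for n in range(1, 6):
            p, x, _, _, _, ok = estimate_segment(
                model, x, p, prefix, spline, sigma, GeneCouplingMap([]),
                {}, (0.0, 0.0), n, dt, np.array([1.0]))
            prefix = np.hstack([prefix, p[:, None]])
            assert ok
            assert p[0] == pytest.approx(2.0, abs=1e-3)

    def test_large_fluctuation_penalty_flattens_trajectory(self):
        model, spline, sigma = one_state_decay_setup(rate=2.0)
        coupling = GeneCouplingMap([("p1", "g1")])
        t = np.linspace(0, 2, 9)
        gene = {"g1": fit_spline(t, np.ones(t.size))}  # flat gene, G floored

        def run(lam2):
            x = np.array([1.0])
            p = np.array([1.0])
            prefix = p[:, None]
            for n in range(1, 6):
                p, x, _, _, _, _ = estimate_segment(
                    model, x, p, prefix, spline, sigma, coupling, gene,
                    (0.0, lam2), n, 0.2, np.array([1.0]))
                prefix = np.hstack([prefix, p[:, None]])
            return np.abs(np.diff(prefix[0])).sum()

        assert run(1e-6) < run(0.0)

    def test_invalid_segment_index(self, scenario_a_noisefree,
                                   baseline_fits_noisefree):
        model = scenario_a_noisefree.model
        p0 = baseline_fits_noisefree[0].parameters
        with pytest.raises(ValueError):
            estimate_segment(model, model.initial_state(p0), p0,
                             p0[:, None], {}, {}, GeneCouplingMap([]), {},
                             (0.0, 0.0), 0, 0.5, p0)


class TestRunAdapt:
    def test_single_segment_equals_one_estimate(self, scenario_a_noisefree,
                                                noisefree_data,
                                                baseline_fits_noisefree):
        model = scenario_a_noisefree.model
        p0 = baseline_fits_noisefree[0].parameters
        ens = build_ensemble(noisefree_data, 1, 0)
        sigma = {o: noisefree_data.sd_function(o)
                 for o in noisefree_data.observables
                 if o in model.output_names}
        sol = run_adapt(model, p0, ens.splines[0], sigma,
                        n_segments=1, t_end=21.0)
        p_hat, x_end, y_end, _, _, _ = estimate_segment(
            model, model.initial_state(p0), p0, p0[:, None], ens.splines[0],
            sigma, GeneCouplingMap([]), {}, (0.0, 0.0), 1, 21.0, p0)
        assert np.array_equal(sol.parameters[:, 1], p_hat)
        assert np.array_equal(sol.states[1], x_end)

    def test_step_change_recovered(self):
        # truth: decay rate steps from 1 to 3 halfway through
        model, _, _ = one_state_decay_setup()
        t_dense = np.linspace(0, 2, 401)
        x_dense = np.where(t_dense < 1.0, np.exp(-t_dense),
                           np.exp(-1.0) * np.exp(-3 * (t_dense - 1.0)))
        spline = {"y_a": fit_spline(t_dense, x_dense)}
        sigma = {"y_a": SdInterpolant(t_dense, np.full(t_dense.size, 0.05))}
        sol = run_adapt(model, np.array([1.0]), spline, sigma,
                        n_segments=20, t_end=2.0, x0=np.array([1.0]))
        assert sol.parameters[0, 2] == pytest.approx(1.0, rel=0.05)
        assert sol.parameters[0, -1] == pytest.approx(3.0, rel=0.05)

    def test_default_segment_count(self):
        model, spline, sigma = one_state_decay_setup()
        sol = run_adapt(model, np.array([2.0]), spline, sigma, t_end=2.0,
                        x0=np.array([1.0]))
        assert sol.parameters.shape == (1, 201)

    def test_zero_lambda_identical_to_uncoupled_path(
            self, scenarios):
        # the regularized code path at λ=(0,0) must match the plain
        # data-only path bit for bit
        import copy
        from pyadapt import generate_truth, generate_observations, \
            generate_gene_profiles
        scen = scenarios["A"]
        truth = generate_truth(scen)
        obs = generate_observations(truth, scen, 3)
        genes = generate_gene_profiles(scen, 3)
        fits = calibrate_baseline(scen.model, obs, n_scatter=400,
                                  keep_fraction=0.1, rng_seed=2)
        ens = build_ensemble(obs, 1, 1)
        g_ens = build_ensemble(genes, 1, 2)
        sigma = {o: obs.sd_function(o) for o in obs.observables
                 if o in scen.model.output_names}
        kw = dict(n_segments=10, t_end=21.0,
                  settings=SolverSettings(collocation_points=3))
        with_genes = run_adapt(scen.model, fits[0].parameters,
                               ens.splines[0], sigma, scen.coupling,
                               g_ens.splines[0], (0.0, 0.0), **kw)
        plain = run_adapt(scen.model, fits[0].parameters, ens.splines[0],
                          sigma, None, None, (0.0, 0.0), **kw)
        assert np.array_equal(with_genes.parameters, plain.parameters)
        assert np.array_equal(with_genes.states, plain.states)
        for bd in with_genes.objective_per_segment:
            assert bd.total == bd.chi_d2

    def test_objective_breakdown_identity(self, scenarios):
        from pyadapt import generate_truth, generate_observations, \
            generate_gene_profiles
        scen = scenarios["B"]
        truth = generate_truth(scen)
        obs = generate_observations(truth, scen, 5)
        genes = generate_gene_profiles(scen, 5)
        fits = calibrate_baseline(scen.model, obs, n_scatter=400,
                                  keep_fraction=0.1, rng_seed=2)
        ens = build_ensemble(obs, 1, 1)
        g_ens = build_ensemble(genes, 1, 2)
        sigma = {o: obs.sd_function(o) for o in obs.observables
                 if o in scen.model.output_names}
        sol = run_adapt(scen.model, fits[0].parameters, ens.splines[0],
                        sigma, scen.coupling, g_ens.splines[0],
                        (0.3, 1e-6), n_segments=6, t_end=21.0,
                        settings=SolverSettings(collocation_points=3))
        for bd in sol.objective_per_segment:
            expected = bd.chi_d2 + 0.3 * bd.chi_g1 + 1e-6 * bd.chi_g2
            assert bd.total == pytest.approx(expected, rel=1e-12)
            assert bd.chi_d2 >= 0 and bd.chi_g1 >= 0

    def test_solution_round_trip(self, tmp_path, scenario_a_noisefree,
                                 noisefree_data, baseline_fits_noisefree):
        model = scenario_a_noisefree.model
        p0 = baseline_fits_noisefree[0].parameters
        ens = build_ensemble(noisefree_data, 1, 0)
        sigma = {o: noisefree_data.sd_function(o)
                 for o in noisefree_data.observables
                 if o in model.output_names}
        sol = run_adapt(model, p0, ens.splines[0], sigma, n_segments=4,
                        t_end=21.0)
        sol.accepted = True
        sol.save(tmp_path, "sol")
        back = AdaptSolution.load(tmp_path / "sol.csv", tmp_path / "sol.json")
        assert np.allclose(back.parameters, sol.parameters)
        assert np.allclose(back.states, sol.states)
        assert back.lambda_pair == sol.lambda_pair
        assert back.accepted is True
        assert back.chi_sum("chi_d2") == pytest.approx(
            sol.chi_sum("chi_d2"), rel=1e-12, abs=1e-12)
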