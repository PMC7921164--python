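"""Synthetic scenario generators: truth, observations, gene profiles."""

import copy

import numpy as np
import pytest

from pyadapt import (LongitudinalDataset, MetabolicModel, benchmark_suite,
                     generate_gene_profiles, generate_observations,
                     generate_truth, pearson, simulate, toy_lipid_model,
                     trajectory_function, write_run_directory)
from pyadapt.estimation import GeneCouplingMap
from pyadapt.synthetic import SyntheticScenario, TRUE_BASELINE, _gene


class TestTrajectoryPrimitives:
    def test_constant(self):
        f = trajectory_function(2.0, {})
        assert np.allclose(f(np.linspace(0, 21, 5)), 2.0)

    def test_sigmoid_anchored_at_baseline(self):
        f = trajectory_function(2.0, {"type": "sigmoid", "factor": 3.0,
                                      "center": 5.0, "width": 1.0})
        assert f(0.0) == pytest.approx(2.0, rel=1e-12)
        assert f(21.0) == pytest.approx(6.0, rel=1e-3)
        t = np.linspace(0, 21, 100)
        assert np.all(np.diff(f(t)) > 0)

    def test_ramp_endpoints(self):
        f = trajectory_function(1.0, {"type": "ramp", "factor": 2.0,
                                      "start": 2.0, "end": 7.0})
        assert f(0.0) == 1.0 and f(2.0) == 1.0
        assert f(7.0) == pytest.approx(2.0)
        assert f(21.0) == pytest.approx(2.0)

    def test_unknown_type(self):
        with pytest.raises(ValueError):
            trajectory_function(1.0, {"type": "sawtooth"})


class TestGenerateTruth:
    def test_constant_scenario_is_stationary(self, scenarios):
        truth = generate_truth(scenarios["A"], n_fine=100)
        ptp = np.ptp(truth.states[:, :4], axis=0)
        assert np.all(ptp < 1e-6)

    def test_constant_params_equal_plain_simulate(self, scenarios, p_true):
        scen = scenarios["A"]
        truth = generate_truth(scen, n_fine=40)
        x0 = scen.model.initial_state(p_true)
        res = simulate(scen.model, x0, p_true, (0, 21.0), truth.times[1:])
        assert np.allclose(res.states, truth.states[1:], atol=1e-6)

    def test_step_scenario_reaches_post_step_steady_state(self):
        model = toy_lipid_model()
        scen = SyntheticScenario(
            name="step", model=model, baseline=dict(TRUE_BASELINE),
            trajectories={"k_dnl": {"type": "sigmoid", "factor": 3.0,
                                    "center": 1.0, "width": 0.2}},
            n_segments=42)
        truth = generate_truth(scen)
        p_end = scen.true_parameters([21.0])[:, 0]
        x_steady = model.initial_state(p_end)
        # everything except the accumulating sink reaches the new steady state
        rel = np.abs(truth.states[-1, :4] - x_steady[:4]) / x_steady[:4]
        assert np.max(rel) < 0.01

    def test_deterministic_without_seed(self, scenarios):
        a = generate_truth(scenarios["C"], n_fine=50)
        b = generate_truth(scenarios["C"], n_fine=50)
        assert np.array_equal(a.states, b.states)


class TestGenerateObservations:
    def test_zero_cv_reproduces_truth(self, scenario_a_noisefree):
        truth = generate_truth(scenario_a_noisefree)
        obs = generate_observations(truth, scenario_a_noisefree, 0)
        for i, name in enumerate(obs.observables):
            mask = np.isfinite(obs.means[i])
            expected = [truth.output_at(name, t) for t in obs.times[mask]]
            assert np.allclose(obs.means[i, mask], expected, rtol=1e-12)
        assert np.nanmax(obs.sds) == 0.0

    def test_seeded_determinism(self, scenarios):
        truth = generate_truth(scenarios["A"], n_fine=100)
        a = generate_observations(truth, scenarios["A"], 5)
        b = generate_observations(truth, scenarios["A"], 5)
        assert np.allclose(a.means, b.means, equal_nan=True)

    def test_means_center_on_truth_across_seeds(self, scenarios):
        scen = scenarios["A"]
        truth = generate_truth(scen, n_fine=100)
        v_true = truth.output_at("y_ffa", 7.0)
        j = int(np.where(scen.schedule == 7.0)[0][0])
        i = scen.model.output_names.index("y_ffa")
        means = [generate_observations(truth, scen, s).means[i, j]
                 for s in range(200)]
        se = scen.cv * v_true / np.sqrt(scen.replicates * 200)
        assert abs(np.mean(means) - v_true) < 3 * se

    def test_baseline_only_observable(self, scenarios):
        truth = generate_truth(scenarios["A"], n_fine=100)
        obs = generate_observations(truth, scenarios["A"], 1)
        i = obs.observables.index("y_cyt_er_ratio")
        assert np.isfinite(obs.means[i, 0])
        assert np.all(~np.isfinite(obs.means[i, 1:]))


class TestGeneProfiles:
    def make_scenario(self, **design):
        model = toy_lipid_model()
        return SyntheticScenario(
            name="g", model=model, baseline=dict(TRUE_BASELINE),
            trajectories={"k_dnl": {"type": "sigmoid", "factor": 3.0,
                                    "center": 3.0, "width": 1.0}},
            coupling=GeneCouplingMap([("k_dnl", "g1")]),
            gene_design={"g1": _gene("k_dnl", **design)},
            n_segments=42)

    def test_noiseless_gene_tracks_parameter_perfectly(self):
        scen = self.make_scenario(cv=0.0)
        genes = generate_gene_profiles(scen, 0)
        p = scen.true_parameters(scen.schedule)[
            scen.model.parameter_names.index("k_dnl")]
        rho = pearson(genes.means[0], p)
        assert rho == pytest.approx(1.0, abs=1e-12)
        assert genes.means[0, 0] == 1.0

    def test_negative_sign_anticorrelates(self):
        scen = self.make_scenario(cv=0.0, sign=-1.0, strength=0.2)
        genes = generate_gene_profiles(scen, 0)
        p = scen.true_parameters(scen.schedule)[
            scen.model.parameter_names.index("k_dnl")]
        assert pearson(genes.means[0], p) == pytest.approx(-1.0, abs=1e-12)

    def test_decoupled_gene_stays_flat(self):
        scen = self.make_scenario(cv=0.0, decoupled=True)
        genes = generate_gene_profiles(scen, 0)
        assert np.allclose(genes.means[0], 1.0)

    def test_coupled_genes_outrank_distractors(self, scenarios):
        scen = copy.deepcopy(scenarios["C"])
        for g in scen.gene_design.values():
            g["cv"] = 0.15
        i = scen.model.parameter_names.index("k_dnl")
        p = scen.true_parameters(scen.schedule)[i]
        wins = 0
        for seed in range(200):
            genes = generate_gene_profiles(scen, seed)
            rho_c = pearson(genes.means[genes.observables.index("g_dnl1")], p)
            rho_d = pearson(genes.means[genes.observables.index("g_flat1")], p)
            wins += rho_c > rho_d
        assert wins >= 0.95 * 200

    def test_seeded_determinism(self, scenarios):
        a = generate_gene_profiles(scenarios["B"], 9)
        b = generate_gene_profiles(scenarios["B"], 9)
        assert np.allclose(a.means, b.means)
        assert a.observables == b.observables


class TestBenchmarkSuite:
    def test_run_directory_round_trips_through_readers(self, tmp_path,
                                                       scenarios):
        out = tmp_path / "runB"
        manifest = write_run_directory(scenarios["B"], out, 3)
        model = MetabolicModel.from_json(out / "model.json")
        assert model.to_dict() == scenarios["B"].model.to_dict()
        metab = LongitudinalDataset.from_csv(out / "metabolic.csv")
        trans = LongitudinalDataset.from_csv(out / "transcript.csv")
        assert set(metab.kinds) == {"metabolic"}
        assert set(trans.kinds) == {"transcript"}
        coupling = GeneCouplingMap.from_csv(out / "coupling.csv")
        coupling.validate(model, trans.observables)
        assert manifest["scenario"] == "B_latent_pools"

    def test_scenario_trajectories_respect_bounds(self, scenarios):
        for scen in scenarios.values():
            t = np.linspace(0, scen.t_end, 200)
            p = scen.true_parameters(t)
            lo, hi = scen.model.parameter_bounds.T
            assert np.all(p >= lo[:, None]) and np.all(p <= hi[:, None])

    def test_out_of_bounds_trajectory_rejected(self):
        model = toy_lipid_model()
        with pytest.raises(ValueError, match="bounds"):
            SyntheticScenario(
                name="bad", model=model, baseline=dict(TRUE_BASELINE),
                trajectories={"k_dnl": {"type": "sigmoid", "factor": 1e6,
                                        "center": 5.0, "width": 1.0}})

    def test_latent_split_hypotheses_fit_equally_without_genes(
            self, scenarios):
        # without the baseline ratio and without gene data, two baseline
        # parameterizations routing the TG pool differently between
        # cytosol and ER reproduce the metabolic data equally well:
        # the split is structurally non-identifiable
        import numpy as np
        from pyadapt import (LongitudinalDataset, SolverSettings,
                             build_ensemble, generate_observations,
                             generate_truth, run_adapt)
        scen = scenarios["B"]
        model = scen.model
        truth = generate_truth(scen)
        obs = generate_observations(truth, scen, 7)
        keep = [i for i, o in enumerate(obs.observables)
                if o != "y_cyt_er_ratio"]
        obs2 = LongitudinalDataset(
            [obs.observables[i] for i in keep], obs.times,
            obs.means[keep], obs.sds[keep],
            [obs.kinds[i] for i in keep])

        def hypothesis(x3):
            # solve the baseline steady state for a prescribed ER pool
            g = {o: obs2.means[obs2.observables.index(o), 0]
                 for o in obs2.observables}
            x1, x4, pool = g["y_ffa"], g["y_tg_vldl"], g["y_tg_liver"]
            f2, f5, f6 = (g["y_ffa_uptake"], g["y_vldl_tg_production"],
                          g["y_tg_catabolism"])
            x2 = pool - x3
            vals = {"k_uptake": f2 / x1, "k_influx": f2,
                    "k_secretion": f5 / x3, "k_catabolism": f6 / x2,
                    "k_transfer": f5 / x2, "k_clearance": f5 / x4}
            vals["k_dnl"] = ((0.8 * vals["k_transfer"]
                              + vals["k_catabolism"]) * x2 - f2)
            return np.array([vals[n] for n in model.parameter_names])

        x3_true = truth.states[0, 2]
        ens = build_ensemble(obs2, 1, 0)
        sigma = {o: obs2.sd_function(o) for o in obs2.observables
                 if o in model.output_names}
        settings = SolverSettings(collocation_points=3)
        chis, er_end = [], []
        for x3 in (0.7 * x3_true, 1.3 * x3_true):
            p0 = hypothesis(x3)
            y0 = model.output_values(model.initial_state(p0), p0)
            idx = [model.output_names.index(o) for o in obs2.observables]
            assert np.allclose(y0[idx], obs2.means[:, 0], rtol=1e-9)
            sol = run_adapt(model, p0, ens.splines[0], sigma,
                            n_segments=21, t_end=scen.t_end,
                            settings=settings)
            chis.append(sol.chi_sum("chi_d2"))
            er_end.append(sol.states[-1, model.state_names.index("tg_er")])
        assert abs(chis[0] - chis[1]) / np.mean(chis) < 0.01
        # ... while the latent trajectories genuinely differ
        assert abs(er_end[0] - er_end[1]) / np.mean(er_end) > 0.2

    def test_coupled_gene_without_design_rejected(self):
        model = toy_lipid_model()
        with pytest.raises(ValueError, match="design"):
            SyntheticScenario(
                name="bad", model=model, baseline=dict(TRUE_BASELINE),
                coupling=GeneCouplingMap([("k_dnl", "mystery")]),
                gene_design={})
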