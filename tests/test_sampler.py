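"""Gibbs engine: conditional λ moves, Langevin dynamics, bias phases, runs."""

import numpy as np
import pytest

from ladybugs import (
    BiasState,
    Configuration,
    GibbsSchedule,
    InstabilityError,
    PhaseError,
    RunConfig,
    build_single_site_graph,
    conditional_lambda_distribution,
    make_gaussian_ligand_model,
    planned_refinements,
    propagate_md,
    run_ladybugs,
    sample_next_state,
    state_energy_vector,
    update_bias_post_mbar,
    update_bias_pre_mbar,
)


class TestConditionalDistribution:
    def test_uniform(self):
        p = conditional_lambda_distribution(np.zeros(4), np.zeros(4), beta=1.0)
        assert np.allclose(p, 0.25)

    def test_boltzmann_ratio(self):
        p = conditional_lambda_distribution(np.array([0.0, np.log(2.0)]), np.zeros(2), beta=1.0)
        assert np.allclose(p, [2 / 3, 1 / 3])

    def test_constant_shift_invariance(self, rng):
        e = rng.normal(size=5)
        b = rng.normal(size=5)
        p1 = conditional_lambda_distribution(e, b, beta=2.0)
        p2 = conditional_lambda_distribution(e + 11.0, b - 3.0, beta=2.0)
        assert np.allclose(p1, p2)

    def test_overflow_safety(self):
        p = conditional_lambda_distribution(np.array([0.0, -5000.0]), np.zeros(2), beta=1.0)
        assert np.allclose(p, [0.0, 1.0])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            conditional_lambda_distribution(np.array([0.0, np.inf]), np.zeros(2), 1.0)


class TestSampleNextState:
    def test_degenerate_certainty(self, rng):
        assert all(sample_next_state([1.0, 0.0, 0.0], rng) == 0 for _ in range(20))

    def test_empirical_frequency(self):
        rng = np.random.default_rng(5)
        n = 100_000
        draws = sum(sample_next_state([0.5, 0.5], rng) for _ in range(n))
        sigma = np.sqrt(n * 0.25)
        assert abs(draws - n / 2) < 3 * sigma

    def test_seed_reproducibility(self):
        seqs = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            seqs.append([sample_next_state([0.2, 0.3, 0.5], rng) for _ in range(50)])
        assert seqs[0] == seqs[1]

    def test_all_zero_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_next_state([0.0, 0.0], rng)


class TestPropagateMD:
    def test_stationary_at_zero_temperature(self):
        model = make_gaussian_ligand_model([2.0, 3.0])
        g = build_single_site_graph(2, 0.5)
        sched = GibbsSchedule(total_gibbs_steps=1, gibbs_steps_per_refinement=1, kT=1e-300, timestep=0.01)
        conf = model.initial_configuration()  # at the minimum for any λ state
        out = propagate_md(conf, g.states[0], model, 50, sched, np.random.default_rng(0))
        assert np.allclose(out.flat, conf.flat, atol=1e-12)

    def test_equipartition_variance(self):
        k = 2.0
        model = make_gaussian_ligand_model([k], env_spring=1.0, x0_dim=0)
        g = build_single_site_graph(1, 0.5)
        sched = GibbsSchedule(total_gibbs_steps=1, gibbs_steps_per_refinement=1, kT=1.0, timestep=0.05, friction=1.0)
        rng = np.random.default_rng(11)
        conf = model.initial_configuration()
        xs = []
        for _ in range(4000):
            conf = propagate_md(conf, g.states[0], model, 20, sched, rng)
            xs.append(conf.flat[0])
        var = np.var(xs)
        assert var == pytest.approx(1.0 / k, rel=0.08)

    def test_bit_identical_for_fixed_seed(self):
        model = make_gaussian_ligand_model([1.0, 4.0])
        g = build_single_site_graph(2, 0.5)
        sched = GibbsSchedule(total_gibbs_steps=1, gibbs_steps_per_refinement=1, kT=1.0)
        outs = []
        for _ in range(2):
            conf = model.initial_configuration()
            outs.append(
                propagate_md(conf, g.states[2], model, 100, sched, np.random.default_rng(3)).flat
            )
        assert np.array_equal(outs[0], outs[1])

    def test_instability_detected(self):
        model = make_gaussian_ligand_model([1000.0, 1000.0])
        g = build_single_site_graph(2, 0.5)
        sched = GibbsSchedule(total_gibbs_steps=1, gibbs_steps_per_refinement=1, kT=1.0, timestep=1.0)  # far beyond stability
        conf = Configuration(model, np.ones(model.n_dof))
        with pytest.raises(InstabilityError):
            propagate_md(conf, g.states[0], model, 200, sched, np.random.default_rng(0))


class TestBiasUpdates:
    def test_pre_mbar_flat_accumulation(self):
        bias = BiasState.initial(3, flat_bias=100.0)
        for s in [0, 0, 1, 0]:
            update_bias_pre_mbar(bias, s)
        assert list(bias.counts) == [3, 1, 0]
        assert list(bias.biases) == [300.0, 100.0, 0.0]

    def test_pre_mbar_zero_counts(self):
        bias = BiasState.initial(4)
        assert np.allclose(bias.biases, 0.0)

    def test_pre_mbar_small_flat_bias(self):
        bias = BiasState.initial(2, flat_bias=10.0)
        update_bias_pre_mbar(bias, 0)
        update_bias_pre_mbar(bias, 1)
        assert list(bias.biases) == [10.0, 10.0]

    def test_post_mbar_equal_counts(self):
        bias = BiasState.initial(2, eps_b=1.0)
        bias.phase = "post-MBAR"
        bias.anchored_dG = np.zeros(2)
        update_bias_post_mbar(bias)
        assert np.allclose(bias.biases, [1.0, 1.0])

    def test_post_mbar_count_gap_doubling(self):
        bias = BiasState.initial(3, eps_b=1.0)
        bias.phase = "post-MBAR"
        bias.counts = np.array([5, 3, 3])
        bias.anchored_dG = np.zeros(3)
        update_bias_post_mbar(bias)
        assert np.allclose(bias.biases, [4.0, 1.0, 1.0])

    def test_post_mbar_anchor_offsets(self):
        bias = BiasState.initial(2, eps_b=1.0)
        bias.phase = "post-MBAR"
        bias.counts = np.array([7, 7])
        bias.anchored_dG = np.array([0.0, -2.0])
        update_bias_post_mbar(bias)
        assert np.allclose(bias.biases, [1.0, 3.0])

    def test_phase_errors(self):
        bias = BiasState.initial(2)
        with pytest.raises(PhaseError):
            update_bias_post_mbar(bias)
        bias.phase = "post-MBAR"
        with pytest.raises(PhaseError):
            update_bias_post_mbar(bias)  # anchors still missing
        with pytest.raises(PhaseError):
            update_bias_pre_mbar(bias, 0)

    def test_large_gap_stays_finite(self):
        bias = BiasState.initial(2, eps_b=1.0)
        bias.phase = "post-MBAR"
        bias.counts = np.array([5000, 0])
        bias.anchored_dG = np.zeros(2)
        update_bias_post_mbar(bias)
        assert np.isfinite(bias.biases).all()


class TestSchedule:
    def test_paper_equivalent_refinement_count(self):
        # 15 ns at 100 x 2 fs per Gibbs step -> 75000 steps -> 75 refinements
        sched = GibbsSchedule.from_total_time(
            15e6, md_steps_per_gibbs=100, timestep=2.0, gibbs_steps_per_refinement=1000, kT=1.0
        )
        assert sched.total_gibbs_steps == 75_000
        assert planned_refinements(sched) == 75

    def test_shorter_run(self):
        sched = GibbsSchedule.from_total_time(
            5e6, md_steps_per_gibbs=100, timestep=2.0, gibbs_steps_per_refinement=1000, kT=1.0
        )
        assert planned_refinements(sched) == 25

    def test_single_refinement(self):
        sched = GibbsSchedule(total_gibbs_steps=1000, gibbs_steps_per_refinement=1000, kT=1.0)
        assert planned_refinements(sched) == 1

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GibbsSchedule(total_gibbs_steps=500, gibbs_steps_per_refinement=1000)
        with pytest.raises(ValueError):
            GibbsSchedule(total_gibbs_steps=100, gibbs_steps_per_refinement=100, kT=-1.0)


class TestRunLadybugs:
    def test_count_conservation_and_phase(self, sym_pair_run):
        cfg, result = sym_pair_run
        for ledger, bias in zip(result.ledgers, result.diagnostics["bias_states"]):
            assert bias.counts.sum() == len(ledger) == cfg.schedule.total_gibbs_steps
            assert bias.phase == "post-MBAR"
            assert ledger.state_counts().sum() == len(ledger)

    def test_refinements_performed(self, sym_pair_run):
        cfg, result = sym_pair_run
        for hist in result.diagnostics["refinement_history"]:
            assert len(hist) == planned_refinements(cfg.schedule)

    def test_symmetric_pair_dG_within_bootstrap(self, sym_pair_run):
        _, result = sym_pair_run
        dg, sigma = result.end_state_dG()[1]
        assert abs(dg) <= 3.5 * sigma

    def test_ledger_energy_round_trip(self, sym_pair_run):
        """Recomputing state energies at stored snapshots is bit-identical."""
        cfg, result = sym_pair_run
        graph = result.diagnostics["graph"]
        model = result.diagnostics["model"]
        ledger = result.ledgers[0]
        assert ledger.snapshots
        for step, flat in ledger.snapshots:
            u = state_energy_vector(Configuration(model, flat), graph, model)
            assert np.array_equal(u, ledger.energies[step - 1])

    def test_deterministic_given_seed(self):
        import ladybugs as lb

        cfg = lb.make_symmetric_pair_config(3, total_gibbs_steps=1000)
        cfg.schedule.replicates = 1
        cfg.n_boot = 0
        a = run_ladybugs(cfg)
        b = run_ladybugs(cfg)
        assert np.array_equal(a.ledgers[0].visited, b.ledgers[0].visited)
        assert np.array_equal(a.ledgers[0].energies, b.ledgers[0].energies)
        assert np.allclose(a.mbar.dG, b.mbar.dG)

    def test_single_state_graph_degenerates_to_md(self):
        cfg = RunConfig(
            model_name="gaussian_ligands",
            model_params={"spring_constants": [2.0]},
            substituent_counts=[1],
            delta_lambda=0.1,
            schedule=GibbsSchedule(
                total_gibbs_steps=200,
                gibbs_steps_per_refinement=200,
                kT=1.0,
                replicates=1,
                equilibration_steps=50,
                minimize_steps=20,
            ),
            n_boot=10,
        )
        result = run_ladybugs(cfg)
        assert result.mbar.dG == pytest.approx([0.0])
        assert (result.ledgers[0].visited == 0).all()

    def test_ledger_csv_round_trip(self, sym_pair_run, tmp_path):
        _, result = sym_pair_run
        from ladybugs import SampleLedger

        path = tmp_path / "ledger.csv"
        result.ledgers[0].save_csv(path)
        back = SampleLedger.load_csv(path)
        assert np.array_equal(back.visited, result.ledgers[0].visited)
        assert np.allclose(back.energies, result.ledgers[0].energies)
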