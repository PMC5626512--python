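"""Kcat harmonization, the doubling procedure, and the micro-GA."""

import numpy as np
import pytest

from popfba.constraints import KcatTable
from popfba.relaxation import (DoublingEvent, GAConfig, GAGenome,
                               PopulationContext, apply_genome,
                               doubling_procedure, genome_fitness,
                               growth_probabilities, harmonize_complex_kcats,
                               microga_select)
from popfba.synthetic import make_planted_chain, make_planted_ga_fixture


class TestHarmonization:
    def test_complex_raised_to_subunit_max(self, toy):
        _, model, prot, _ = toy
        out = harmonize_complex_kcats(prot.true_kcats, model)
        # GLY1 (900) is pulled up to its complex partner GLY2 (1700)
        assert out.kcat("GLY1") == out.kcat("GLY2") == 1700.0
        assert out.provenance("GLY1") == "complex-harmonized"

    def test_isozymes_untouched(self, toy):
        _, model, prot, _ = toy
        out = harmonize_complex_kcats(prot.true_kcats, model)
        assert out.kcat("PDC1") == prot.true_kcats.kcat("PDC1")
        assert out.kcat("PDC2") == prot.true_kcats.kcat("PDC2")

    def test_shared_gene_propagates_to_fixpoint(self):
        """A gene in two complexes takes the max over both groups, and the
        raise propagates transitively."""
        from conftest import build_mini_model
        model = build_mini_model(
            {
                "EX_A": ({"A": -1}, -10.0, 1000.0, ""),
                "R1": ({"A": -1, "B": 1}, 0.0, 1000.0, "G1 and G2"),
                "R2": ({"B": -1, "C": 1}, 0.0, 1000.0, "G2 and G3"),
                "BIOMASS": ({"C": -1}, 0.0, 1000.0, ""),
            },
            ["A", "B", "C"], "BIOMASS", {"G1", "G2", "G3"})
        kt = KcatTable({"G1": 100.0, "G2": 10.0, "G3": 500.0})
        out = harmonize_complex_kcats(kt, model)
        assert out.kcat("G1") == out.kcat("G2") == out.kcat("G3") == 500.0


class TestDoubling:
    def test_planted_gene_doubled_exactly_log2_deficit_times(self):
        """A transporter kcat planted 100x too low needs ceil(log2(100))=7
        doublings before the batch mean growth recovers the clean value."""
        fx = make_planted_chain(deficit=100.0)
        ctx = PopulationContext(fx.model, fx.marginals, None, fx.cal,
                                fx.true_kcats, fx.medium)
        target = float(ctx.simulate(400, 999).growth_rates.mean())
        table, log = doubling_procedure(
            fx.model, fx.marginals, None, fx.cal, fx.kcats, fx.medium,
            target_mean_growth=target, batch_size=400, seed=3)
        assert log.n_doublings == 7
        assert log.genes_affected == {"T1"}
        assert all(e.reaction_id == "T" for e in log.events)
        assert table.kcat("T1") == pytest.approx(
            fx.kcats.kcat("T1") * 2 ** 7)
        assert log.final_mean_growth >= target

    def test_zero_doublings_when_target_already_met(self):
        fx = make_planted_chain()
        table, log = doubling_procedure(
            fx.model, fx.marginals, None, fx.cal, fx.true_kcats, fx.medium,
            target_mean_growth=0.05, batch_size=100, seed=0)
        assert log.n_doublings == 0
        assert table.kcat("T1") == fx.true_kcats.kcat("T1")

    def test_replay_reproduces_final_table(self):
        fx = make_planted_chain(deficit=16.0)
        ctx = PopulationContext(fx.model, fx.marginals, None, fx.cal,
                                fx.true_kcats, fx.medium)
        target = float(ctx.simulate(200, 999).growth_rates.mean())
        table, log = doubling_procedure(
            fx.model, fx.marginals, None, fx.cal, fx.kcats, fx.medium,
            target_mean_growth=target, batch_size=200, seed=1)
        replayed = log.replay(fx.kcats)
        for g in table.genes():
            assert replayed.kcat(g) == table.kcat(g)

    def test_batch_mean_growth_nondecreasing(self):
        """Relaxing bounds only helps: logged batch means trend upward."""
        fx = make_planted_chain(deficit=100.0)
        ctx = PopulationContext(fx.model, fx.marginals, None, fx.cal,
                                fx.true_kcats, fx.medium)
        target = float(ctx.simulate(200, 999).growth_rates.mean())
        _, log = doubling_procedure(
            fx.model, fx.marginals, None, fx.cal, fx.kcats, fx.medium,
            target_mean_growth=target, batch_size=200, seed=2)
        mus = [e.batch_mean_growth for e in log.events] + [log.final_mean_growth]
        assert all(b >= a - 1e-6 for a, b in zip(mus, mus[1:]))

    def test_medium_limited_growth_raises(self):
        fx = make_planted_chain()
        with pytest.raises(RuntimeError, match="medium"):
            doubling_procedure(
                fx.model, fx.marginals, None, fx.cal, fx.true_kcats,
                fx.medium, target_mean_growth=5.0, batch_size=50, seed=0,
                max_iterations=5)

    def test_and_complex_doubles_all_subunits(self):
        """When the binding reaction is a complex, one event doubles every
        subunit simultaneously; isozymes would instead double only the
        highest-expressed member."""
        from conftest import build_mini_model
        from popfba.constraints import MediumSpec
        from popfba.proteomics import ProteinMarginal
        from popfba.synthetic import IDENTITY_CAL
        model = build_mini_model(
            {
                "EX_S": ({"s_e": -1}, -10.0, 1000.0, ""),
                "T": ({"s_e": -1, "s_c": 1}, 0.0, 1000.0, "TA and TB"),
                "BIOMASS": ({"s_c": -20.0}, 0.0, 1000.0, ""),
            },
            ["s_e", "s_c"], "BIOMASS", {"TA", "TB"})
        margs = [ProteinMarginal("TA", 25.0, 190_000.0 / 25.0, 18),
                 ProteinMarginal("TB", 25.0, 120_000.0 / 25.0, 18)]
        kcats = KcatTable({"TA": 30.0, "TB": 80.0})  # both choke the complex
        _, log = doubling_procedure(
            model, margs, None, IDENTITY_CAL, kcats, MediumSpec({"EX_S": 10.0}),
            target_mean_growth=0.30, batch_size=100, seed=4, max_iterations=30)
        assert log.events
        for e in log.events:
            assert e.reaction_id == "T"
            assert set(e.genes) == {"TA", "TB"}

    def test_event_validation(self):
        with pytest.raises(ValueError):
            DoublingEvent(0, "R", ("G",), (10.0,), (25.0,), 0.1)


class TestMicroGA:
    @pytest.fixture(scope="class")
    def ga_setup(self):
        fx = make_planted_ga_fixture()
        ctx = PopulationContext(fx.model, fx.marginals, None, fx.cal,
                                fx.kcats, fx.medium)
        cfg = GAConfig(cells_per_eval=40, max_generations=12, seed=0)
        big = ctx.simulate(2000, 12345, kcats=fx.true_kcats)
        target = growth_probabilities(big.growth_rates[big.feasible], cfg)
        return fx, ctx, cfg, target

    def test_fitness_deterministic(self, ga_setup):
        fx, ctx, cfg, target = ga_setup
        g = GAGenome(tuple(int(i < 3) for i in range(12)))
        f1 = genome_fitness(g, ctx, target, cfg, fx.candidate_genes)
        f2 = genome_fitness(g, ctx, target, cfg, fx.candidate_genes)
        assert f1 == f2

    def test_self_match_dominates_all_zeros(self, ga_setup):
        """The genome the target was generated from outranks the genome
        that keeps the planted-bad kcats."""
        fx, ctx, cfg, target = ga_setup
        true_bits = tuple(int(g in fx.planted_genes) for g in fx.candidate_genes)
        f_true = genome_fitness(GAGenome(true_bits), ctx, target, cfg,
                                fx.candidate_genes)
        f_zero = genome_fitness(GAGenome((0,) * 12), ctx, target, cfg,
                                fx.candidate_genes)
        assert f_true > f_zero

    def test_pathway_irrelevant_gene_is_fitness_neutral(self, ga_setup):
        """Two genomes differing only in a decoy gene's bit score within
        sampling noise of each other (here: identically, same seed)."""
        fx, ctx, cfg, target = ga_setup
        base = tuple(int(g in fx.planted_genes) for g in fx.candidate_genes)
        flipped = list(base)
        flipped[fx.candidate_genes.index("DEC5")] ^= 1
        f_a = genome_fitness(GAGenome(base), ctx, target, cfg,
                             fx.candidate_genes)
        f_b = genome_fitness(GAGenome(tuple(flipped)), ctx, target, cfg,
                             fx.candidate_genes)
        assert f_a == pytest.approx(f_b, abs=1e-12)

    def test_elite_trace_monotone_and_recovery(self, ga_setup):
        fx, ctx, cfg, target = ga_setup
        res = microga_select(ctx, target, cfg, fx.candidate_genes)
        assert all(b >= a for a, b in zip(res.trace, res.trace[1:]))
        lifted = {g for g, b in zip(fx.candidate_genes, res.best.bits) if b}
        assert set(fx.planted_genes) <= lifted

    def test_all_infeasible_scores_neg_inf(self, ga_setup):
        fx, ctx, cfg, target = ga_setup
        dead = ctx.model.copy()
        dead.lb[dead.index("BIOMASS")] = 900.0  # impossible demand
        dead_ctx = PopulationContext(dead, fx.marginals, None, fx.cal,
                                     fx.kcats, fx.medium)
        small = GAConfig(cells_per_eval=5, max_generations=5, seed=0)
        f = genome_fitness(GAGenome((1,) * 12), dead_ctx, target, small,
                           fx.candidate_genes)
        assert f == -np.inf

    def test_apply_genome_lifts_selected(self, ga_setup):
        fx, *_ = ga_setup
        bits = tuple(int(g == "PA") for g in fx.candidate_genes)
        out = apply_genome(fx.kcats, GAGenome(bits), fx.candidate_genes)
        assert out.kcat("PA") == 38_000.0
        assert out.provenance("PA") == "lifted-38000"
        assert out.kcat("PB") == fx.kcats.kcat("PB")

    def test_lifting_never_hurts_any_cell(self, ga_setup):
        """Raising a kcat relaxes bounds, so no cell grows slower."""
        fx, ctx, cfg, _ = ga_setup
        before = ctx.simulate(100, 8, kcats=fx.kcats)
        lifted = apply_genome(fx.kcats, GAGenome((1,) + (0,) * 11),
                              fx.candidate_genes)
        after = ctx.simulate(100, 8, kcats=lifted)
        assert (after.growth_rates >= before.growth_rates - 1e-9).all()
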