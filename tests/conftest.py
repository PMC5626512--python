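import pytest
from hypothesis import settings

from popfba.population import simulate_population
from popfba.sampling import sample_population
from popfba.synthetic import (ToyModelConfig, make_toy_medium, make_toy_model,
                              make_toy_proteomics)

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy():
    """Toy Crabtree model with matching synthetic omics."""
    cfg = ToyModelConfig()
    model = make_toy_model(cfg)
    prot = make_toy_proteomics(model, cfg, seed=1)
    return cfg, model, prot, make_toy_medium(cfg)


@pytest.fixture(scope="session")
def toy_population(toy):
    """A 2,000-cell correlated population under the clean kcat table.

    Session-scoped: several analytics tests share this single pFBA sweep.
    """
    cfg, model, prot, medium = toy
    samples = sample_population(2000, prot.marginals, prot.corr, prot.cal,
                                seed=42)
    result = simulate_population(model, samples, prot.true_kcats, medium,
                                 track_active=True)
    return samples, result


def build_mini_model(reactions, mets, biomass_id, genes=()):
    """Assemble a small MetabolicModel from {rxn: (stoich, lb, ub, gpr)}."""
    from popfba.synthetic import _build_model
    return _build_model("mini", mets, reactions, biomass_id, set(genes))


@pytest.fixture()
def chain_model():
    """EX_A(<=10) -> A->B -> biomass(1 B): one path, mu = uptake."""
    return build_mini_model(
        {
            "EX_A": ({"A": -1}, -10.0, 1000.0, ""),
            "R1": ({"A": -1, "B": 1}, 0.0, 1000.0, "G1"),
            "BIOMASS": ({"B": -1}, 0.0, 1000.0, ""),
        },
        ["A", "B"], "BIOMASS", {"G1"})


@pytest.fixture()
def parallel_model():
    """Two equal-yield routes A->B: direct (1 reaction) vs via C (2 reactions)."""
    return build_mini_model(
        {
            "EX_A": ({"A": -1}, -10.0, 1000.0, ""),
            "DIRECT": ({"A": -1, "B": 1}, 0.0, 1000.0, ""),
            "VIA1": ({"A": -1, "C": 1}, 0.0, 1000.0, ""),
            "VIA2": ({"C": -1, "B": 1}, 0.0, 1000.0, ""),
            "BIOMASS": ({"B": -1}, 0.0, 1000.0, ""),
        },
        ["A", "B", "C"], "BIOMASS")


@pytest.fixture()
def mini_crabtree():
    """7-reaction overflow network: respiration yields 3 ATP/pyruvate,
    fermentation 0, so capping respiration forces ethanol secretion."""
    return build_mini_model(
        {
            "EX_glc": ({"glc": -1}, -10.0, 1000.0, ""),
            "EX_o2": ({"o2": -1}, -1000.0, 1000.0, ""),
            "EX_eth": ({"eth": -1}, 0.0, 1000.0, ""),
            "GLYC": ({"glc": -1, "pyr": 2, "atp": 2}, 0.0, 1000.0, ""),
            "FERM": ({"pyr": -1, "eth": 1}, 0.0, 1000.0, ""),
            "RESP": ({"pyr": -1, "o2": -1, "atp": 3}, 0.0, 1000.0, "QCR"),
            "BIOMASS": ({"pyr": -2, "atp": -10}, 0.0, 1000.0, ""),
        },
        ["glc", "pyr", "atp", "o2", "eth"], "BIOMASS", {"QCR"})
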