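"""Small programmatically-built models shared across test modules."""

from conftest import build_mini_model


def two_reaction_shared_gene_model():
    """Gene G1 catalyzes both A->B and A->C."""
    return build_mini_model(
        {
            "EX_A": ({"A": -1}, -10.0, 1000.0, ""),
            "R1": ({"A": -1, "B": 1}, 0.0, 1000.0, "G1"),
            "R2": ({"A": -1, "C": 1}, 0.0, 1000.0, "G1"),
            "B1": ({"B": -1, "BM": 1}, 0.0, 1000.0, ""),
            "B2": ({"C": -1, "BM": 1}, 0.0, 1000.0, ""),
            "BIOMASS": ({"BM": -1}, 0.0, 1000.0, ""),
        },
        ["A", "B", "C", "BM"], "BIOMASS", {"G1"})
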