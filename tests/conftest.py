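import numpy as np
import pytest

from gsmdep import depletion as dep
from gsmdep import synthetic as synth
from gsmdep.gpr import parse_gpr
from gsmdep.network import MetabolicNetwork, Reaction


def _rxn(rid, stoich, gpr=None, **kw):
    return Reaction(id=rid, stoichiometry=stoich, gpr=parse_gpr(gpr), **kw)


@pytest.fixture(scope="session")
def toy_chain():
    """Linear chain EX -> A -(g1)-> B -(g2)-> C -(g3)-> D, biomass {B, C, D}."""
    return MetabolicNetwork(
        metabolites=("A", "B", "C", "D"),
        reactions=(
            _rxn("EX_A", {"A": 1.0}),
            _rxn("R1", {"A": -1.0, "B": 1.0}, "g1"),
            _rxn("R2", {"B": -1.0, "C": 1.0}, "g2"),
            _rxn("R3", {"C": -1.0, "D": 1.0}, "g3"),
        ),
        biomass_components=("B", "C", "D"),
        exchanges=frozenset(["EX_A"]),
    )


@pytest.fixture(scope="session")
def four_branch():
    """Four independent biomass branches, one gene each: removing one
    gene knocks out exactly one of four biomass components."""
    mets, reactions, biomass = ["S"], [_rxn("EX_S", {"S": 1.0})], []
    for i in range(1, 5):
        mets.append(f"B{i}")
        biomass.append(f"B{i}")
        reactions.append(_rxn(f"R{i}", {"S": -1.0, f"B{i}": 1.0}, f"g{i}"))
    return MetabolicNetwork(
        metabolites=tuple(mets),
        reactions=tuple(reactions),
        biomass_components=tuple(biomass),
        exchanges=frozenset(["EX_S"]),
    )


@pytest.fixture(scope="session")
def small_network():
    return synth.make_network(seed=42, n_genes=8, n_biomass=3)


@pytest.fixture(scope="session")
def default_network():
    return synth.make_network(seed=1)


@pytest.fixture(scope="session")
def null_series(default_network):
    """Null expression fixture (effect 0, 4 conditions x 3 replicates)
    with its cached per-sample removal series."""
    design, _ = synth.make_expression(
        default_network, seed=3, n_conditions=4, n_replicates=3,
        planted=None, effect=0.0,
    )
    return default_network, design, dep.series_by_sample(default_network, design, step=1)


@pytest.fixture(scope="session")
def planted_series(default_network):
    """Planted-signal fixture: 4 conditions x 6 replicates, the planted
    set down-shifted in condition C1."""
    sets, planted = synth.make_gene_sets(default_network, seed=2, n_sets=30)
    design, truth = synth.make_expression(
        default_network, seed=4, n_conditions=4, n_replicates=6,
        planted=planted, effect=3.0,
    )
    series = dep.series_by_sample(default_network, design, step=1)
    return default_network, design, series, sets, planted, truth


@pytest.fixture(scope="session")
def eight_condition_series():
    """8-condition design on a small model, for contrast enumeration."""
    net = synth.make_network(seed=9, n_genes=12, n_biomass=4)
    design, _ = synth.make_expression(net, seed=10, n_conditions=8,
                                      n_replicates=2, effect=0.0)
    return net, design, dep.series_by_sample(net, design, step=2)


@pytest.fixture(scope="session")
def causal_fixture_series():
    fx = synth.make_causal_fixture(seed=7)
    series = dep.series_by_sample(fx.network, fx.design, step=1)
    return fx, series


@pytest.fixture(scope="session")
def chip_sim():
    return synth.make_chip(seed=11)


@pytest.fixture(scope="session")
def chip_called(chip_sim):
    from gsmdep.chip import call_regions

    regions, density = call_regions(chip_sim.chip_tracks, chip_sim.input_of,
                                    chip_sim.condition_of)
    return regions, density
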