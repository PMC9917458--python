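import pytest

from snbp.simulate.config import CoverageParams, EventRates, SimulationConfig


@pytest.fixture
def quartet_newick() -> str:
    return "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def base_config(quartet_newick) -> SimulationConfig:
    return SimulationConfig(seed=1, tree_spec=quartet_newick).validate()


@pytest.fixture
def coverage_params() -> CoverageParams:
    lengths, classes = {}, {}
    layout = ["A"] * 14 + ["X"] * 4 + ["Y"] * 2
    for i, cls in enumerate(layout):
        name = f"ctg{i:02d}"
        lengths[name] = 100_000
        classes[name] = cls
    return CoverageParams(
        haploid_depth=30.0,
        dispersion=0.2,
        window=10_000,
        contig_lengths=lengths,
        contig_classes=classes,
    )


def loss_only_config(seed: int, newick: str, loss: float) -> SimulationConfig:
    rates = {c: EventRates(loss=loss) for c in ("A", "X", "Y")}
    return SimulationConfig(
        seed=seed, tree_spec=newick, rates=rates, n_root_genes=4
    ).validate()
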