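import pytest

from cnvmir.genome import GenomeBuild
from cnvmir.simulate import GroupSpec, SimulationSpec, simulate_cohort


@pytest.fixture(scope="session")
def toy_genome() -> GenomeBuild:
    return GenomeBuild({"chr1": 10_000, "chr2": 10_000})


def small_spec(seed: int = 3, **overrides) -> SimulationSpec:
    """A scaled-down cohort spec: same five-group design, fewer events."""
    groups = {
        "de_novo": GroupSpec(8, 2.5e6, 0.6, mirna_bias=5.0, brain_fraction=0.55),
        "familial": GroupSpec(10, 0.55e6, 0.6, 1.0, 0.50),
        "common_case": GroupSpec(20, 0.45e6, 0.5, 1.0, 0.25),
        "common_control": GroupSpec(10, 0.50e6, 0.5, 1.0, 0.0),
        "decipher": GroupSpec(8, 2.5e6, 0.6, 5.0, 0.46),
    }
    defaults = dict(seed=seed, n_mirnas=300, n_genes=1000, groups=groups,
                    n_decoy_pathways=10)
    defaults.update(overrides)
    return SimulationSpec(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_spec())
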