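import numpy as np
import pytest

from c1comp import (
    HgtEvent,
    IslandSpec,
    SimConfig,
    SingletonSpec,
    simulate,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(AA[i] for i in rng.integers(0, 20, n))


@pytest.fixture(scope="session")
def small_pair():
    """Two genomes, 60 core genes, target AAI 70 — reused across tests."""
    cfg = SimConfig(seed=42, labels=("A", "B"), genes_per_genome=60,
                    target_identity_pct=70.0)
    return simulate(cfg)


@pytest.fixture(scope="session")
def hgt_pair():
    """Donor/recipient pair at AAI 55 with an 8-gene island moved at 85%."""
    functions = ("Mao", "Tmo", "Tmd", "EutQ", "Hps", "Hpi", "Gma", "MgsA")
    cfg = SimConfig(
        seed=99, labels=("D", "R"), genes_per_genome=60,
        target_identity_pct=55.0,
        islands=(IslandSpec("isl1", functions, ("D",)),),
        singletons=(SingletonSpec("Fdh1", ("D", "R")),
                    SingletonSpec("Gnd", ("D", "R"))),
        hgt=(HgtEvent("D", "R", functions, 85.0),),
    )
    return simulate(cfg)
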