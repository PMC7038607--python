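import numpy as np
import pytest

from ecprofiler import lsh, simulate as sim
from ecprofiler.reference_db import GoldStandard, ProteinRecord


@pytest.fixture(scope="session")
def small_ensemble() -> lsh.GallagerHashEnsemble:
    return lsh.build_gallager_ensemble(k=8, r=4, m=8, seed=7)


@pytest.fixture(scope="session")
def toy_gold() -> GoldStandard:
    """Four synthetic enzyme families at moderate divergence."""
    cfg = sim.SimulationConfig(n_ecs=4, family_size=4, length_range=(60, 90), divergence=0.1, seed=3)
    gold, _ = sim.simulate_protein_families(cfg)
    return gold


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_protein(rng: np.random.Generator, length: int) -> str:
    aa = np.frombuffer(lsh.ALPHABET.encode(), dtype=np.uint8)
    return aa[rng.integers(0, 20, size=length)].tobytes().decode()
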