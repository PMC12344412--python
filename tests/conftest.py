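import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20250921)


def random_genome(rng, length, gc=0.5, circular=True, name="rand"):
    from gntmotif import Genome

    bases = np.array(list("ACGT"))
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(bases, size=length, p=probs))
    return Genome(name=name, sequence=seq, circular=circular)


def random_model(rng, length):
    from gntmotif import ReplichoreModel

    oriC = int(rng.integers(0, length))
    ter = int(rng.integers(0, length - 1))
    if ter >= oriC:
        ter += 1  # ensure ter != oriC
    ter %= length
    if ter == oriC:
        ter = (oriC + length // 2) % length
    return ReplichoreModel(oriC=oriC, ter=ter, genome_length=length)
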