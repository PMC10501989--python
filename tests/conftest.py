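import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_library():
    """A 4-gene, 2-guide library plus two non-targeting controls."""
    from sortscreen import GuideLibrary
    from sortscreen.simulate import random_guide_sequences

    seqs = random_guide_sequences(10, np.random.default_rng(7))
    entries = []
    k = 0
    for gene in ["GA", "GB", "GC", "GD"]:
        for j in range(2):
            entries.append((f"{gene}_g{j}", seqs[k], gene))
            k += 1
    for j in range(2):
        entries.append((f"NT_g{j}", seqs[k], "NT"))
        k += 1
    return GuideLibrary(entries)
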